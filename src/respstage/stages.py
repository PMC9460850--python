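"""The five sleep stages used throughout the pipeline."""

from __future__ import annotations

import enum


class SleepStage(enum.IntEnum):
    """Sleep stages: wakefulness, the three non-REM depths, and REM.

    The integer order AWAKE < N1 < N2 < N3 < REM is used only for stable
    reporting (confusion-matrix axes, file columns); it carries no
    physiological meaning beyond non-REM depth.
    """

    AWAKE = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4

    @classmethod
    def from_name(cls, name: str) -> "SleepStage":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise KeyError(f"unknown sleep stage {name!r}; expected one of "
                           f"{[s.name for s in cls]}") from None


#: Canonical reporting order.
STAGE_ORDER: tuple[SleepStage, ...] = tuple(SleepStage)
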