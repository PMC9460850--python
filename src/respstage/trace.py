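"""Time-series containers: a single voltage trace and a night of epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .stages import SleepStage


@dataclass(frozen=True, eq=False)
class RespirationTrace:
    """A uniformly sampled voltage time series from the mask sensor.

    Parameters
    ----------
    samples : array of float
        Voltage in volts, one value per sample.
    dt : float
        Sampling interval in seconds (0.017 s for the mask sensor chain).
    start_time : float
        Time of the first sample in seconds.
    stage_label : SleepStage, optional
        Ground-truth stage, if known.
    """

    samples: np.ndarray
    dt: float
    start_time: float = 0.0
    stage_label: SleepStage | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidParameterError("trace needs a 1-D sample array with length >= 1")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("trace samples must be finite")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the trace in seconds (n_samples * dt)."""
        return self.samples.size * self.dt

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + self.dt * np.arange(self.samples.size)

    def with_samples(self, samples: np.ndarray) -> "RespirationTrace":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class AcquisitionModel:
    """DC offset and additive Gaussian noise of the acquisition electronics."""

    dc_offset: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class SleepSession:
    """An ordered, time-contiguous list of labeled measurement epochs."""

    epochs: list[tuple[SleepStage, RespirationTrace]] = field(default_factory=list)

    def __post_init__(self):
        t = None
        for stage, trace in self.epochs:
            if t is not None and abs(trace.start_time - t) > trace.dt / 2:
                raise InvalidParameterError(
                    f"epochs must be time-contiguous; expected start {t:.6f}, "
                    f"got {trace.start_time:.6f}")
            t = trace.start_time + trace.duration

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def hypnogram(self) -> list[tuple[float, float, SleepStage]]:
        """(start_s, duration_s, stage) records, one per epoch."""
        return [(tr.start_time, tr.duration, st) for st, tr in self.epochs]

    def stage_at(self, time_s: float) -> SleepStage | None:
        """Stage of the epoch containing ``time_s``, or None if outside."""
        for start, dur, stage in self.hypnogram:
            if start <= time_s < start + dur:
                return stage
        return None

    def concatenated(self) -> RespirationTrace:
        """All epochs joined into one continuous trace (label dropped)."""
        if not self.epochs:
            raise InvalidParameterError("cannot concatenate an empty session")
        samples = np.concatenate([tr.samples for _, tr in self.epochs])
        first = self.epochs[0][1]
        return RespirationTrace(samples, first.dt, start_time=first.start_time)
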