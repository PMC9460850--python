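"""The two feature-scaling steps applied before clustering.

Raw features live on incommensurate scales: respiration rates are ~12-18
b/min while relative voltages are <= 1, so an unscaled Euclidean distance is
dominated by the rate axis.  Two steps fix this:

1. the *relative output voltage* — every window voltage is divided by the
   highest voltage observed in the training data, suppressing night-to-night
   drift of the sensor output;
2. a *weight value* W (default 0.1) multiplied onto the respiration rate,
   bringing the two axes to a similar order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import InvalidParameterError
from .processing import FeatureVector


@dataclass(frozen=True)
class ScalingConfig:
    """Weight on the rate axis and the stored voltage reference (volts)."""

    weight_W: float = 0.1
    voltage_reference: float = 1.0

    def __post_init__(self):
        if self.weight_W <= 0:
            raise InvalidParameterError("weight_W must be positive")
        if self.voltage_reference <= 0:
            raise InvalidParameterError("voltage_reference must be positive")


def fit_voltage_reference(features: Sequence[FeatureVector]) -> float:
    """The highest output voltage among the raw features (the reference).

    New data scaled with a stored reference may exceed 1; the reference is
    never refitted at classification time.
    """
    if not features:
        raise InvalidParameterError("cannot fit a voltage reference on no features")
    ref = max(f.voltage for f in features)
    if ref <= 0:
        raise InvalidParameterError("all voltages are zero; no usable reference")
    return ref


def fit_scaling(features: Sequence[FeatureVector], weight_W: float = 0.1) -> ScalingConfig:
    """Convenience: fit the voltage reference and bundle it with W."""
    return ScalingConfig(weight_W=weight_W,
                         voltage_reference=fit_voltage_reference(features))


def apply_scaling(features: Iterable[FeatureVector],
                  config: ScalingConfig) -> list[FeatureVector]:
    """Map each feature to (W * rate, voltage / reference); labels kept."""
    return [replace(f, rate_bpm=config.weight_W * f.rate_bpm,
                    voltage=f.voltage / config.voltage_reference)
            for f in features]


def invert_scaling(features: Iterable[FeatureVector],
                   config: ScalingConfig) -> list[FeatureVector]:
    """Undo :func:`apply_scaling` with the same config."""
    return [replace(f, rate_bpm=f.rate_bpm / config.weight_W,
                    voltage=f.voltage * config.voltage_reference)
            for f in features]
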