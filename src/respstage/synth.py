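"""Synthetic mask-sensor respiration signals with sleep-stage structure.

No participant recordings are publicly available for this kind of
triboelectric mask sensor, so the pipeline is exercised on synthetic traces
whose per-stage statistics follow what is reported for real nights: the
dominant breath frequency per stage, voltage amplitudes that shrink as
non-REM sleep deepens, and markedly irregular breathing during REM.

Every generated quantity is drawn from an explicitly seeded
``numpy.random.Generator``, so a (model, seed, duration, dt) tuple is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .stages import STAGE_ORDER, SleepStage
from .trace import AcquisitionModel, RespirationTrace, SleepSession

#: Physiological band used to truncate breath-frequency draws (Hz).
FREQ_BOUNDS = (0.05, 1.0)

#: Default breath-cycle shape fractions (rise, plateau); the fall takes the rest.
DEFAULT_RISE_FRAC = 0.25
DEFAULT_PLATEAU_FRAC = 0.25

#: Open-circuit voltage of a normal nasal breath, used as the awake amplitude (V).
NORMAL_BREATH_VOLTS = 7.89


@dataclass(frozen=True)
class StageSignalModel:
    """Generative parameters of the breathing signal for one sleep stage.

    ``breath_freq_mean``/``breath_freq_sd`` describe the night-to-night /
    epoch-to-epoch distribution of the dominant breath frequency (Hz);
    ``amp_mean``/``amp_sd`` the epoch-level breath amplitude (V). The two
    coefficients of variation add breath-to-breath jitter inside an epoch:
    ``breath_period_cv`` on the period, ``breath_amp_cv`` on the amplitude.
    """

    stage: SleepStage
    breath_freq_mean: float
    breath_freq_sd: float = 0.0
    amp_mean: float = NORMAL_BREATH_VOLTS
    amp_sd: float = 0.0
    breath_period_cv: float = 0.0
    breath_amp_cv: float = 0.0

    def __post_init__(self):
        if not (0 < self.breath_freq_mean <= 1):
            raise InvalidParameterError("breath_freq_mean must lie in (0, 1] Hz")
        if self.amp_mean <= 0:
            raise InvalidParameterError("amp_mean must be positive")
        for name in ("breath_freq_sd", "amp_sd", "breath_period_cv", "breath_amp_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    def zero_variance(self) -> "StageSignalModel":
        """Copy of the model with all dispersion parameters set to zero."""
        return replace(self, breath_freq_sd=0.0, amp_sd=0.0,
                       breath_period_cv=0.0, breath_amp_cv=0.0)


# Per-stage dominant breath frequencies as reported for a sleeping adult:
# awake 0.272 Hz, N1 0.264 Hz, N2 0.233 Hz, N3 0.210 Hz, REM 0.292 Hz.
_STAGE_FREQS = {
    SleepStage.AWAKE: 0.272,
    SleepStage.N1: 0.264,
    SleepStage.N2: 0.233,
    SleepStage.N3: 0.210,
    SleepStage.REM: 0.292,
}

# Amplitude means: non-REM tidal volume (and hence sensor voltage) decreases
# with sleep depth; REM breathes at awake-like amplitude but irregularly.
_AMP_SCALE = {
    SleepStage.AWAKE: 1.0,
    SleepStage.N1: 0.9,
    SleepStage.N2: 0.8,
    SleepStage.N3: 0.7,
    SleepStage.REM: 1.0,
}

# Dispersion defaults (synthetic; the per-stage sigma table of the reference
# recordings is not public).  Non-REM breathing is regular; REM gets ~2.5-3x
# the dispersion on every axis, which reproduces the qualitative findings
# (widest REM rate distribution, REM hardest to classify).
_NONREM_FREQ_SD = 0.005   # Hz, epoch-to-epoch
_REM_FREQ_SD = 0.012
_NONREM_AMP_CV = 0.025    # fraction of amp_mean, epoch-to-epoch
_REM_AMP_CV = 0.075
_NONREM_PERIOD_CV = 0.03  # breath-to-breath
_REM_PERIOD_CV = 0.10
_NONREM_BREATH_AMP_CV = 0.04
_REM_BREATH_AMP_CV = 0.12


def default_stage_models() -> dict[SleepStage, StageSignalModel]:
    """Default generative model per stage.

    Breath-frequency means are the published per-stage values; amplitude
    means decrease strictly through the non-REM depths from the normal
    nasal-breath voltage of 7.89 V; REM carries the largest dispersion on
    every parameter.
    """
    models = {}
    for stage in STAGE_ORDER:
        rem = stage is SleepStage.REM
        amp_mean = NORMAL_BREATH_VOLTS * _AMP_SCALE[stage]
        models[stage] = StageSignalModel(
            stage=stage,
            breath_freq_mean=_STAGE_FREQS[stage],
            breath_freq_sd=_REM_FREQ_SD if rem else _NONREM_FREQ_SD,
            amp_mean=amp_mean,
            amp_sd=amp_mean * (_REM_AMP_CV if rem else _NONREM_AMP_CV),
            breath_period_cv=_REM_PERIOD_CV if rem else _NONREM_PERIOD_CV,
            breath_amp_cv=_REM_BREATH_AMP_CV if rem else _NONREM_BREATH_AMP_CV,
        )
    return models


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """One draw from N(mean, sd) truncated to (lo, hi] by rejection."""
    if sd == 0:
        return float(np.clip(mean, lo + 1e-12, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-12, hi))


def synth_breath_cycle(period: float, amplitude: float, dt: float,
                       rise_frac: float = DEFAULT_RISE_FRAC,
                       plateau_frac: float = DEFAULT_PLATEAU_FRAC) -> RespirationTrace:
    """One breath cycle as a piecewise-linear rise/plateau/fall pulse.

    The voltage rises while the sensor film contacts the electrode during
    exhalation, holds a plateau while contact is maintained, and falls back
    to zero during inhalation.  The cycle starts and ends at 0 V and its
    maximum equals ``amplitude`` throughout the plateau.
    """
    if period <= 0 or dt <= 0:
        raise InvalidParameterError("period and dt must be positive")
    if period <= dt:
        raise InvalidParameterError("period must exceed the sampling interval")
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    if rise_frac < 0 or plateau_frac < 0 or rise_frac + plateau_frac > 1:
        raise InvalidParameterError("need rise_frac, plateau_frac >= 0 with sum <= 1")
    n = int(round(period / dt))
    n = max(n, 1)
    if n == 1:
        return RespirationTrace(np.zeros(1), dt)
    phase = np.arange(n) / (n - 1)
    knots_x = np.array([0.0, rise_frac, rise_frac + plateau_frac, 1.0])
    knots_y = np.array([0.0, 1.0, 1.0, 0.0])
    samples = amplitude * np.interp(phase, knots_x, knots_y)
    return RespirationTrace(samples, dt)


def _breath_train(model: StageSignalModel, duration: float, dt: float,
                  rng: np.random.Generator,
                  rise_frac: float, plateau_frac: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated breath cycles filling ``duration``; returns (samples, phase).

    ``phase`` holds each sample's position within its own cycle in [0, 1],
    so callers can locate exhalation (rise + plateau) segments.
    """
    n_total = int(round(duration / dt))
    mean_period = 1.0 / model.breath_freq_mean
    if duration < mean_period:
        raise InvalidParameterError(
            f"duration {duration} s is shorter than one mean breath "
            f"({mean_period:.2f} s)")
    f_epoch = _truncated_normal(rng, model.breath_freq_mean,
                                model.breath_freq_sd, *FREQ_BOUNDS)
    amp_epoch = _truncated_normal(rng, model.amp_mean, model.amp_sd,
                                  0.0, np.inf)
    base_period = 1.0 / f_epoch
    period_lo, period_hi = 1.0 / FREQ_BOUNDS[1], 1.0 / FREQ_BOUNDS[0]

    chunks, phases = [], []
    total = 0
    while total < n_total:
        if model.breath_period_cv > 0:
            period = base_period * (1.0 + model.breath_period_cv * rng.standard_normal())
        else:
            period = base_period
        period = float(np.clip(period, max(period_lo, 2 * dt), period_hi))
        if model.breath_amp_cv > 0:
            amp = max(0.0, amp_epoch * (1.0 + model.breath_amp_cv * rng.standard_normal()))
        else:
            amp = amp_epoch
        cycle = synth_breath_cycle(period, amp, dt, rise_frac, plateau_frac)
        n = len(cycle)
        chunks.append(cycle.samples)
        phases.append(np.arange(n) / max(n - 1, 1))
        total += n
    samples = np.concatenate(chunks)[:n_total]
    phase = np.concatenate(phases)[:n_total]
    return samples, phase


def synth_epoch(model: StageSignalModel, duration: float = 30.0,
                dt: float = 0.017, seed: int = 0,
                rise_frac: float = DEFAULT_RISE_FRAC,
                plateau_frac: float = DEFAULT_PLATEAU_FRAC,
                start_time: float = 0.0) -> RespirationTrace:
    """One labeled measurement epoch (default 30 s at dt = 0.017 s).

    Breath periods and amplitudes are drawn hierarchically: an epoch-level
    frequency f ~ N(breath_freq_mean, breath_freq_sd) truncated to
    (0.05, 1] Hz and amplitude A ~ N(amp_mean, amp_sd) truncated at 0, then
    per-breath jitter through the model's coefficients of variation.  The
    trace has exactly round(duration/dt) samples and carries the model's
    stage label.  Identical seeds give identical traces.
    """
    rng = np.random.default_rng(seed)
    samples, _ = _breath_train(model, duration, dt, rng, rise_frac, plateau_frac)
    return RespirationTrace(samples, dt, start_time=start_time,
                            stage_label=model.stage)


def synth_snoring_epoch(model: StageSignalModel, vib_freq: float = 8.0,
                        vib_depth: float = 0.5, duration: float = 30.0,
                        dt: float = 0.017, seed: int = 0,
                        attenuation: float = 0.6,
                        rise_frac: float = DEFAULT_RISE_FRAC,
                        plateau_frac: float = DEFAULT_PLATEAU_FRAC,
                        start_time: float = 0.0) -> RespirationTrace:
    """An epoch with snoring: attenuated breaths carrying a fast vibration.

    Snoring makes the airflow discrete rather than continuous: the sensor
    output shrinks (reduced tidal volume, ``attenuation`` < 1) and acquires
    a vibrating component at ``vib_freq`` during exhalation.  With
    ``vib_depth = 0`` and ``attenuation = 1`` this reduces exactly to
    :func:`synth_epoch` at the same seed.
    """
    if not (0 <= vib_depth <= 1):
        raise InvalidParameterError("vib_depth must lie in [0, 1]")
    if attenuation <= 0:
        raise InvalidParameterError("attenuation must be positive")
    if vib_freq < 5 * model.breath_freq_mean:
        raise InvalidParameterError(
            "vib_freq must be well above the breath frequency (>= 5x)")
    rng = np.random.default_rng(seed)
    samples, phase = _breath_train(model, duration, dt, rng, rise_frac, plateau_frac)
    samples = attenuation * samples
    if vib_depth > 0:
        t = dt * np.arange(samples.size)
        exhale = phase <= rise_frac + plateau_frac
        vib = 1.0 + vib_depth * np.sin(2 * np.pi * vib_freq * t) * exhale
        samples = samples * vib
    return RespirationTrace(samples, dt, start_time=start_time,
                            stage_label=model.stage)


def add_acquisition_artifacts(trace: RespirationTrace, acq: AcquisitionModel,
                              seed: int = 0) -> RespirationTrace:
    """Add the acquisition chain's DC offset and Gaussian noise to a trace."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, acq.noise_sd, size=len(trace)) if acq.noise_sd > 0 \
        else np.zeros(len(trace))
    return trace.with_samples(trace.samples + acq.dc_offset + noise)


def synth_session(hypnogram: Sequence[tuple[SleepStage, float]],
                  models: Mapping[SleepStage, StageSignalModel] | None = None,
                  acq: AcquisitionModel | None = None,
                  dt: float = 0.017, seed: int = 0) -> SleepSession:
    """A whole night: one epoch per hypnogram entry, artifacts applied.

    Each epoch uses the derived seed ``seed + index`` so epochs are
    independent yet the session is reproducible as a whole.
    """
    if not hypnogram:
        raise InvalidParameterError("hypnogram must contain at least one epoch")
    models = models if models is not None else default_stage_models()
    acq = acq if acq is not None else AcquisitionModel()
    epochs = []
    t = 0.0
    for i, (stage, dur) in enumerate(hypnogram):
        if dur <= 0:
            raise InvalidParameterError(f"epoch {i}: duration must be positive")
        trace = synth_epoch(models[stage], duration=dur, dt=dt,
                            seed=seed + i, start_time=t)
        trace = add_acquisition_artifacts(trace, acq, seed=seed + i)
        trace = replace(trace, stage_label=stage)
        epochs.append((stage, trace))
        t += trace.duration
    return SleepSession(epochs)
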