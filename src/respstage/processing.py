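"""Feature extraction: respiration rate via FFT, output voltage via peaks.

Two numbers summarize each 30-s analysis window of an offset-removed trace:

* the respiration rate in breaths/minute, 60x the dominant frequency of the
  spectrum inside the physiological band (0.1-0.5 Hz), refined by
  zero-padding the FFT to a <= 0.002 Hz grid;
* the output voltage in volts, the mean height of the detected per-breath
  peaks above the window baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.signal

from .errors import FeatureExtractionError, InvalidParameterError, NoSignalError
from .stages import SleepStage
from .trace import RespirationTrace
from .trace import SleepSession

#: Physiological respiration band in Hz.
DEFAULT_BAND = (0.1, 0.5)

#: Frequency-grid spacing after zero padding (Hz).
DEFAULT_GRID_HZ = 0.002


@dataclass(frozen=True, eq=False)
class AnalysisWindow:
    """An offset-removed trace segment analyzed as one unit."""

    trace: RespirationTrace
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self):
        lo, hi = self.band
        if not (0 < lo < hi):
            raise InvalidParameterError(f"band must satisfy 0 < lo < hi, got {self.band}")
        if len(self.trace) < 2:
            raise InvalidParameterError("window must contain at least 2 samples")


@dataclass(frozen=True)
class FeatureVector:
    """One (respiration rate, output voltage) observation.

    Before scaling the voltage is in volts; after scaling both coordinates
    are dimensionless and form the point (a, b) whose distance to each
    cluster centroid decides the stage.
    """

    rate_bpm: float
    voltage: float
    stage_label: SleepStage | None = None

    def __post_init__(self):
        if not (math.isfinite(self.rate_bpm) and math.isfinite(self.voltage)):
            raise InvalidParameterError("feature coordinates must be finite")
        if self.rate_bpm < 0 or self.voltage < 0:
            raise InvalidParameterError("feature coordinates must be >= 0")


def remove_offset(trace: RespirationTrace) -> RespirationTrace:
    """Subtract the sample median, removing the acquisition DC offset.

    The median rather than the mean is used because breath pulses are
    asymmetric: the mean sits well above the baseline of the rise/plateau/
    fall waveform, while the median is robust to it.  The result has median
    0 and the operation is idempotent.
    """
    if len(trace) < 2:
        raise InvalidParameterError("offset removal needs at least 2 samples")
    return trace.with_samples(trace.samples - np.median(trace.samples))


def segment_windows(trace: RespirationTrace, window_length: float = 30.0,
                    band: tuple[float, float] = DEFAULT_BAND) -> list[AnalysisWindow]:
    """Cut a trace into consecutive non-overlapping windows.

    A trailing remainder shorter than half a window is dropped; otherwise it
    is kept as a short final window.
    """
    if window_length < 2 * trace.dt:
        raise InvalidParameterError("window_length must cover at least 2 samples")
    n_win = int(round(window_length / trace.dt))
    n = len(trace)
    windows = []
    start = 0
    while start < n:
        chunk = trace.samples[start:start + n_win]
        if chunk.size < n_win and chunk.size < n_win / 2:
            break
        sub = RespirationTrace(chunk, trace.dt,
                               start_time=trace.start_time + start * trace.dt,
                               stage_label=trace.stage_label)
        windows.append(AnalysisWindow(sub, band))
        start += n_win
    return windows


def dominant_frequency(window: AnalysisWindow,
                       grid_hz: float = DEFAULT_GRID_HZ,
                       taper: str | None = None) -> float:
    """Frequency of the largest spectral magnitude inside the band (Hz).

    The transform is zero-padded so the frequency grid is no coarser than
    ``grid_hz``; the raw 1/T resolution of a 30-s window (~0.033 Hz) would
    otherwise quantize the reported rate far too coarsely.  No taper is
    applied by default; pass any ``scipy.signal.get_window`` name to taper.
    """
    x = window.trace.samples.astype(float)
    x = x - x.mean()
    if not np.any(np.abs(x) > 0):
        raise NoSignalError("window is constant: no oscillatory signal")
    if taper is not None:
        x = x * scipy.signal.get_window(taper, x.size)
    dt = window.trace.dt
    n_fft = scipy.fft.next_fast_len(max(x.size, int(np.ceil(1.0 / (grid_hz * dt)))))
    mag = np.abs(scipy.fft.rfft(x, n_fft))
    freqs = scipy.fft.rfftfreq(n_fft, dt)
    lo, hi = window.band
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise InvalidParameterError("frequency band contains no FFT bins")
    band_mag = mag[mask]
    peak = band_mag.max()
    if peak <= 1e-9 * x.size:
        raise NoSignalError("no spectral peak above the numerical floor")
    return float(freqs[mask][int(np.argmax(band_mag))])


def respiration_rate(freq: float) -> float:
    """Convert a breath frequency in Hz to breaths/minute (exactly 60x)."""
    if freq < 0:
        raise InvalidParameterError("frequency must be >= 0")
    return 60.0 * freq


def peak_output_voltage(window: AnalysisWindow,
                        prominence_frac: float = 0.2,
                        summary: str = "mean") -> float:
    """Mean per-breath peak height above the window baseline (volts).

    Positive peaks are detected with a minimum separation of 0.5/f_hi
    seconds and a minimum prominence of ``prominence_frac`` times the
    window's maximum absolute value.  Heights are measured from the window
    minimum, which makes the result invariant to any additive offset (the
    median removed upstream shifts the whole window).  ``summary`` selects
    the mean (default, robust to one outlier breath) or the max peak.
    """
    x = window.trace.samples
    scale = float(np.max(np.abs(x)))
    if scale == 0:
        raise NoSignalError("all-zero window: no breath peaks")
    dt = window.trace.dt
    min_sep = max(1, int(round((0.5 / window.band[1]) / dt)))
    peaks, _ = scipy.signal.find_peaks(x, distance=min_sep,
                                       prominence=prominence_frac * scale)
    if peaks.size == 0:
        raise NoSignalError("no peaks found above the prominence threshold")
    heights = x[peaks] - x.min()
    if summary == "mean":
        return float(heights.mean())
    if summary == "max":
        return float(heights.max())
    raise InvalidParameterError(f"unknown summary {summary!r}; use 'mean' or 'max'")


def extract_features(session: SleepSession, window_length: float = 30.0,
                     band: tuple[float, float] = DEFAULT_BAND,
                     grid_hz: float = DEFAULT_GRID_HZ,
                     peak_summary: str = "mean") -> list[FeatureVector]:
    """One (rate, voltage) feature per window of a whole night.

    The session's epochs are concatenated, the acquisition offset removed,
    the trace segmented, and each window reduced to its respiration rate
    and peak output voltage.  Each window inherits the stage of the epoch
    containing its midpoint.  A window with no usable signal raises
    :class:`FeatureExtractionError` carrying the window index.
    """
    if not session.epochs:
        return []
    clean = remove_offset(session.concatenated())
    features = []
    for idx, window in enumerate(segment_windows(clean, window_length, band)):
        try:
            rate = respiration_rate(dominant_frequency(window, grid_hz))
            volt = peak_output_voltage(window, summary=peak_summary)
        except NoSignalError as exc:
            raise FeatureExtractionError(idx, str(exc)) from exc
        midpoint = window.trace.start_time + window.trace.duration / 2
        features.append(FeatureVector(rate, volt, session.stage_at(midpoint)))
    return features
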