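"""Feature extraction from the four physiological channels.

The four features driving the sonification are:

* windowed mean skin conductance (EDA level, μS, 0.25-s windows),
* instantaneous skin temperature (°C, nearest-sample lookup),
* the interbeat interval of the blood volume pulse, averaged over a sliding
  window of four heart periods (s), and
* the duration of each exhalation, read as the peak-to-trough interval of the
  respiration signal (s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .errors import (
    InsufficientBeatsError,
    InsufficientSamplesError,
    NoBeatsError,
    NoBreathsError,
    ValidationError,
)
from .physio_io import PhysioRecording
from .preprocess import PreprocessConfig, lowpass_filter, window_mean

FEATURE_KINDS = ("eda_level", "temp_sample", "ibi", "exhalation")

#: physiological heart-period bounds in seconds
IBI_BOUNDS_S = (0.25, 2.0)


@dataclass
class FeatureSeries:
    """Timestamped feature values for one channel."""

    kind: str
    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValidationError("times_s and values must be 1-D vectors of equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("times_s must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if self.kind in ("ibi", "exhalation") and self.times_s.size and np.any(self.values <= 0):
            raise ValidationError(f"{self.kind} values must be positive durations")

    def __len__(self) -> int:
        return self.times_s.size

    def latest_at(self, t: float, default: float | None = None) -> float:
        """Value of the most recent sample at or before time ``t``."""
        idx = np.searchsorted(self.times_s, t, side="right") - 1
        if idx < 0:
            if default is not None:
                return default
            return float(self.values[0])
        return float(self.values[idx])


@dataclass
class BeatTrain:
    """Heartbeat event times detected from the blood volume pulse."""

    beat_times_s: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=np.float64)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValidationError("beat times must be strictly increasing")
        if self.beat_times_s.size >= 2:
            diffs = np.diff(self.beat_times_s)
            lo, hi = IBI_BOUNDS_S
            if np.any((diffs < lo) | (diffs > hi)):
                flag = f"interbeat intervals outside physiological bounds [{lo}, {hi}] s"
                if flag not in self.flags:
                    self.flags.append(flag)

    def __len__(self) -> int:
        return self.beat_times_s.size


def extract_eda_levels(rec: PhysioRecording, cfg=None) -> FeatureSeries:
    """Windowed mean skin conductance, one value per non-overlapping window."""
    from .sonify import SonifyConfig

    cfg = cfg or SonifyConfig()
    eda = rec.require_channel("eda")
    return window_mean(eda, rec.sampling_rate_hz, cfg.eda_window_s, kind="eda_level")


def detect_beats(
    bvp: np.ndarray,
    sampling_rate_hz: float,
    *,
    mad_k: float = 4.0,
    rolling_window_s: float = 2.0,
    refractory_s: float = 0.25,
    edge_guard_s: float = 0.5,
    filter_cutoff_hz: float = 8.0,
) -> BeatTrain:
    """Detect heartbeat times as local maxima of the filtered pulse waveform.

    The waveform is low-pass filtered (zero-phase, 8 Hz — well above any
    plausible heart rate, well below motion/noise), then peaks are kept when
    they exceed an adaptive threshold of rolling median + ``mad_k`` x rolling
    MAD and are separated by at least the refractory period.  Beats within
    ``edge_guard_s`` of either end are discarded as unreliable.
    """
    x = np.asarray(bvp, dtype=np.float64)
    if x.size < 2 * sampling_rate_hz:
        raise InsufficientSamplesError("insufficient-samples: need >= 2 s of BVP signal")
    filt = lowpass_filter(x, sampling_rate_hz, PreprocessConfig(butterworth_order=4, cutoff_hz=filter_cutoff_hz))

    win = int(round(rolling_window_s * sampling_rate_hz)) | 1  # odd
    med = ndimage.median_filter(filt, size=win, mode="nearest")
    mad = ndimage.median_filter(np.abs(filt - med), size=win, mode="nearest")
    threshold = med + mad_k * mad

    peaks, _ = sps.find_peaks(filt, distance=max(1, int(round(refractory_s * sampling_rate_hz))))
    peaks = peaks[filt[peaks] > threshold[peaks]]
    times = peaks / sampling_rate_hz
    duration = x.size / sampling_rate_hz
    times = times[(times >= edge_guard_s) & (times <= duration - edge_guard_s)]
    if times.size == 0:
        raise NoBeatsError("no-beats: BVP signal is flat or unphysiological")
    return BeatTrain(beat_times_s=times)


def average_ibi(beats: BeatTrain, n_periods: int = 4) -> FeatureSeries:
    """Sliding mean of the last ``n_periods`` interbeat differences.

    One value is emitted at each beat time from the ``(n_periods + 1)``-th
    beat onward.  The output is invariant to uniform time translation of the
    beat train.
    """
    if n_periods < 1:
        raise ValidationError(f"n_periods must be >= 1, got {n_periods}")
    t = beats.beat_times_s
    if t.size < n_periods + 1:
        raise InsufficientBeatsError(
            f"insufficient-beats: need >= {n_periods + 1} beats, got {t.size}"
        )
    diffs = np.diff(t)
    kernel = np.ones(n_periods) / n_periods
    means = np.convolve(diffs, kernel, mode="valid")
    return FeatureSeries(kind="ibi", times_s=t[n_periods:], values=means)


def _alternating_extrema(
    peak_idx: np.ndarray, trough_idx: np.ndarray, values: np.ndarray
) -> list[tuple[int, bool]]:
    """Merge peak/trough indices into a strictly alternating sequence.

    Between consecutive troughs the highest candidate peak is kept, and
    conversely the lowest of consecutive troughs, so the sequence alternates
    peak, trough, peak, ...
    """
    events = [(int(i), True) for i in peak_idx] + [(int(i), False) for i in trough_idx]
    events.sort()
    out: list[tuple[int, bool]] = []
    for idx, is_peak in events:
        if out and out[-1][1] == is_peak:
            prev_idx = out[-1][0]
            better = values[idx] > values[prev_idx] if is_peak else values[idx] < values[prev_idx]
            if better:
                out[-1] = (idx, is_peak)
        else:
            out.append((idx, is_peak))
    return out


def _refine_extremum(x: np.ndarray, idx: int, half_window: int) -> float:
    """Sub-sample extremum location by a local cubic least-squares fit.

    Respiration extrema are locally flat, so the raw argmax is noise-limited;
    fitting a low-order polynomial over a wider neighbourhood averages the
    noise.  A cubic (rather than a parabola) also absorbs the asymmetry left
    by a breathing period that drifts across the window, which would
    otherwise bias the vertex by a few samples.
    """
    i0 = max(0, idx - half_window)
    i1 = min(x.size, idx + half_window + 1)
    xs = np.arange(i0, i1, dtype=np.float64) - idx
    c = np.polynomial.polynomial.polyfit(xs, x[i0:i1], 3)
    # stationary points of c1 + 2 c2 x + 3 c3 x^2
    roots = np.roots([3 * c[3], 2 * c[2], c[1]]) if c[3] != 0 else (
        np.array([-c[1] / (2 * c[2])]) if c[2] != 0 else np.array([])
    )
    roots = np.real(roots[np.abs(np.imag(roots)) < 1e-9]) if roots.size else roots
    roots = roots[np.abs(roots) <= half_window]
    if roots.size == 0:  # ill-conditioned fit; keep the raw argmax
        return float(idx)
    return float(idx) + float(roots[np.argmin(np.abs(roots))])


def detect_exhalations(
    resp: np.ndarray,
    sampling_rate_hz: float,
    *,
    smooth_s: float = 0.25,
    min_separation_s: float = 0.5,
    prominence_iqr_frac: float = 0.10,
    refine_window_s: float = 0.5,
) -> FeatureSeries:
    """Exhalation durations as peak-to-trough intervals of the respiration signal.

    The signal is smoothed with a 0.25-s moving average, then peaks and
    troughs with prominence of at least 10% of the signal interquartile range
    and minimum separation 0.5 s are paired into alternating peak → trough
    events, with each extremum refined to sub-sample precision by a local
    quadratic fit.  Each pair yields one feature value: timestamp = peak
    time, value = trough time − peak time.
    """
    x = np.asarray(resp, dtype=np.float64)
    if x.size < 4 * sampling_rate_hz:
        raise InsufficientSamplesError("insufficient-samples: need >= 4 s of respiration signal")
    w = max(1, int(round(smooth_s * sampling_rate_hz))) | 1  # odd, symmetric
    smoothed = ndimage.uniform_filter1d(x, size=w, mode="nearest")

    q75, q25 = np.percentile(smoothed, [75, 25])
    prominence = prominence_iqr_frac * (q75 - q25)
    if prominence <= 0:
        raise NoBreathsError("no-breaths: respiration signal is flat")
    distance = max(1, int(round(min_separation_s * sampling_rate_hz)))
    peak_idx, _ = sps.find_peaks(smoothed, prominence=prominence, distance=distance)
    trough_idx, _ = sps.find_peaks(-smoothed, prominence=prominence, distance=distance)
    seq = _alternating_extrema(peak_idx, trough_idx, smoothed)

    # refinement window: wide for noise averaging, but clear of neighbours
    half_max = max(3, int(round(refine_window_s * sampling_rate_hz)))
    refined = []
    for k, (i, is_peak) in enumerate(seq):
        gaps = []
        if k > 0:
            gaps.append(i - seq[k - 1][0])
        if k < len(seq) - 1:
            gaps.append(seq[k + 1][0] - i)
        half = min(half_max, max(3, int(0.35 * min(gaps)))) if gaps else half_max
        refined.append(_refine_extremum(smoothed, i, half) / sampling_rate_hz)

    times, values = [], []
    for k, ((_, i_peak), (_, j_peak)) in enumerate(zip(seq, seq[1:])):
        if i_peak and not j_peak and refined[k + 1] > refined[k]:
            times.append(refined[k])
            values.append(refined[k + 1] - refined[k])
    if not times:
        raise NoBreathsError("no-breaths: fewer than one peak-trough pair found")
    return FeatureSeries(kind="exhalation", times_s=np.array(times), values=np.array(values))


def sample_temperature(rec: PhysioRecording, times_s: np.ndarray) -> FeatureSeries:
    """Instantaneous skin temperature by nearest-sample lookup.

    "Instantaneous" is read as nearest sample, not interpolation; the
    difference is at most one sample period.
    """
    temp = rec.require_channel("temp")
    t = np.asarray(times_s, dtype=np.float64)
    if t.size and (t.min() < 0 or t.max() > rec.duration_s):
        raise ValidationError(
            f"requested times span [{t.min()}, {t.max()}] outside recording [0, {rec.duration_s}]"
        )
    idx = np.clip(np.round(t * rec.sampling_rate_hz).astype(int), 0, temp.size - 1)
    return FeatureSeries(kind="temp_sample", times_s=t, values=temp[idx])
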