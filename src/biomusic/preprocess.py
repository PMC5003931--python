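"""Signal conditioning: anti-alias low-pass filtering and window averaging.

The acquisition chain this package emulates low-pass filters every channel
with a 5th-order Butterworth before sampling at 256 Hz.  Here the filter is
re-applied in software (zero-phase, forward-backward) so the pipeline is
self-sufficient on raw synthetic signals; the default 40 Hz cutoff sits above
all physiological content of interest and below the Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientSamplesError, ValidationError


@dataclass
class PreprocessConfig:
    butterworth_order: int = 5
    cutoff_hz: float = 40.0
    #: channels the low-pass is applied to by default; EDA and temperature are
    #: slow signals whose windowed/instantaneous features do not need it.
    channels: tuple[str, ...] = ("bvp", "resp")

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ValidationError(f"butterworth_order must be >= 1, got {self.butterworth_order}")
        if self.cutoff_hz <= 0:
            raise ValidationError(f"cutoff_hz must be positive, got {self.cutoff_hz}")


def lowpass_filter(
    signal: np.ndarray,
    sampling_rate_hz: float,
    cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a sample vector.

    Forward-backward application (``sosfiltfilt``) doubles the magnitude
    roll-off and cancels phase shift, so event timing (beats, exhalation
    peaks) is not lagged.  DC is preserved.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(signal, dtype=np.float64)
    nyquist = sampling_rate_hz / 2.0
    if cfg.cutoff_hz >= nyquist:
        raise ValidationError(
            f"cutoff {cfg.cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if x.size <= 3 * cfg.butterworth_order:
        raise InsufficientSamplesError(
            f"insufficient-samples: need > {3 * cfg.butterworth_order} samples, got {x.size}"
        )
    sos = sps.butter(cfg.butterworth_order, cfg.cutoff_hz, btype="low", fs=sampling_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def window_mean(signal: np.ndarray, sampling_rate_hz: float, window_s: float, kind: str = "eda_level"):
    """Non-overlapping window averages of a signal.

    Returns a :class:`~biomusic.features.FeatureSeries` with one value per
    contiguous window of ``window_s`` seconds (``floor(n / window_samples)``
    values), each the arithmetic mean of its window and timestamped at the
    window start.  A trailing partial window is dropped.
    """
    from .features import FeatureSeries  # local import to avoid a module cycle

    x = np.asarray(signal, dtype=np.float64)
    w = int(round(window_s * sampling_rate_hz))
    if w < 1:
        raise ValidationError(
            f"window_s * sampling_rate_hz must be >= 1, got {window_s} s at {sampling_rate_hz} Hz"
        )
    n_windows = x.size // w
    if n_windows < 1:
        raise InsufficientSamplesError(
            f"insufficient-samples: need >= {w} samples for one {window_s}-s window, got {x.size}"
        )
    means = x[: n_windows * w].reshape(n_windows, w).mean(axis=1)
    times = np.arange(n_windows) * (w / sampling_rate_hz)
    return FeatureSeries(kind=kind, times_s=times, values=means)
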