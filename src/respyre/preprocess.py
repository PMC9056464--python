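"""Pre-processing: missing-sample interpolation, band-pass filtering,
peak enhancement and Hampel outlier removal.

Two filter branches are used downstream: the respiratory band
(0.1-0.4 Hz, i.e. 6-24 breaths/min) yields the slow waveform whose
amplitude range feeds the post-processing scaling, while peak detection
runs on a cardiac band (0.5-3.5 Hz) where the pulse train actually lives.
Both are zero-phase Butterworth filters so that peak timing — which the
RR-interval spectral estimate depends on — is not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError

__all__ = [
    "PreprocessConfig",
    "interpolate_missing",
    "bandpass",
    "enhance_peaks",
    "hampel_filter",
]

#: MAD -> sigma consistency constant for the normal distribution.
MAD_TO_SIGMA = 1.4826


@dataclass
class PreprocessConfig:
    """Filter bands, peak-enhancement range and Hampel settings.

    ``band_low_hz``/``band_high_hz`` bound the physiological respiratory
    band; ``rb`` and ``l_lt`` are the enhancement output range and lower
    limit (defaults 1024 and 0).  ``hampel_half_window`` of 3 reproduces
    the classic 7-point (sample + 3 per side) sliding window.
    """

    band_low_hz: float = 0.1
    band_high_hz: float = 0.4
    cardiac_low_hz: float = 0.5
    cardiac_high_hz: float = 3.5
    filter_order: int = 2
    rb: float = 1024.0
    l_lt: float = 0.0
    hampel_half_window: int = 3
    hampel_n_sigma: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ConfigError("need 0 < band_low_hz < band_high_hz")
        if not (0 < self.cardiac_low_hz < self.cardiac_high_hz):
            raise ConfigError("need 0 < cardiac_low_hz < cardiac_high_hz")
        if self.rb <= 0:
            raise ConfigError("rb must be > 0")
        if self.hampel_half_window < 1:
            raise ConfigError("hampel_half_window must be >= 1")


def interpolate_missing(samples: np.ndarray) -> np.ndarray:
    """Fill missing (NaN) samples.

    An isolated missing sample becomes the mean of its two neighbours; a
    run of consecutive missing samples is filled by linear interpolation
    between the bounding valid values; leading/trailing runs take the
    nearest valid value.  Length is unchanged and the output contains no
    missing values.
    """
    x = np.asarray(samples, dtype=float).copy()
    valid = ~np.isnan(x)
    if x.size == 0 or not valid.any():
        raise DataError("cannot interpolate: no valid samples")
    if valid.all():
        return x
    idx = np.arange(x.size)
    x[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return x


def bandpass(
    samples: np.ndarray,
    fs: float,
    low_hz: float,
    high_hz: float,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, so the effective
    attenuation is that of a filter of twice the nominal order)."""
    x = np.asarray(samples, dtype=float)
    if np.isnan(x).any():
        raise DataError("bandpass input contains missing values")
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ConfigError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={fs} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                     output="sos")
    # pad conservatively; short windows at very low cut-offs otherwise ring
    padlen = min(x.size - 1, 3 * int(fs / low_hz))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def enhance_peaks(samples: np.ndarray, rb: float = 1024.0,
                  l_lt: float = 0.0) -> np.ndarray:
    """Affine rescaling ``rb * (x - min) / range + l_lt``.

    Maps the window onto [l_lt, l_lt + rb]; strictly order-preserving, so
    peak locations are unchanged while the dynamic range becomes uniform
    across windows.
    """
    x = np.asarray(samples, dtype=float)
    rng = float(np.max(x) - np.min(x))
    if rng <= 0 or not np.isfinite(rng):
        raise DataError("cannot enhance a constant (zero-range) signal")
    return rb * (x - np.min(x)) / rng + l_lt


def hampel_filter(
    samples: np.ndarray,
    half_window: int = 3,
    n_sigma: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window Hampel outlier replacement.

    The signal is extended at the end by ``half_window`` samples equal to
    the overall mean, so the final samples still see a full right-hand
    neighbourhood; at the start the window is simply truncated.  For each
    sample the window median and the MAD-based robust sigma
    (1.4826 * MAD) are computed; samples deviating from the median by more
    than ``n_sigma`` sigmas are replaced by the median.

    Returns the filtered signal (same length) and the indices replaced.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n <= 2 * half_window:
        raise DataError(
            f"signal of length {n} too short for half_window={half_window}"
        )
    padded = np.concatenate([x, np.full(half_window, np.mean(x))])
    medians = np.empty(n)
    sigmas = np.empty(n)
    # truncated windows at the start edge
    for i in range(min(half_window, n)):
        win = padded[: i + half_window + 1]
        medians[i] = np.median(win)
        sigmas[i] = np.median(np.abs(win - medians[i]))
    # full-width windows, vectorised
    if n > half_window:
        wins = np.lib.stride_tricks.sliding_window_view(
            padded, 2 * half_window + 1
        )
        medians[half_window:] = np.median(wins, axis=1)
        sigmas[half_window:] = np.median(
            np.abs(wins - medians[half_window:, None]), axis=1
        )
    sigmas *= MAD_TO_SIGMA
    mask = np.abs(x - medians) > n_sigma * sigmas
    out = np.where(mask, medians, x)
    return out, np.flatnonzero(mask).astype(np.int64)
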