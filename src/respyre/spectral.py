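"""Respiratory-rate extraction from the RR-interval series.

Respiratory sinus arrhythmia modulates beat-to-beat intervals at the
breathing frequency, so the RR sequence carries a spectral line inside the
physiological respiratory band (0.1-0.4 Hz).  The RR series is unevenly
spaced in time (one value per beat), so it is first resampled onto a
uniform grid, then a Welch power spectral density is computed with
Hann-tapered, 50 %-overlapping segments (density scaling, mean averaging,
FFT zero-padded to the full series length).  The estimated rate is the
frequency of the in-band PSD maximum times 60.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import ConfigError, DataError
from .io import RRSeries, SpectralEstimate

__all__ = [
    "WelchConfig",
    "EstimationFailure",
    "resample_rr",
    "welch_psd",
    "respr_from_psd",
]


class EstimationFailure(DataError):
    """The spectral estimate could not be formed for this window."""


@dataclass
class WelchConfig:
    """Welch PSD settings for the resampled RR series.

    The RR sequence is resampled to ``resample_hz`` (4 Hz comfortably
    covers the 0.4 Hz upper band edge).  Segments are
    ``nperseg_fraction`` of the series with ``overlap_fraction`` overlap,
    Hann-tapered; each segment's FFT is zero-padded to the full series
    length (never below ``nfft_floor``) to refine the frequency grid.
    """

    resample_hz: float = 4.0
    window_fn: str = "hann"
    overlap_fraction: float = 0.5
    nperseg_fraction: float = 0.5
    nfft_floor: int = 256
    band_low_hz: float = 0.1
    band_high_hz: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.overlap_fraction < 1):
            raise ConfigError("overlap_fraction must be in (0, 1)")
        if not (0 < self.nperseg_fraction <= 1):
            raise ConfigError("nperseg_fraction must be in (0, 1]")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ConfigError("invalid respiratory band")


def resample_rr(rr: RRSeries, resample_hz: float = 4.0) -> np.ndarray:
    """Uniformly resample the RR sequence and remove its mean.

    Each interval is placed at the time of the beat that closes it; a cubic
    spline through these points is evaluated on a uniform grid spanning the
    beat times.  Mean removal detrends the series so the PSD is not
    dominated by the DC bin.
    """
    if rr.rr_ms.size < 4:
        raise EstimationFailure(
            f"only {rr.rr_ms.size} RR intervals; need at least 4"
        )
    t = rr.peak_times_s[1:]  # interval k ends at peak k+1
    spline = CubicSpline(t, rr.rr_ms)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    series = spline(grid)
    return series - np.mean(series)


def welch_psd(series: np.ndarray, fs: float,
              cfg: WelchConfig | None = None) -> SpectralEstimate:
    """Welch power spectral density of a uniform series."""
    cfg = cfg or WelchConfig()
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise EstimationFailure(f"series of length {n} too short for Welch")
    nperseg = max(8, int(round(cfg.nperseg_fraction * n)))
    nperseg = min(nperseg, n)
    noverlap = int(cfg.overlap_fraction * nperseg)
    nfft = max(n, cfg.nfft_floor, nperseg)
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window=cfg.window_fn,
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        scaling="density",
        average="mean",
    )
    return SpectralEstimate(freqs=freqs, psd=psd)


def respr_from_psd(
    spec: SpectralEstimate,
    band_low_hz: float = 0.1,
    band_high_hz: float = 0.4,
) -> float:
    """Respiratory rate (breaths/min) from the in-band PSD maximum.

    Only bins inside [band_low_hz, band_high_hz] compete; ties break to the
    lowest frequency.  The result is therefore confined to
    [band_low_hz*60, band_high_hz*60] by construction.
    """
    in_band = (spec.freqs >= band_low_hz) & (spec.freqs <= band_high_hz)
    if not in_band.any():
        raise EstimationFailure("spectrum has no bins in the respiratory band")
    f = spec.freqs[in_band]
    p = spec.psd[in_band]
    return float(f[int(np.argmax(p))] * 60.0)
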