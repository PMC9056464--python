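"""Systolic-peak analysis: clipped-signal repair, moving-average/ROI peak
detection, false-peak rejection and RR-interval statistics.

Peak detection follows the moving-average intersection scheme: a moving
average of the (peak-enhanced) signal is elevated by a percentage of the
signal's amplitude range, regions of interest (ROIs) are the maximal runs
where the signal exceeds that threshold, and each ROI contributes one peak
at its maximum.  Because no single elevation suits every signal, a sweep of
candidate percentages is scored by the regularity (standard deviation) of
the implied RR intervals, restricted to physiologically plausible mean
rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, DataError
from .io import RRSeries

__all__ = [
    "PeakDetectConfig",
    "DetectionFailure",
    "repair_clipping",
    "detect_peaks",
    "reject_false_peaks",
    "rr_series",
    "heart_rate_bpm",
]


class DetectionFailure(DataError):
    """No acceptable peak set could be found in the window."""


@dataclass
class PeakDetectConfig:
    """Moving-average peak detection settings.

    ``raise_percentages`` are the candidate threshold elevations, in percent
    of the signal's amplitude range; the sweep keeps candidates whose mean
    rate falls in [bpm_min, bpm_max] and picks the one with the most regular
    RR intervals.  A run of at least ``clip_run_min`` samples at the global
    maximum is treated as sensor saturation.  An RR interval shorter than
    ``false_peak_fraction`` of the mean RR marks a false peak.
    """

    ma_window_s: float = 0.75
    raise_percentages: tuple = (5, 10, 15, 20, 25, 30, 35, 40)
    bpm_min: float = 40.0
    bpm_max: float = 180.0
    clip_run_min: int = 3
    false_peak_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.ma_window_s <= 0:
            raise ConfigError("ma_window_s must be > 0")
        if not (0 < self.false_peak_fraction < 1):
            raise ConfigError("false_peak_fraction must be in (0, 1)")


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open (start, end)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def repair_clipping(
    samples: np.ndarray,
    clip_run_min: int = 3,
    n_anchors: int = 3,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Restore saturated (ceiling-clipped) spans by cubic-spline interpolation.

    A clipped span is a run of at least ``clip_run_min`` consecutive samples
    at the signal's global maximum (within 1e-9 relative).  Each span is
    replaced by a cubic spline fitted through ``n_anchors`` non-clipped
    samples on each side, so the restored apex can exceed the saturation
    ceiling.  Samples outside the reported spans are returned untouched.
    """
    x = np.asarray(samples, dtype=float).copy()
    if x.size == 0:
        return x, []
    gmax = np.nanmax(x)
    tol = 1e-9 * max(1.0, abs(gmax))
    at_max = x >= gmax - tol
    spans = [(s, e) for s, e in _runs_of(at_max) if e - s >= clip_run_min]
    repaired_spans = []
    for s, e in spans:
        left = np.arange(max(0, s - n_anchors), s)
        right = np.arange(e, min(x.size, e + n_anchors))
        if left.size == 0 and right.size == 0:
            raise DataError(
                "clipped run spans the whole signal; nothing to anchor the "
                "spline on"
            )
        if left.size == 0 or right.size == 0:
            # run touches one signal end: extrapolating a spline from a
            # single side is unstable, leave the run as-is
            continue
        anchors = np.concatenate([left, right])
        spline = CubicSpline(anchors, x[anchors])
        x[s:e] = spline(np.arange(s, e))
        repaired_spans.append((int(s), int(e)))
    return x, repaired_spans


def _peaks_for_threshold(
    x: np.ndarray, threshold: np.ndarray
) -> np.ndarray:
    """One peak (earliest argmax) per maximal run where x > threshold."""
    rois = _runs_of(x > threshold)
    peaks = [s + int(np.argmax(x[s:e])) for s, e in rois]
    return np.asarray(peaks, dtype=np.int64)


def detect_peaks(
    samples: np.ndarray,
    fs: float,
    cfg: Optional[PeakDetectConfig] = None,
) -> np.ndarray:
    """Detect systolic peaks via the elevated moving-average sweep.

    Raises :class:`DetectionFailure` when no elevation yields at least two
    peaks at a plausible mean rate; the pipeline turns that into a skipped
    window rather than an error.
    """
    cfg = cfg or PeakDetectConfig()
    x = np.asarray(samples, dtype=float)
    ma_len = max(1, int(round(cfg.ma_window_s * fs)))
    if x.size < 2 * ma_len:
        raise DetectionFailure(
            f"window of {x.size} samples too short for a "
            f"{cfg.ma_window_s} s moving average"
        )
    rng = float(np.max(x) - np.min(x))
    if rng <= 0:
        raise DetectionFailure("flat signal: no region of interest")
    ma = uniform_filter1d(x, size=ma_len, mode="nearest")

    best: Optional[np.ndarray] = None
    best_sd = np.inf
    for p in cfg.raise_percentages:
        peaks = _peaks_for_threshold(x, ma + rng * p / 100.0)
        if peaks.size < 2:
            continue
        rr_s = np.diff(peaks) / fs
        bpm = 60.0 / float(np.mean(rr_s))
        if not (cfg.bpm_min <= bpm <= cfg.bpm_max):
            continue
        sd = float(np.std(rr_s))
        if sd < best_sd:
            best_sd = sd
            best = peaks
    if best is None:
        raise DetectionFailure(
            "no threshold elevation produced a plausible peak train"
        )
    return best


def reject_false_peaks(
    peak_indices: Sequence[int],
    fs: float,
    false_peak_fraction: float = 0.30,
) -> np.ndarray:
    """Drop false peaks by the 30 % rule.

    A peak pair whose interval is shorter than ``false_peak_fraction`` of
    the mean RR interval marks a false peak; the later peak of the pair is
    dropped and the intervals (and their mean) are recomputed before the
    rule is applied again, until no short interval remains.
    """
    peaks = list(np.asarray(peak_indices, dtype=np.int64))
    if len(peaks) < 2:
        raise DetectionFailure("need at least 2 peaks")
    while len(peaks) >= 2:
        rr = np.diff(peaks) / fs
        mean_rr = float(np.mean(rr))
        short = np.flatnonzero(rr < false_peak_fraction * mean_rr)
        if short.size == 0:
            break
        # drop the later peak of the first offending pair, then recompute
        del peaks[int(short[0]) + 1]
    if len(peaks) < 2:
        raise DetectionFailure("fewer than 2 peaks remain after rejection")
    return np.asarray(peaks, dtype=np.int64)


def rr_series(peak_indices: Sequence[int], fs: float) -> RRSeries:
    """Inter-beat intervals (ms) from strictly increasing peak indices."""
    return RRSeries.from_peaks(peak_indices, fs)


def heart_rate_bpm(rr: RRSeries) -> float:
    """Mean heart rate implied by the RR series: 60000 / mean(rr_ms)."""
    if rr.rr_ms.size == 0:
        raise DataError("empty RR series")
    return 60000.0 / float(np.mean(rr.rr_ms))
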