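"""Windowed end-to-end estimation and evaluation.

The record is cut into consecutive non-overlapping windows; each window
runs the full chain

    interpolate -> (ESQI gate) -> Hampel -> clip repair ->
    respiratory-band filter (amplitude range) ->
    cardiac-band filter -> peak enhancement -> peak detection ->
    false-peak rejection -> RR series -> resample -> Welch PSD ->
    in-band maximum x 60 -> amplitude scaling -> clamp

A window that fails quality gating or peak detection yields a skipped
estimate with a reason; it never aborts the other windows.  Clip repair and
the Hampel filter run on the interpolated raw signal: saturation plateaus
and single-sample spikes only exist as such before band-pass filtering,
which would smear them past the repair mechanisms' reach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .io import PPGRecord, RespEstimate, WindowSegment
from .peaks import (PeakDetectConfig, detect_peaks, reject_false_peaks,
                    repair_clipping, rr_series)
from .postprocess import ScalingConfig, amplitude_scale, clamp_physiological
from .preprocess import (PreprocessConfig, bandpass, enhance_peaks,
                         hampel_filter, interpolate_missing)
from .quality import esqi, gate_window
from .spectral import WelchConfig, resample_rr, respr_from_psd, welch_psd

__all__ = [
    "PipelineConfig",
    "EvalResult",
    "WINDOW_SWEEP_S",
    "segment",
    "estimate_record",
    "mae",
    "rmse",
    "pair_with_reference",
    "evaluate_record",
    "select_best_window",
]

logger = logging.getLogger("respyre")

#: Window sizes evaluated in the standard sweep, in seconds.
WINDOW_SWEEP_S = (10, 20, 30, 45, 60, 90, 120, 32, 64)


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    ``use_esqi`` enables entropy-quality gating; the ablation switches
    (``use_hampel``, ``use_clip_repair``, ``nan_policy``) exist so the
    contribution of each robustness stage can be measured.  ``nan_policy``
    is ``"interpolate"`` (default) or one of the naive alternatives it is
    meant to replace: ``"zero"`` (insert zeros) or ``"drop"`` (delete the
    missing samples, which compresses the time axis and corrupts beat
    timing).
    """

    window_s: float = 90.0
    use_esqi: bool = True
    use_hampel: bool = True
    use_clip_repair: bool = True
    nan_policy: str = "interpolate"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    peaks: PeakDetectConfig = field(default_factory=PeakDetectConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ConfigError("window_s must be > 0")
        if self.nan_policy not in ("interpolate", "zero", "drop"):
            raise ConfigError(
                "nan_policy must be 'interpolate', 'zero' or 'drop'")


@dataclass(frozen=True)
class EvalResult:
    """Windowed evaluation summary for one record and window size."""

    mae: float
    rmse: float
    n_windows: int
    n_skipped: int
    window_s: float


def segment(record: PPGRecord, window_s: float) -> list[WindowSegment]:
    """Consecutive non-overlapping windows from t=0; remainder discarded."""
    win = int(round(window_s * record.fs))
    if win <= 0:
        raise ConfigError("window_s too small for this sampling rate")
    n = len(record)
    if n < win:
        raise DataError(
            f"record of {n} samples shorter than one {window_s} s window"
        )
    return [
        WindowSegment(start_idx=k * win, end_idx=(k + 1) * win,
                      window_s=window_s, fs=record.fs)
        for k in range(n // win)
    ]


def _estimate_window(
    raw: np.ndarray, fs: float, seg: WindowSegment, cfg: PipelineConfig,
    keep_details: bool = False,
) -> RespEstimate:
    est = RespEstimate(window=seg)
    pp = cfg.preprocess

    # missing samples
    if np.isnan(raw).all():
        est.skipped, est.skip_reason = True, "all-missing"
        return est
    if cfg.nan_policy == "interpolate":
        x = interpolate_missing(raw)
    elif cfg.nan_policy == "zero":
        x = np.nan_to_num(raw, nan=0.0)
    else:  # "drop": delete missing samples, shifting everything after them
        x = raw[~np.isnan(raw)]

    # quality gating happens on the raw-scale signal, before any repair
    q = esqi(x)
    est.esqi = q.esqi
    if not gate_window(q, cfg.use_esqi):
        est.skipped, est.skip_reason = True, "esqi-undefined"
        return est

    try:
        # Hampel first: a surviving spike would masquerade as the global
        # maximum and hide genuine saturation plateaus from clip detection
        if cfg.use_hampel:
            x, _idx = hampel_filter(x, pp.hampel_half_window,
                                    pp.hampel_n_sigma)

        if cfg.use_clip_repair:
            x, _spans = repair_clipping(x, cfg.peaks.clip_run_min)

        resp_band = bandpass(x, fs, pp.band_low_hz, pp.band_high_hz,
                             pp.filter_order)
        resp_band_range = float(np.ptp(resp_band))

        cardiac = bandpass(x, fs, pp.cardiac_low_hz, pp.cardiac_high_hz,
                           pp.filter_order)
        enhanced = enhance_peaks(cardiac, pp.rb, pp.l_lt)
        peaks = detect_peaks(enhanced, fs, cfg.peaks)
        peaks = reject_false_peaks(peaks, fs, cfg.peaks.false_peak_fraction)
        rr = rr_series(peaks, fs)
        series = resample_rr(rr, cfg.welch.resample_hz)
        spec = welch_psd(series, cfg.welch.resample_hz, cfg.welch)
        respr_raw = respr_from_psd(spec, cfg.welch.band_low_hz,
                                   cfg.welch.band_high_hz)
    except DataError as exc:
        est.skipped = True
        est.skip_reason = getattr(exc, "reason", None) or type(exc).__name__
        logger.info("window at %.1f s skipped: %s", seg.start_s, exc)
        return est

    if keep_details:
        est.peaks = peaks + seg.start_idx
        est.spectrum = spec

    est.respr_raw = respr_raw
    scaled, scale = amplitude_scale(respr_raw, resp_band_range, seg.window_s,
                                    cfg.scaling)
    est.scale = scale
    est.scaled = scale != 1.0
    est.respr, est.clamped = clamp_physiological(
        scaled, cfg.scaling.clamp_min, cfg.scaling.clamp_max
    )
    return est


def estimate_record(
    record: PPGRecord, cfg: Optional[PipelineConfig] = None,
    keep_details: bool = False,
) -> list[RespEstimate]:
    """Run the full pipeline on every window of a record.

    With ``keep_details`` each estimate also carries the accepted peak
    indices (record-global, 0-based) and the window's spectral estimate.
    """
    cfg = cfg or PipelineConfig()
    segments = segment(record, cfg.window_s)
    out = []
    for seg in segments:
        raw = record.samples[seg.start_idx: seg.end_idx]
        out.append(_estimate_window(raw, record.fs, seg, cfg, keep_details))
    return out


def mae(ref: Sequence[float], est: Sequence[float]) -> float:
    """Mean absolute error between reference and estimated rates."""
    r = np.asarray(ref, dtype=float)
    e = np.asarray(est, dtype=float)
    if r.shape != e.shape or r.size == 0:
        raise DataError("mae needs equal-length, non-empty sequences")
    return float(np.mean(np.abs(r - e)))


def rmse(ref: Sequence[float], est: Sequence[float]) -> float:
    """Root-mean-square error between reference and estimated rates."""
    r = np.asarray(ref, dtype=float)
    e = np.asarray(est, dtype=float)
    if r.shape != e.shape or r.size == 0:
        raise DataError("rmse needs equal-length, non-empty sequences")
    return float(np.sqrt(np.mean((r - e) ** 2)))


def pair_with_reference(
    estimates: Sequence[RespEstimate], ref_resp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pair non-skipped window estimates with the reference series.

    Each window's reference is the mean of the reference samples whose
    timestamps fall within the window span; windows without any reference
    coverage are excluded.
    """
    ref_resp = np.asarray(ref_resp, dtype=float).reshape(-1, 2)
    if ref_resp.shape[0] == 0:
        raise DataError("empty reference series")
    refs, ests = [], []
    for e in estimates:
        if e.skipped or e.respr is None:
            continue
        t0 = e.window.start_s
        sel = (ref_resp[:, 0] >= t0) & (ref_resp[:, 0] < t0 + e.window.window_s)
        if not sel.any():
            continue
        refs.append(float(np.mean(ref_resp[sel, 1])))
        ests.append(e.respr)
    if not refs:
        raise DataError("no window could be paired with the reference")
    return np.asarray(refs), np.asarray(ests)


def evaluate_record(
    record: PPGRecord, cfg: Optional[PipelineConfig] = None
) -> EvalResult:
    """Estimate a record and score it against its reference series."""
    cfg = cfg or PipelineConfig()
    estimates = estimate_record(record, cfg)
    n_skipped = sum(e.skipped for e in estimates)
    ref, est = pair_with_reference(estimates, record.ref_resp)
    return EvalResult(mae=mae(ref, est), rmse=rmse(ref, est),
                      n_windows=len(estimates), n_skipped=n_skipped,
                      window_s=cfg.window_s)


def select_best_window(
    record: PPGRecord,
    cfg: Optional[PipelineConfig] = None,
    candidate_windows: Sequence[float] = WINDOW_SWEEP_S,
    calibration_value: Optional[float] = None,
) -> tuple[float, dict[float, EvalResult]]:
    """Pick the window size with minimal MAE (ties -> smaller window).

    By default the record's reference series is the comparison standard;
    alternatively a single user-entered ``calibration_value``
    (breaths/min, e.g. from counted regular breaths) is compared against
    every window's estimates.
    """
    from dataclasses import replace as _replace

    cfg = cfg or PipelineConfig()
    results: dict[float, EvalResult] = {}
    for w in candidate_windows:
        wcfg = _replace(cfg, window_s=float(w))
        try:
            if calibration_value is None:
                results[float(w)] = evaluate_record(record, wcfg)
            else:
                estimates = estimate_record(record, wcfg)
                vals = [e.respr for e in estimates
                        if not e.skipped and e.respr is not None]
                if not vals:
                    continue
                ref = np.full(len(vals), float(calibration_value))
                results[float(w)] = EvalResult(
                    mae=mae(ref, vals), rmse=rmse(ref, vals),
                    n_windows=len(estimates),
                    n_skipped=len(estimates) - len(vals),
                    window_s=float(w),
                )
        except DataError:
            continue
    if not results:
        raise DataError("no candidate window produced a valid evaluation")
    best = min(results, key=lambda w: (results[w].mae, w))
    return best, results
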