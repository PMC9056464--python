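"""Post-processing: amplitude-variation scaling and physiological clamp.

Respiratory-induced amplitude variation (RIAV) modulates PPG pulse height
with breathing, but the pre-processing branch that feeds peak detection
deliberately normalises amplitude away.  The post-processing stage therefore
applies a multiplicative correction driven by the amplitude range of the
respiratory-band signal within the window:

    scale = 1 + gain * (range / ref_range - 1) / window_s

With the default ``gain = 0`` the correction is the identity; ``gain`` and
``ref_range`` are meant to be set by :func:`calibrate_scaling` against
reference rates.  Finally the estimate is clamped to a physiologically
plausible interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError, ConfigError

__all__ = [
    "ScalingConfig",
    "amplitude_scale",
    "calibrate_scaling",
    "clamp_physiological",
]


@dataclass(frozen=True)
class ScalingConfig:
    """Amplitude-scaling and clamping parameters.

    ``ref_range`` is the reference amplitude range (in the units of the
    respiratory-band signal) at which the correction is neutral; ``gain``
    is its sensitivity (0 disables it).  ``clamp_min``/``clamp_max`` bound
    the final rate in breaths/min; 45 sits above the paediatric upper
    normal of 40.
    """

    enabled: bool = True
    ref_range: float = 1.0
    gain: float = 0.0
    clamp_min: float = 6.0
    clamp_max: float = 45.0

    def __post_init__(self) -> None:
        if not (self.clamp_min < self.clamp_max):
            raise ConfigError("clamp_min must be < clamp_max")
        if self.gain < 0:
            raise ConfigError("gain must be >= 0")
        if self.ref_range <= 0:
            raise ConfigError("ref_range must be > 0")


def amplitude_scale(
    respr_raw: float,
    resp_band_range: float,
    window_s: float,
    cfg: ScalingConfig,
) -> tuple[float, float]:
    """Apply the RIAV-driven multiplicative correction.

    Returns ``(scaled_rate, scale)``; with scaling disabled or gain 0 the
    scale is exactly 1.
    """
    if not cfg.enabled or cfg.gain == 0:
        return float(respr_raw), 1.0
    scale = 1.0 + cfg.gain * (resp_band_range / cfg.ref_range - 1.0) / window_s
    scale = max(scale, 0.0)
    return float(respr_raw * scale), float(scale)


def clamp_physiological(
    respr: float,
    clamp_min: float = 6.0,
    clamp_max: float = 45.0,
) -> tuple[float, bool]:
    """Limit the rate to [clamp_min, clamp_max]; flag when limiting occurs."""
    if respr < clamp_min:
        return float(clamp_min), True
    if respr > clamp_max:
        return float(clamp_max), True
    return float(respr), False


def calibrate_scaling(
    observations: Sequence[tuple[float, float, float, float]],
    cfg: ScalingConfig | None = None,
    gain_grid: np.ndarray | None = None,
) -> ScalingConfig:
    """Choose ``gain`` and ``ref_range`` by deterministic grid search.

    ``observations`` are ``(respr_raw, resp_band_range, window_s, ref_rate)``
    tuples collected from records with reference respiratory rates.  The
    grid minimises the MAE of the scaled-and-clamped estimates; ties break
    toward smaller gain (0 first), so when the raw estimates are already
    unbiased the identity is returned.
    """
    cfg = cfg or ScalingConfig()
    obs = [o for o in observations if o[0] is not None]
    if len(obs) == 0:
        raise CalibrationError("no (estimate, reference) pairs to calibrate on")
    raw = np.array([o[0] for o in obs])
    rng = np.array([o[1] for o in obs])
    win = np.array([o[2] for o in obs])
    ref = np.array([o[3] for o in obs])

    if gain_grid is None:
        gain_grid = np.linspace(0.0, 2.0, 21)
    # candidate neutral ranges: robust quantiles of what was observed
    positive = rng[rng > 0]
    if positive.size == 0:
        ref_range_grid = np.array([cfg.ref_range])
    else:
        ref_range_grid = np.unique(np.quantile(positive, [0.25, 0.5, 0.75]))

    best = (np.inf, 0.0, float(ref_range_grid[0]))
    for rr0 in ref_range_grid:
        for g in gain_grid:
            scale = 1.0 + g * (rng / rr0 - 1.0) / win
            est = np.clip(raw * np.maximum(scale, 0.0),
                          cfg.clamp_min, cfg.clamp_max)
            mae = float(np.mean(np.abs(est - ref)))
            if mae < best[0] - 1e-12:
                best = (mae, float(g), float(rr0))
    return replace(cfg, gain=best[1], ref_range=best[2])
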