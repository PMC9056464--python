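"""Synthetic PPG generator with known respiratory ground truth.

The generator emulates the two respiratory couplings the estimator relies
on: respiratory sinus arrhythmia (beat-to-beat intervals frequency-modulated
at the breathing frequency) and respiratory-induced amplitude variation
(pulse heights amplitude-modulated at the same frequency).  Beats render a
fixed asymmetric pulse template (fast systolic rise, slower decay,
~0.35 s wide); baseline wander, white noise, isolated spike outliers, NaN
dropouts and amplitude clipping can be layered on top.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError
from .io import PPGRecord

__all__ = ["SynthConfig", "SynthTruth", "generate", "make_fixture_suite"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``resp_hz`` is the breathing frequency (0.1-0.4 Hz is the physiological
    band); ``fm_depth`` is the fractional RR modulation (RSA) and
    ``am_depth`` the fractional pulse-amplitude modulation (RIAV).  Spike
    and dropout rates are expected events per minute; ``clip_level`` clips
    at an absolute amplitude while ``clip_quantile`` clips at a quantile of
    the rendered clean signal (e.g. 0.95 saturates the top 5 % of samples).
    """

    duration_s: float = 480.0
    fs: float = 125.0
    hr_bpm: float = 70.0
    resp_hz: float = 0.25
    fm_depth: float = 0.05
    am_depth: float = 0.2
    dc_offset: float = 2.0
    noise_sd: float = 0.05
    wander_amp: float = 0.3
    wander_hz: float = 0.05
    spike_rate: float = 0.0
    dropout_rate: float = 0.0
    dropout_len_s: float = 1.0
    clip_level: Optional[float] = None
    clip_quantile: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.hr_bpm <= 0:
            raise ConfigError("duration_s, fs and hr_bpm must be positive")
        if not (0 <= self.fm_depth <= 0.5 and 0 <= self.am_depth <= 0.5):
            raise ConfigError("fm_depth and am_depth must be in [0, 0.5]")
        if self.resp_hz <= 0:
            raise ConfigError("resp_hz must be positive")


@dataclass
class SynthTruth:
    """Ground truth of a generated record."""

    resp_hz: float
    beat_times: np.ndarray
    spike_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    dropout_spans: list = field(default_factory=list)
    clipped_spans: list = field(default_factory=list)

    @property
    def resp_brpm(self) -> float:
        return self.resp_hz * 60.0


def _pulse_template(fs: float, width_s: float = 0.35,
                    rise_s: float = 0.10) -> tuple[np.ndarray, int]:
    """Asymmetric positive pulse: two-sided Gaussian, fast rise, slow decay.

    Returns the template and the offset (in samples) of its maximum.
    """
    n = int(round(width_s * fs))
    t = np.arange(n) / fs
    s_rise = rise_s / 2.5
    s_fall = (width_s - rise_s) / 2.5
    tpl = np.where(
        t < rise_s,
        np.exp(-0.5 * ((t - rise_s) / s_rise) ** 2),
        np.exp(-0.5 * ((t - rise_s) / s_fall) ** 2),
    )
    return tpl, int(round(rise_s * fs))


def generate(config: SynthConfig) -> tuple[PPGRecord, SynthTruth]:
    """Generate a PPG record and its ground truth.

    Beat times are produced iteratively: the k-th interval is
    ``(60/hr_bpm) * (1 + fm_depth * sin(2*pi*resp_hz*t_k))``, and the pulse
    rendered at each beat is scaled by
    ``1 + am_depth * sin(2*pi*resp_hz*t_k)``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    base_interval = 60.0 / config.hr_bpm
    if config.duration_s < 2 * base_interval:
        raise ConfigError("duration too short to contain two beats")

    # iterative beat train with RSA frequency modulation
    beats = []
    t = 0.0
    while t < config.duration_s:
        beats.append(t)
        t += base_interval * (
            1.0 + config.fm_depth * np.sin(2 * np.pi * config.resp_hz * t)
        )
    beat_times = np.asarray(beats)

    tpl, peak_off = _pulse_template(config.fs)
    x = np.zeros(n)
    for tb in beat_times:
        amp = 1.0 + config.am_depth * np.sin(2 * np.pi * config.resp_hz * tb)
        start = int(round(tb * config.fs)) - peak_off
        a = max(start, 0)
        b = min(start + tpl.size, n)
        if b > a:
            x[a:b] += amp * tpl[a - start: b - start]

    x += config.dc_offset
    tt = np.arange(n) / config.fs
    wander_phase = rng.uniform(0, 2 * np.pi)
    x += config.wander_amp * np.sin(2 * np.pi * config.wander_hz * tt
                                    + wander_phase)
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, n)

    truth = SynthTruth(resp_hz=config.resp_hz, beat_times=beat_times)

    # isolated spike outliers: single-sample excursions of 5-10x the range
    if config.spike_rate > 0:
        n_spikes = rng.poisson(config.spike_rate * config.duration_s / 60.0)
        if n_spikes > 0:
            idx = rng.choice(n, size=min(n_spikes, n), replace=False)
            rng_x = np.ptp(x)
            mags = rng.uniform(5, 10, idx.size) * rng_x
            signs = rng.choice([-1.0, 1.0], idx.size)
            x[idx] += signs * mags
            truth.spike_indices = np.sort(idx).astype(np.int64)

    # clipping before dropouts so NaNs are never "clipped"
    clip_at = config.clip_level
    if clip_at is None and config.clip_quantile is not None:
        clip_at = float(np.quantile(x, config.clip_quantile))
    if clip_at is not None:
        over = x > clip_at
        x[over] = clip_at
        d = np.diff(over.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if over[0]:
            starts.insert(0, 0)
        if over[-1]:
            ends.append(n)
        truth.clipped_spans = [(int(s), int(e)) for s, e in zip(starts, ends)]

    if config.dropout_rate > 0:
        n_drop = rng.poisson(config.dropout_rate * config.duration_s / 60.0)
        drop_len = max(1, int(round(config.dropout_len_s * config.fs)))
        for _ in range(n_drop):
            s = int(rng.integers(0, max(1, n - drop_len)))
            x[s: s + drop_len] = np.nan
            truth.dropout_spans.append((s, s + drop_len))

    # reference series: the true (constant) respiratory rate at 1 Hz
    ref_t = np.arange(0, int(config.duration_s))
    ref = np.column_stack([ref_t, np.full(ref_t.size, config.resp_hz * 60.0)])
    rec = PPGRecord(samples=x, fs=config.fs,
                    subject_id=f"synth-seed{config.seed}", ref_resp=ref)
    return rec, truth


def make_fixture_suite(out_dir, base_seed: int = 20_000) -> list[Path]:
    """Write a fixed battery of records + truth sidecars to ``out_dir``.

    Ten clean records span 8-23 breaths/min; three artefact-laden variants
    (spikes, dropouts, clipping) are added on top.  Each record is a
    value-only CSV next to a ``.truth.txt`` key-value sidecar.  Re-running
    with the same seeds writes identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    resp_list = [8, 10, 12, 14, 15, 16, 18, 20, 22, 23]
    configs = [
        SynthConfig(duration_s=240, resp_hz=r / 60.0, hr_bpm=70,
                    seed=base_seed + i)
        for i, r in enumerate(resp_list)
    ]
    configs += [
        replace(configs[4], spike_rate=2.0, seed=base_seed + 100),
        replace(configs[4], dropout_rate=1.0, seed=base_seed + 101),
        replace(configs[4], clip_quantile=0.95, seed=base_seed + 102),
    ]
    for i, cfg in enumerate(configs):
        rec, truth = generate(cfg)
        stem = f"record_{i:02d}_resp{truth.resp_brpm:g}"
        csv_path = out_dir / f"{stem}.csv"
        np.savetxt(csv_path, rec.samples, fmt="%.6f")
        sidecar = out_dir / f"{stem}.truth.txt"
        sidecar.write_text(
            f"resp_brpm={truth.resp_brpm:.6f}\n"
            f"resp_hz={truth.resp_hz:.6f}\n"
            f"hr_bpm={cfg.hr_bpm:.6f}\n"
            f"fs={cfg.fs:.6f}\n"
            f"seed={cfg.seed}\n"
            f"n_beats={truth.beat_times.size}\n"
            f"n_spikes={truth.spike_indices.size}\n"
            f"n_dropouts={len(truth.dropout_spans)}\n"
            f"n_clipped_spans={len(truth.clipped_spans)}\n"
        )
        written += [csv_path, sidecar]
    return written
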