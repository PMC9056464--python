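"""Domain containers and CSV readers/writers.

The missing-value convention is uniform across the package: any cell that
does not parse as a number, any empty cell and any IEEE NaN all map to
``numpy.nan``, which every downstream stage treats as "missing".  Sample
indices are 0-based and index ranges are half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

__all__ = [
    "PPGRecord",
    "WindowSegment",
    "RRSeries",
    "SpectralEstimate",
    "RespEstimate",
    "read_ppg_csv",
    "read_bidmc_pair",
    "write_estimates_csv",
    "read_estimates_csv",
]

#: Column names tried (case-insensitively) for the PPG channel of a
#: BIDMC-style "Signals" file.  "PLETH" is the conventional label.
PPG_COLUMN_CANDIDATES = ("PLETH", "PPG", "PULSE", "PLETHYSMOGRAM")

#: Column names tried for the respiratory-rate channel of a "Numerics" file.
RESP_COLUMN_CANDIDATES = ("RESP", "RR", "RESPIRATORY RATE", "RESP RATE")


@dataclass
class PPGRecord:
    """A raw sampled PPG trace.

    Parameters
    ----------
    samples
        Sensor values in arbitrary units; ``nan`` marks a missing sample.
    fs
        Sampling frequency in Hz, strictly positive.
    start_time
        Offset of the first sample, in seconds.
    subject_id
        Opaque label used in file names and reports.
    ref_resp
        Optional reference respiratory rate as ``(time_s, breaths_per_min)``
        pairs with strictly increasing times (typically 1 Hz numerics).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    subject_id: str = ""
    ref_resp: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DataError("samples must be a non-empty 1-D sequence")
        if not (self.fs > 0):
            raise ConfigError(f"fs must be > 0, got {self.fs}")
        self.ref_resp = np.asarray(self.ref_resp, dtype=float).reshape(-1, 2)
        if self.ref_resp.shape[0] > 1 and not np.all(
            np.diff(self.ref_resp[:, 0]) > 0
        ):
            raise DataError("ref_resp times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class WindowSegment:
    """A half-open sample range ``[start_idx, end_idx)`` of a record."""

    start_idx: int
    end_idx: int
    window_s: float
    fs: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_idx < self.end_idx):
            raise DataError("window indices must satisfy 0 <= start < end")

    @property
    def start_s(self) -> float:
        return self.start_idx / self.fs

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class RRSeries:
    """Peak positions and the inter-beat intervals they imply.

    ``rr_ms[k] = (peak_indices[k+1] - peak_indices[k]) / fs * 1000``.
    """

    peak_indices: np.ndarray
    rr_ms: np.ndarray
    fs: float

    @classmethod
    def from_peaks(cls, peak_indices: Sequence[int], fs: float) -> "RRSeries":
        idx = np.asarray(peak_indices, dtype=np.int64)
        if idx.size < 2:
            raise DataError("need at least 2 peaks to form RR intervals")
        if not np.all(np.diff(idx) > 0):
            raise DataError("peak indices must be strictly increasing")
        rr_ms = np.diff(idx) / fs * 1000.0
        return cls(peak_indices=idx, rr_ms=rr_ms, fs=fs)

    @property
    def peak_times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs


@dataclass
class SpectralEstimate:
    """One-sided power spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise DataError("freqs and psd must have equal length")


@dataclass
class RespEstimate:
    """Per-window respiratory-rate estimate with quality/bookkeeping flags.

    ``peaks`` and ``spectrum`` are populated only when the pipeline is asked
    to keep details (diagnostics dumps); they are never serialised.
    """

    window: WindowSegment
    respr: Optional[float] = None
    respr_raw: Optional[float] = None
    esqi: Optional[float] = None
    scale: float = 1.0
    skipped: bool = False
    skip_reason: str = ""
    clamped: bool = False
    scaled: bool = False
    peaks: Optional[np.ndarray] = None
    spectrum: Optional["SpectralEstimate"] = None


# ---------------------------------------------------------------------------
# readers / writers


def _infer_fs_from_time(time_s: np.ndarray) -> float:
    """Median time step, with a 1 % uniformity check (robust to one bad stamp)."""
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise FormatError("time column is not strictly increasing")
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError("degenerate time column")
    # allow isolated glitches but not a genuinely non-uniform grid
    frac_bad = np.mean(np.abs(dt - med) > 0.01 * med)
    if frac_bad > 0.05:
        raise FormatError(
            "time column is not uniformly sampled (>5% of steps deviate "
            "from the median by more than 1%)"
        )
    return 1.0 / med


def read_ppg_csv(
    path,
    fs: Optional[float] = None,
    column: Optional[str] = None,
) -> PPGRecord:
    """Read a generic PPG CSV.

    Accepted layouts (header row optional):

    * two or more columns, the first being time in seconds — ``fs`` is
      inferred from the median time step unless given explicitly;
    * a single value column — ``fs`` must then be supplied.

    Unparseable or empty cells become the missing marker (NaN); no row is
    ever dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        rest = fh.read()

    def _is_number(tok: str) -> bool:
        tok = tok.strip()
        if not tok:
            return True  # empty cell = missing value, still a data row
        try:
            float(tok)
            return True
        except ValueError:
            return False

    first_tokens = first.strip().split(",")
    has_header = not all(_is_number(t) for t in first_tokens)
    text = rest if has_header else first + rest
    names = [t.strip() for t in first_tokens] if has_header else None
    df = pd.read_csv(
        _io.StringIO(text), header=None, names=names, skip_blank_lines=True
    )
    # coerce everything numeric; bad cells -> NaN (the missing marker)
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.shape[0] == 0:
        raise FormatError(f"{path} contains no data rows")

    time_col = None
    value_col = None
    if column is not None:
        if names is None:
            raise ConfigError("--column given but the file has no header row")
        lookup = {n.lower(): n for n in names}
        if column.lower() not in lookup:
            raise FormatError(
                f"column {column!r} not found; file has {names}"
            )
        value_col = lookup[column.lower()]
    if df.shape[1] >= 2:
        time_col = df.columns[0]
        if value_col is None:
            value_col = df.columns[1]
    else:
        if value_col is None:
            value_col = df.columns[0]

    if fs is None:
        if time_col is None:
            raise ConfigError(
                "single-column file: a sampling rate (fs) is required"
            )
        t = df[time_col].to_numpy(dtype=float)
        if np.isnan(t).any():
            raise FormatError("time column contains unparseable values")
        fs = _infer_fs_from_time(t)
        start_time = float(t[0])
    else:
        start_time = 0.0
        if time_col is not None:
            t = df[time_col].to_numpy(dtype=float)
            if not np.isnan(t).any():
                dt = np.diff(t)
                if np.any(dt <= 0):
                    raise FormatError("time column is not strictly increasing")
                start_time = float(t[0])

    samples = df[value_col].to_numpy(dtype=float)
    return PPGRecord(samples=samples, fs=float(fs), start_time=start_time,
                     subject_id=path.stem)


def read_bidmc_pair(
    signals_path,
    numerics_path=None,
    ppg_candidates: Sequence[str] = PPG_COLUMN_CANDIDATES,
    resp_candidates: Sequence[str] = RESP_COLUMN_CANDIDATES,
    fs: float = 125.0,
    numerics_fs: float = 1.0,
) -> PPGRecord:
    """Read a BIDMC-style "Signals"/"Numerics" CSV pair.

    The signals file holds one row per sample at 125 Hz with a header naming
    the channels; the PPG channel is located case-insensitively among
    ``ppg_candidates``.  The numerics file (optional) holds 1 Hz physiological
    parameters including a respiratory-rate column, which populates
    ``ref_resp``.
    """
    signals_path = Path(signals_path)
    if not signals_path.exists():
        raise FileNotFoundError(signals_path)
    sig = pd.read_csv(signals_path)
    sig.columns = [str(c).strip() for c in sig.columns]

    def _find(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
        lookup = {c.lower(): c for c in df.columns}
        for cand in candidates:
            if cand.lower() in lookup:
                return lookup[cand.lower()]
        raise FormatError(
            f"no {what} column among {list(df.columns)}; "
            f"expected one of {list(candidates)}"
        )

    ppg_col = _find(sig, ppg_candidates, "PPG")
    samples = pd.to_numeric(sig[ppg_col], errors="coerce").to_numpy(float)

    ref = np.empty((0, 2))
    if numerics_path is not None:
        numerics_path = Path(numerics_path)
        if not numerics_path.exists():
            raise FileNotFoundError(numerics_path)
        num = pd.read_csv(numerics_path)
        num.columns = [str(c).strip() for c in num.columns]
        resp_col = _find(num, resp_candidates, "respiratory-rate")
        rr = pd.to_numeric(num[resp_col], errors="coerce").to_numpy(float)
        t = np.arange(rr.size) / numerics_fs
        keep = ~np.isnan(rr)
        ref = np.column_stack([t[keep], rr[keep]])

    return PPGRecord(samples=samples, fs=fs, subject_id=signals_path.stem,
                     ref_resp=ref)


_EST_COLUMNS = [
    "start_s", "window_s", "respr", "respr_raw", "esqi", "scale",
    "skipped", "clamped", "scaled", "skip_reason",
]


def write_estimates_csv(estimates: Sequence[RespEstimate], path) -> None:
    """Write per-window estimates to CSV (deterministic column order).

    Skipped windows get an empty ``respr`` cell.  Floats are written with 6
    decimals so a write/read round trip preserves values to 1e-6.
    """
    if len(estimates) == 0:
        raise DataError("no estimates to write")
    rows = []
    for e in estimates:
        rows.append({
            "start_s": e.window.start_s,
            "window_s": e.window.window_s,
            "respr": e.respr if not e.skipped else None,
            "respr_raw": e.respr_raw,
            "esqi": e.esqi,
            "scale": e.scale,
            "skipped": e.skipped,
            "clamped": e.clamped,
            "scaled": e.scaled,
            "skip_reason": e.skip_reason,
        })
    df = pd.DataFrame(rows, columns=_EST_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_estimates_csv(path) -> pd.DataFrame:
    """Read back a file produced by :func:`write_estimates_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(_EST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"estimate CSV missing columns {sorted(missing)}")
    return df
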