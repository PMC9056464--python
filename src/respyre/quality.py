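"""Entropy-based signal-quality index (ESQI) and window gating.

ESQI is the Shannon-style sum ``E = -sum(x[i]^2 * ln(x[i]^2))`` over the
analysed window.  When any sample is (numerically) zero, the ``0 * ln 0``
term is undefined and the whole window is declared undefined; the pipeline
then skips that window rather than emitting a rate from a signal with no
fluctuation.  The statistic is deliberately scale-sensitive: no hidden
normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DataError

__all__ = ["QualityResult", "esqi", "gate_window", "ZERO_TOL"]

#: Samples with |x| at or below this are treated as exact zeros, since
#: floating-point underflow in x**2 produces the same 0*log(0) pathology.
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class QualityResult:
    esqi: Optional[float]
    defined: bool


def esqi(samples: np.ndarray, zero_tol: float = ZERO_TOL) -> QualityResult:
    """Entropy signal-quality index of a window.

    Returns an undefined result (``defined=False``) when any sample is a
    numerical zero; otherwise the finite entropy sum.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise DataError("esqi of an empty window")
    if np.any(np.abs(x) <= zero_tol) or np.isnan(x).any():
        return QualityResult(esqi=None, defined=False)
    x2 = x * x
    return QualityResult(esqi=float(-np.sum(x2 * np.log(x2))), defined=True)


def gate_window(q: QualityResult, use_esqi: bool) -> bool:
    """Return whether estimation should proceed for this window.

    With gating disabled every window proceeds; with gating enabled only
    windows whose ESQI is defined do.
    """
    if not use_esqi:
        return True
    return q.defined
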