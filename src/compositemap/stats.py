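"""Shared statistical primitives: rank correlation, the fit-value selection
heuristic and anchor regression."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .model import Projection

__all__ = ["spearman_rho", "fit_value", "fit_projection"]


def spearman_rho(a, b) -> float | None:
    """Signed Spearman rank correlation of two position vectors, with
    mean-rank treatment of ties.

    Returns None (undefined) for fewer than 2 pairs or when either side has
    zero rank variance (all positions tied).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("position vectors must have equal length")
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return None
    rho = sps.spearmanr(a, b).statistic
    if not math.isfinite(rho):
        return None
    return float(rho)


def fit_value(rho: float | None, n_common: int, log_base: float = 10.0) -> float | None:
    """Selection heuristic |rho| x log(n_common).

    The correlation magnitude rewards marker-order agreement (orientation
    being arbitrary across maps) and the log term rewards shared-marker count
    with diminishing returns.  Candidate ranking is invariant to the log base
    (a positive rescaling); base 10 is the default.  Returns 0 for a single
    shared marker and None (undefined) when n_common is 0 or rho is undefined.
    """
    if n_common < 1:
        return None
    if n_common == 1:
        return 0.0
    if rho is None:
        return None
    return abs(rho) * math.log(n_common) / math.log(log_base)


def fit_projection(pc, pi) -> Projection:
    """Ordinary least squares fit of the line pc = m * pi + c.

    ``pc`` are anchor positions on the building composite LG, ``pi`` on the
    component LG (already flipped if the component orientation is reversed).
    Raises ``ValueError`` on < 2 anchors or when all pi coincide (degenerate).
    """
    pc = np.asarray(pc, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if pc.size != pi.size:
        raise ValueError("anchor vectors must have equal length")
    if pc.size < 2:
        raise ValueError("projection needs >= 2 anchors")
    if np.all(pi == pi[0]):
        raise ValueError("degenerate fit: all component anchor positions identical")
    res = sps.linregress(pi, pc)
    if not (np.isfinite(res.slope) and np.isfinite(res.intercept)):
        # anchor spread can underflow to zero variance even when values differ
        raise ValueError("degenerate fit: component anchor positions have no usable spread")
    resid = pc - (res.slope * pi + res.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return Projection(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_rmse=rmse,
        n_anchors=int(pc.size),
    )
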