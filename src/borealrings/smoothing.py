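"""Cubic smoothing splines with a 50% frequency-response cutoff.

This is the standard dendrochronology smoother: a penalized least-squares
fit on a unit-spaced grid, with the penalty placed on second differences.
Its amplitude response is

    H(f) = 1 / (1 + 16 * lam * sin^4(pi * f)),

so choosing ``lam = 1 / (16 sin^4(pi / T))`` puts the half-power point at
period ``T`` years: variance at periods longer than ``T`` is mostly kept,
variance at shorter periods is mostly removed.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = ["cutoff_lambda", "smoothing_spline", "highpass_ratio"]


def cutoff_lambda(period: float) -> float:
    """Penalty weight that places the 50% amplitude cutoff at ``period``."""
    if period <= 2.0:
        raise ValueError("cutoff period must exceed 2 samples")
    return 1.0 / (16.0 * np.sin(np.pi / period) ** 4)


def smoothing_spline(
    y: np.ndarray,
    cutoff: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth ``y`` on a unit-spaced grid with a 50% cutoff at ``cutoff``.

    Parameters
    ----------
    y
        Observations on consecutive integer positions.  Positions with
        zero weight are interpolated smoothly (their ``y`` is ignored).
    cutoff
        Period (in samples) at which the smoother passes 50% amplitude.
    weights
        Nonnegative observation weights, e.g. sample depth; default all 1.

    Series shorter than 4 samples are returned unchanged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        return y.copy()
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("weights must be nonnegative and match y")
        if not np.any(w > 0):
            raise ValueError("at least one positive weight required")
    lam = cutoff_lambda(cutoff)
    # second-difference operator, (n-2) x n
    e = np.ones(n)
    d2 = sparse.diags([e[:-2], -2 * e[:-2], e[:-2]], [0, 1, 2], shape=(n - 2, n))
    a = sparse.diags(w) + lam * (d2.T @ d2)
    rhs = w * np.where(w > 0, y, 0.0)
    return spsolve(a.tocsc(), rhs)


def highpass_ratio(y: np.ndarray, cutoff: float, floor: float = 1e-6) -> np.ndarray:
    """High-pass a positive series as the ratio to its smoothed level."""
    smooth = smoothing_spline(y, cutoff)
    smooth = np.maximum(smooth, floor)
    return np.asarray(y, dtype=float) / smooth
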