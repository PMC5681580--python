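"""Tukey biweight robust location, scalar and row-vectorized forms.

The biweight mean downweights values far from the current location
estimate with the weight ``(1 - u^2)^2`` for ``|u| < 1`` (else 0), where
``u = (x - t) / (c * MAD)`` with tuning constant ``c = 9`` and the median
absolute deviation as the scale.  Iteration starts at the median.
"""

from __future__ import annotations

import numpy as np

__all__ = ["biweight_mean", "biweight_rows"]

TUNING_C = 9.0
TOL = 1e-9
MAX_ITER = 50


def biweight_mean(
    values,
    c: float = TUNING_C,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> float:
    """Tukey biweight location of a 1-D sample.

    Returns the value itself for n = 1 and the median for n <= 3 or when
    the MAD is zero (no resolvable scale).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("biweight_mean of empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("biweight_mean requires finite values")
    if x.size == 1:
        return float(x[0])
    med = float(np.median(x))
    if x.size <= 3:
        return med
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    t = med
    scale = c * mad
    for _ in range(max_iter):
        u = np.clip((x - t) / scale, -1.0, 1.0)
        w = (1.0 - u * u) ** 2
        sw = w.sum()
        if sw == 0.0:
            return med
        t_new = float((w * x).sum() / sw)
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def biweight_rows(matrix: np.ndarray, c: float = TUNING_C, tol: float = TOL,
                  max_iter: int = MAX_ITER) -> np.ndarray:
    """Biweight location of each row of a 2-D array (no NaNs).

    Vectorized across rows; used for bootstrap resampling where thousands
    of same-length samples are reduced at once.  Follows the same n <= 3
    and zero-MAD fallbacks as :func:`biweight_mean`.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] == 0:
        raise ValueError("expected a nonempty 2-D array")
    med = np.median(m, axis=1)
    if m.shape[1] <= 3:
        return med
    mad = np.median(np.abs(m - med[:, None]), axis=1)
    degenerate = mad == 0.0
    scale = np.where(degenerate, 1.0, c * mad)
    t = med.copy()
    active = ~degenerate
    for _ in range(max_iter):
        if not active.any():
            break
        u = np.clip((m[active] - t[active, None]) / scale[active, None], -1.0, 1.0)
        w = (1.0 - u * u) ** 2
        sw = w.sum(axis=1)
        zero = sw == 0.0
        t_new = np.where(zero, med[active], (w * m[active]).sum(axis=1) / np.where(zero, 1.0, sw))
        moved = np.abs(t_new - t[active]) >= tol
        t[active] = t_new
        idx = np.flatnonzero(active)
        active[idx[~moved]] = False
    t[degenerate] = med[degenerate]
    return t
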