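"""Static, moving-window and nonlinear (BRT) climate-growth analysis.

The variable set follows standard boreal dendroclimatology practice:
monthly mean air temperature and monthly precipitation for May-August of
the growth year and the previous year, plus seasonal precipitation totals
(May-August, and October-April with the winter total assigned to the later
year).  Precipitation is natural-log transformed (log(x + 0.1 mm)) before
any correlation, because monthly totals are positively skewed.

Significance of Pearson correlations is assessed with a stationary
bootstrap of years (mean block length 5, to respect the modest
autocorrelation of ring-width indices): the growth series is resampled
in blocks against the fixed climate to build the null distribution of r
under independence, and the observed correlation is significant when it
falls outside that null's central 95% band.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .brt import BRTConfig, BRTResult, fit_brt
from .detrend import Chronology

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateTable",
    "build_variable_set",
    "is_precip_variable",
    "log_precip",
    "static_correlations",
    "moving_correlations",
    "low_frequency_test",
    "brt_climate_model",
]

MONTHS = ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug",
          "sep", "oct", "nov", "dec"]
SEASON_MONTHS = ["may", "jun", "jul", "aug"]
PRECIP_LOG_OFFSET = 0.1  # mm; keeps zero-precipitation months representable
MEAN_BLOCK_YEARS = 5


class ClimateTable:
    """Monthly station climate by year with derived seasonal aggregates.

    Wraps a year-indexed DataFrame with columns ``t_jan..t_dec`` (degrees C)
    and ``p_jan..p_dec`` (mm).  Years must be contiguous and precipitation
    nonnegative.
    """

    def __init__(self, data: pd.DataFrame):
        required = [f"t_{m}" for m in MONTHS] + [f"p_{m}" for m in MONTHS]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        data = data.sort_index()
        years = data.index.to_numpy()
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError("climate years must be contiguous")
        if (data[[f"p_{m}" for m in MONTHS]] < 0).any().any():
            raise ValueError("negative precipitation")
        self.data = data

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def seasonal(self) -> pd.DataFrame:
        """May-Aug mean T, May-Aug precip total, and Oct-Apr precip total
        (October-December of the previous year plus January-April of the
        labelled year)."""
        d = self.data
        t_mjja = d[[f"t_{m}" for m in SEASON_MONTHS]].mean(axis=1)
        p_mjja = d[[f"p_{m}" for m in SEASON_MONTHS]].sum(axis=1)
        p_oct_dec_prev = d[["p_oct", "p_nov", "p_dec"]].sum(axis=1).shift(1)
        p_jan_apr = d[["p_jan", "p_feb", "p_mar", "p_apr"]].sum(axis=1)
        return pd.DataFrame(
            {
                "t_mjja": t_mjja,
                "p_mjja": p_mjja,
                "p_oct_apr": p_oct_dec_prev + p_jan_apr,
            }
        )

    @classmethod
    def from_csv(cls, path) -> "ClimateTable":
        return cls(pd.read_csv(path, index_col="year"))

    def to_csv(self, path) -> None:
        self.data.rename_axis("year").to_csv(path)


def build_variable_set(climate: ClimateTable) -> pd.DataFrame:
    """Climate predictors for correlation analysis, year-indexed.

    Sixteen monthly variables (T and P for May-August, current and
    previous year) plus current/previous seasonal precipitation totals.
    Previous-year variables are lagged exactly one year.
    """
    d = climate.data
    seas = climate.seasonal()
    out = {}
    for m in SEASON_MONTHS:
        out[f"t_{m}"] = d[f"t_{m}"]
        out[f"t_prev_{m}"] = d[f"t_{m}"].shift(1)
        out[f"p_{m}"] = d[f"p_{m}"]
        out[f"p_prev_{m}"] = d[f"p_{m}"].shift(1)
    out["p_mjja"] = seas["p_mjja"]
    out["p_prev_mjja"] = seas["p_mjja"].shift(1)
    out["p_oct_apr"] = seas["p_oct_apr"]
    out["p_prev_oct_apr"] = seas["p_oct_apr"].shift(1)
    return pd.DataFrame(out)


MONTHLY_VARIABLES = [
    f"{kind}{lag}_{m}"
    for kind in ("p", "t")
    for lag in ("_prev", "")
    for m in SEASON_MONTHS
]
TEMPERATURE_VARIABLES = [v for v in MONTHLY_VARIABLES if v.startswith("t")]


def is_precip_variable(name: str) -> bool:
    return name.startswith("p_")


def log_precip(x: np.ndarray) -> np.ndarray:
    return np.log(np.asarray(x, dtype=float) + PRECIP_LOG_OFFSET)


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------


def stationary_bootstrap_indices(
    n: int, n_reps: int, mean_block: float, rng: np.random.Generator
) -> np.ndarray:
    """Index matrix (n_reps, n) from the stationary (geometric-block)
    bootstrap with wrap-around."""
    p = 1.0 / mean_block
    idx = np.empty((n_reps, n), dtype=np.intp)
    idx[:, 0] = rng.integers(0, n, size=n_reps)
    for t in range(1, n):
        restart = rng.random(n_reps) < p
        idx[:, t] = np.where(
            restart, rng.integers(0, n, size=n_reps), (idx[:, t - 1] + 1) % n
        )
    return idx


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape 2-D arrays."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc ** 2).sum(axis=1) * (Yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _bootstrap_significant(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> bool:
    """Bootstrap test of the correlation between climate ``x`` and growth
    ``y``.

    The null distribution is built under independence: the growth series
    is resampled in stationary (mean length 5) blocks -- preserving its
    autocorrelation -- against the fixed climate series, and the observed
    r is called significant when it falls outside the null's central 95%
    band.  Resampling under the null keeps the test at nominal size,
    which interval-excludes-zero constructions miss at this sample size.
    """
    r = float(np.corrcoef(x, y)[0, 1])
    idx = stationary_bootstrap_indices(y.size, n_boot, MEAN_BLOCK_YEARS, rng)
    null = _pearson_rows(np.broadcast_to(x, (n_boot, x.size)), y[idx])
    null = null[np.isfinite(null)]
    if null.size == 0:
        return False
    lo, hi = np.percentile(null, [2.5, 97.5])
    return bool(r < lo or r > hi)


def _as_series(chron) -> pd.Series:
    if isinstance(chron, Chronology):
        return chron.as_series()
    return chron


# ---------------------------------------------------------------------------
# Correlation analyses
# ---------------------------------------------------------------------------


def static_correlations(
    chron,
    variables: pd.DataFrame,
    span: tuple[int, int] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    min_overlap: int = 30,
) -> pd.DataFrame:
    """Pearson correlation of the chronology with each climate variable.

    Precipitation variables are log-transformed.  Significance: stationary
    bootstrap of years, 95% percentile interval excluding zero.  Constant
    variables yield ``r = NaN``.
    """
    g = _as_series(chron).dropna()
    years = g.index.intersection(variables.dropna().index)
    if span is not None:
        years = years[(years >= span[0]) & (years <= span[1])]
    if len(years) < min_overlap:
        raise ValueError(f"overlap of {len(years)} years; need >= {min_overlap}")
    rng = np.random.default_rng(seed)
    yv = g.loc[years].to_numpy()
    rows = []
    for var in variables.columns:
        xv = variables.loc[years, var].to_numpy(dtype=float)
        if is_precip_variable(var):
            xv = log_precip(xv)
        if np.std(xv) == 0 or np.std(yv) == 0:
            rows.append({"variable": var, "r": np.nan, "significant": False})
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        sig = _bootstrap_significant(xv, yv, n_boot, rng)
        rows.append({"variable": var, "r": r, "significant": sig})
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["span"] = (int(years.min()), int(years.max()))
    return out


def moving_correlations(
    chron,
    variables: pd.DataFrame,
    window: int = 25,
    step: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Window-by-window Pearson correlations with bootstrap significance.

    Windows of ``window`` years advance by ``step``; each window's r uses
    the same transforms as the static analysis.  Returns a tidy frame
    (window_start, window_end, variable, r, significant).
    """
    g = _as_series(chron).dropna()
    common = g.index.intersection(variables.dropna().index)
    common = common.sort_values()
    n = len(common)
    if n < window:
        raise ValueError(f"record of {n} years shorter than window {window}")
    rng = np.random.default_rng(seed)
    yv = g.loc[common].to_numpy()
    rows = []
    for var in variables.columns:
        xv = variables.loc[common, var].to_numpy(dtype=float)
        if is_precip_variable(var):
            xv = log_precip(xv)
        for start in range(0, n - window + 1, step):
            xs, ys = xv[start : start + window], yv[start : start + window]
            if np.std(xs) == 0 or np.std(ys) == 0:
                r, sig = np.nan, False
            else:
                r = float(np.corrcoef(xs, ys)[0, 1])
                sig = _bootstrap_significant(xs, ys, n_boot, rng)
            rows.append(
                {
                    "window_start": int(common[start]),
                    "window_end": int(common[start + window - 1]),
                    "variable": var,
                    "r": r,
                    "significant": sig,
                }
            )
    return pd.DataFrame(rows)


def _moving_r_matrix(Y: np.ndarray, x: np.ndarray, window: int) -> np.ndarray:
    """Moving-window Pearson r of each row of Y against x (shape
    (n_rows, n_windows)), via cumulative sums."""

    def winsum(a):
        cs = np.cumsum(a, axis=-1)
        out = np.empty(a.shape[:-1] + (a.shape[-1] - window + 1,))
        out[..., 0] = cs[..., window - 1]
        out[..., 1:] = cs[..., window:] - cs[..., :-window]
        return out

    w = window
    sx = winsum(x[None, :])[0]
    sxx = winsum((x * x)[None, :])[0]
    sy = winsum(Y)
    syy = winsum(Y * Y)
    sxy = winsum(Y * x[None, :])
    num = w * sxy - sx[None, :] * sy
    den = np.sqrt(
        np.maximum(w * sxx - sx * sx, 0.0)[None, :]
        * np.maximum(w * syy - sy * sy, 0.0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def low_frequency_test(
    chron_values: np.ndarray,
    climate_values: np.ndarray,
    window: int = 25,
    n_boot: int = 1000,
    block: int = 5,
    seed: int | None = None,
) -> float:
    """Test whether low-frequency change in the moving correlation exceeds
    chance.

    The statistic is the variance of the moving-window correlation series.
    The null is built by recomputing moving correlations for ``n_boot``
    surrogate chronologies whose years are resampled in circular blocks of
    ``block`` years against the fixed climate series.  Returns the
    fraction of null variances at least as large as the observed one.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(chron_values, dtype=float)
    x = np.asarray(climate_values, dtype=float)
    if y.size != x.size:
        raise ValueError("series lengths differ")
    n = y.size
    n_windows = n - window + 1
    if n_windows < 20:
        raise ValueError("need at least 20 moving windows")
    obs_r = _moving_r_matrix(y[None, :], x, window)[0]
    obs = float(np.var(obs_r))
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n, size=(n_boot, n_blocks))
    idx = (starts[:, :, None] + np.arange(block)[None, None, :]) % n
    surrogates = y[idx.reshape(n_boot, -1)[:, :n]]
    null_r = _moving_r_matrix(surrogates, x, window)
    null_var = np.nanvar(null_r, axis=1)
    return float(np.mean(null_var >= obs))


def brt_climate_model(
    chron,
    variables: pd.DataFrame,
    config: BRTConfig | None = None,
) -> BRTResult:
    """Gradient-boosted model of the chronology on the climate variables.

    Precipitation variables are log-transformed for consistency with the
    correlation analyses (monotone transforms do not change tree splits,
    but keep partial-dependence axes comparable).
    """
    g = _as_series(chron).rename("rwi")
    X = variables.copy()
    for var in X.columns:
        if is_precip_variable(var):
            X[var] = log_precip(X[var].to_numpy())
    X, g = X.align(g, join="inner", axis=0)
    return fit_brt(X, g, config)
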