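"""Multi-curve signal-free RCS detrending and chronology construction.

Regional curve standardization (RCS) removes the age-related decline in
ring width by dividing each measured width by the width expected for a
ring of that cambial age, estimated from the whole cohort.  Multi-curve
RCS fits one expected-width curve per growth-rate class (series grouped
by mean ring width, >40 series per group).  Chronologies are Tukey
biweight robust means of the ring-width indices per calendar year, and
the signal-free iteration removes the common year signal from the
measurements before refitting the age curves, which reduces trend
distortion relative to a single RCS pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ringio import RingSeries
from .robust import biweight_mean, biweight_rows
from .smoothing import smoothing_spline

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalCurve",
    "Chronology",
    "RCSResult",
    "biweight_mean",
    "assign_rcs_groups",
    "fit_regional_curve",
    "ratio_indices",
    "build_chronology",
    "single_pass_rcs",
    "signal_free_rcs",
    "subgroup_chronology",
]

CURVE_FLOOR_MM = 0.001
DEFAULT_N_GROUPS = 4
MIN_GROUP_SIZE = 40
DEFAULT_TRUNCATION_N = 50
SF_TOL = 0.002
SF_MAX_ITER = 9


@dataclass
class RegionalCurve:
    """Expected ring width (mm) as a function of cambial age for one group."""

    group_id: int
    ages: np.ndarray            # cambial ages 1..A_max
    expected_width: np.ndarray  # smoothed mean width per age, floored > 0
    n_per_age: np.ndarray       # sample depth per age

    def expected_at(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        if ages.min() < 1 or ages.max() > self.ages[-1]:
            raise ValueError(
                f"group {self.group_id}: cambial age {ages.max()} outside "
                f"curve support 1..{self.ages[-1]}"
            )
        return self.expected_width[ages - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_id,
                "age": self.ages,
                "expected_width_mm": self.expected_width,
                "n": self.n_per_age,
            }
        )


@dataclass
class Chronology:
    """Year-indexed growth index with sample depth and 95% confidence band.

    The index has mean 1.0 over the retained span.  ``low_depth_interior``
    flags interior years kept despite a sample depth below the truncation
    threshold (truncation removes sub-threshold years at the ends only).
    """

    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    low_depth_interior: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.low_depth_interior is None:
            self.low_depth_interior = np.zeros(self.years.size, dtype=bool)

    @property
    def empty(self) -> bool:
        return self.years.size == 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name="rwi")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "index": self.index,
                "sample_depth": self.sample_depth,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class RCSResult:
    """Chronology plus the regional curves and indices that produced it."""

    chronology: Chronology
    curves: dict[int, RegionalCurve]
    groups: pd.Series                 # series_id -> group id
    indices: dict[str, pd.Series]     # series_id -> year-indexed RWI
    iterations: int = 1
    index_deltas: list[float] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# Grouping and curve fitting
# ---------------------------------------------------------------------------


def assign_rcs_groups(
    series_list: Sequence[RingSeries],
    n_groups: int = DEFAULT_N_GROUPS,
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.Series:
    """Partition series into growth-rate classes of near-equal size.

    Series are ranked by age-adjusted mean growth rate -- the mean ratio
    of each series to a preliminary one-curve RCS fit -- and split into
    contiguous, near-equal groups.  Ranking on the age-adjusted rate
    rather than the raw mean width keeps young trees (which carry only
    wide juvenile rings) from being misclassified as fast growers, which
    would couple group membership to calendar time.  If any group would
    hold ``min_group_size`` series or fewer, the number of groups is
    reduced until every group exceeds it (or a single group remains,
    i.e. classic one-curve RCS).
    """
    if not series_list:
        raise ValueError("empty series set")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    n = len(series_list)
    while n_groups > 1 and n // n_groups <= min_group_size:
        n_groups -= 1
    if n_groups > 1:
        pilot = fit_regional_curve(series_list, group_id=-1)
        rate = np.array(
            [float(np.mean(ratio_indices(s, pilot))) for s in series_list]
        )
    else:
        rate = np.array([float(np.mean(s.widths)) for s in series_list])
    order = np.argsort(rate, kind="stable")
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        labels[chunk] = g
    if n_groups > 1:
        logger.info("assigned %d series to %d RCS groups", n, n_groups)
    return pd.Series(labels, index=[s.series_id for s in series_list], name="group")


def _negexp(a, alpha, beta, kappa):
    return alpha * np.exp(-beta * a) + kappa


def fit_regional_curve(
    group_series: Sequence[RingSeries],
    group_id: int = 0,
    cutoff_fraction: float = 0.10,
    method: str = "spline",
    widths_override: dict[str, np.ndarray] | None = None,
) -> RegionalCurve:
    """Fit the expected-width-by-cambial-age curve for one group.

    Widths are aligned by cambial age (missing-ring offsets included), a
    biweight mean is taken per age, and the age profile is smoothed by a
    cubic smoothing spline with 50% cutoff at ``cutoff_fraction`` of the
    maximum cambial age (weighted by per-age sample depth).  A
    negative-exponential fit ``alpha*exp(-beta*age)+kappa`` is available
    as ``method="negexp"``.  Output is floored at 0.001 mm.

    ``widths_override`` substitutes alternative measurements (e.g.
    signal-free widths) per series id while keeping the age alignment.
    """
    if not group_series:
        raise ValueError("empty group")
    max_age = max(int(s.cambial_ages[-1]) for s in group_series)
    buckets: list[list[float]] = [[] for _ in range(max_age)]
    for s in group_series:
        w = s.widths if widths_override is None else widths_override[s.series_id]
        for age, width in zip(s.cambial_ages, w):
            buckets[age - 1].append(width)
    n_per_age = np.array([len(b) for b in buckets])
    raw_mean = np.array(
        [biweight_mean(b) if b else np.nan for b in buckets], dtype=float
    )
    observed = n_per_age > 0
    if observed.any() and np.all(raw_mean[observed] == 0):
        raise ValueError(f"group {group_id}: all-zero mean widths")
    if method == "negexp":
        ages = np.arange(1, max_age + 1, dtype=float)
        a_obs, y_obs = ages[observed], raw_mean[observed]
        try:
            p0 = (max(y_obs[0] - y_obs[-1], 0.1), 0.02, max(y_obs[-1], 0.01))
            popt, _ = curve_fit(
                _negexp, a_obs, y_obs, p0=p0,
                bounds=([0, 1e-6, 0], [np.inf, 1.0, np.inf]), maxfev=10000,
            )
            smooth = _negexp(ages, *popt)
        except RuntimeError:
            logger.warning("group %d: negexp fit failed; falling back to spline", group_id)
            smooth = _spline_curve(raw_mean, n_per_age, max_age, cutoff_fraction)
    else:
        smooth = _spline_curve(raw_mean, n_per_age, max_age, cutoff_fraction)
    expected = np.maximum(smooth, CURVE_FLOOR_MM)
    return RegionalCurve(
        group_id=group_id,
        ages=np.arange(1, max_age + 1),
        expected_width=expected,
        n_per_age=n_per_age,
    )


def _spline_curve(raw_mean, n_per_age, max_age, cutoff_fraction):
    cutoff = max(cutoff_fraction * max_age, 3.0)
    y = np.where(n_per_age > 0, raw_mean, 0.0)
    return smoothing_spline(y, cutoff, weights=n_per_age.astype(float))


def ratio_indices(series: RingSeries, curve: RegionalCurve) -> pd.Series:
    """Ring-width indices: observed over age-expected width, year-indexed."""
    expected = curve.expected_at(series.cambial_ages)
    return pd.Series(series.widths / expected, index=series.years,
                     name=series.series_id)


# ---------------------------------------------------------------------------
# Chronology
# ---------------------------------------------------------------------------


def build_chronology(
    indices_by_tree: dict[str, pd.Series],
    truncation_n: int = DEFAULT_TRUNCATION_N,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> Chronology:
    """Biweight-mean chronology across trees with end truncation and CI.

    Years whose sample depth falls below ``truncation_n`` are removed from
    both ends; interior sub-threshold years are retained and flagged.  The
    95% band is a percentile bootstrap over trees within each year
    (``n_boot`` replicates; pass 0 to skip).  The retained index is
    rescaled multiplicatively so its mean is exactly 1.0.
    """
    if not indices_by_tree:
        raise ValueError("no tree indices supplied")
    frame = pd.DataFrame(indices_by_tree).sort_index()
    depth = frame.notna().sum(axis=1).to_numpy()
    ok = depth >= truncation_n
    if not ok.any():
        logger.warning(
            "no year reaches sample depth %d; empty chronology", truncation_n
        )
        z = np.array([])
        return Chronology(z, z.copy(), z.copy(), z.copy(), z.copy())
    start, stop = np.argmax(ok), len(ok) - np.argmax(ok[::-1])
    frame = frame.iloc[start:stop]
    depth = depth[start:stop]
    years = frame.index.to_numpy()
    rng = rng or np.random.default_rng()
    index = np.empty(len(frame))
    lo = np.full(len(frame), np.nan)
    hi = np.full(len(frame), np.nan)
    for i, (_, row) in enumerate(frame.iterrows()):
        vals = row.dropna().to_numpy()
        index[i] = biweight_mean(vals)
        if n_boot > 0:
            draws = rng.integers(0, vals.size, size=(n_boot, vals.size))
            reps = biweight_rows(vals[draws])
            lo[i], hi[i] = np.percentile(reps, [2.5, 97.5])
    scale = 1.0 / float(np.mean(index))
    return Chronology(
        years=years,
        index=index * scale,
        sample_depth=depth,
        ci_low=lo * scale,
        ci_high=hi * scale,
        low_depth_interior=depth < truncation_n,
    )


def _mean_one(values: np.ndarray) -> np.ndarray:
    return values / np.mean(values)


def _chronology_values(indices_by_tree: dict[str, pd.Series]) -> pd.Series:
    """Untruncated biweight chronology (mean 1.0) used inside the
    signal-free iteration."""
    frame = pd.DataFrame(indices_by_tree).sort_index()
    vals = np.array(
        [biweight_mean(row.dropna().to_numpy()) for _, row in frame.iterrows()]
    )
    return pd.Series(_mean_one(vals), index=frame.index)


# ---------------------------------------------------------------------------
# RCS pipelines
# ---------------------------------------------------------------------------


def _fit_all(series_list, groups, cutoff_fraction, method, widths_override=None):
    curves: dict[int, RegionalCurve] = {}
    for g in sorted(groups.unique()):
        members = [s for s in series_list if groups[s.series_id] == g]
        curves[g] = fit_regional_curve(
            members, group_id=g, cutoff_fraction=cutoff_fraction, method=method,
            widths_override=widths_override,
        )
    return curves


def _indices_all(series_list, groups, curves):
    return {
        s.series_id: ratio_indices(s, curves[groups[s.series_id]])
        for s in series_list
    }


def single_pass_rcs(
    series_list: Sequence[RingSeries],
    n_groups: int = DEFAULT_N_GROUPS,
    truncation_n: int = DEFAULT_TRUNCATION_N,
    cutoff_fraction: float = 0.10,
    curve_method: str = "spline",
    n_boot: int = 1000,
    seed: int | None = None,
) -> RCSResult:
    """Classic (non-iterated) multi-curve RCS detrending."""
    groups = assign_rcs_groups(series_list, n_groups)
    curves = _fit_all(series_list, groups, cutoff_fraction, curve_method)
    indices = _indices_all(series_list, groups, curves)
    chron = build_chronology(
        indices, truncation_n, n_boot, np.random.default_rng(seed)
    )
    return RCSResult(chron, curves, groups, indices)


def signal_free_rcs(
    series_list: Sequence[RingSeries],
    n_groups: int = DEFAULT_N_GROUPS,
    truncation_n: int = DEFAULT_TRUNCATION_N,
    cutoff_fraction: float = 0.10,
    curve_method: str = "spline",
    max_iter: int = SF_MAX_ITER,
    tol: float = SF_TOL,
    n_boot: int = 1000,
    seed: int | None = None,
) -> RCSResult:
    """Signal-free multi-curve RCS.

    Iterates: divide each raw width by the current chronology index for
    its year (producing signal-free measurements), refit the regional
    curves from those measurements, recompute indices and the chronology
    from the RAW widths against the refit curves.  Stops when the maximum
    per-year index change is below ``tol`` (default 0.002) or after
    ``max_iter`` iterations (default 9), warning on non-convergence.
    """
    if not series_list:
        raise ValueError("empty series set")
    groups = assign_rcs_groups(series_list, n_groups)
    curves = _fit_all(series_list, groups, cutoff_fraction, curve_method)
    indices = _indices_all(series_list, groups, curves)
    chron_vals = _chronology_values(indices)
    deltas: list[float] = []
    converged = False
    iteration = 1
    while iteration < max_iter:
        iteration += 1
        sf_widths = {
            s.series_id: s.widths / chron_vals.loc[s.years].to_numpy()
            for s in series_list
        }
        curves = _fit_all(
            series_list, groups, cutoff_fraction, curve_method,
            widths_override=sf_widths,
        )
        indices = _indices_all(series_list, groups, curves)
        new_vals = _chronology_values(indices)
        delta = float(np.max(np.abs(new_vals.to_numpy() - chron_vals.to_numpy())))
        deltas.append(delta)
        chron_vals = new_vals
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "signal-free RCS did not converge in %d iterations "
            "(last max index change %.4f); returning last iterate",
            max_iter, deltas[-1] if deltas else float("nan"),
        )
    chron = build_chronology(
        indices, truncation_n, n_boot, np.random.default_rng(seed)
    )
    return RCSResult(chron, curves, groups, indices, iteration, deltas, converged)


def subgroup_chronology(
    series_list: Sequence[RingSeries],
    predicate: Callable[[RingSeries], bool],
    min_n: int = 25,
    truncation_n: int | None = None,
    **kwargs,
) -> RCSResult:
    """Signal-free RCS chronology for the subset selected by ``predicate``.

    Used for species-by-plot-type and good/poor-habitat chronologies.
    Refuses subsets smaller than ``min_n`` trees.  Truncation defaults to
    ``min_n`` for subgroups (full-population chronologies use 50).
    """
    subset = [s for s in series_list if predicate(s)]
    if len(subset) < min_n:
        raise ValueError(
            f"subgroup has {len(subset)} trees; at least {min_n} required"
        )
    if truncation_n is None:
        truncation_n = min_n
    return signal_free_rcs(subset, truncation_n=truncation_n, **kwargs)
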