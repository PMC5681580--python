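"""Tree-ring carbon-isotope gas-exchange physiology.

Carbon isotope discrimination in tree rings,

    D13C = (d13Ca - d13Ctree) / (1 + d13Ctree / 1000),

reflects the balance between photosynthesis (A) and stomatal conductance
(Gs).  From discrimination the ratio of intercellular to atmospheric CO2
follows as Ci/Ca = (D - a) / (b - a) with a = 4.4 permil (diffusion
through stomata) and b = 27 permil (carboxylation), and intrinsic
water-use efficiency as iWUE = A/Gs = (Ca - Ci) / 1.6.

Alpha-cellulose is isotopically enriched relative to the whole-leaf
tissue for which the Ci/Ca relation was developed, so a fixed offset of
-1.33 permil is applied to cellulose d13C before the Ci/Ca step (the raw
discrimination series is reported without it).

A tree's early rings show elevated discrimination (soil-respired CO2,
shading, low hydraulic resistance), so period means are adjusted for ring
age with a random-forest regression of D13C on {ring age, period},
reporting the modeled value per period with ring age held at 100 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

__all__ = [
    "A_DIFFUSION",
    "B_CARBOXYLATION",
    "CELLULOSE_OFFSET",
    "PERIOD_LABELS",
    "period_bounds",
    "period_midyear",
    "discrimination",
    "d13c_tree_from_discrimination",
    "extrapolate_reference",
    "AgeAdjustment",
    "age_adjustment",
    "ci_over_ca",
    "iwue",
    "physio_series",
]

A_DIFFUSION = 4.4       # permil, diffusion through stomata
B_CARBOXYLATION = 27.0  # permil, carboxylation by Rubisco
CELLULOSE_OFFSET = -1.33  # permil, alpha-cellulose -> leaf-tissue scale
DEFAULT_HOLD_AGE = 100

PERIOD_LABELS = ["1895-1904", "1930-1949", "1950-1959", "1993-2002", "2003-2012"]


def period_bounds(label: str) -> tuple[int, int]:
    lo, hi = label.split("-")
    return int(lo), int(hi)


def period_midyear(label: str) -> float:
    lo, hi = period_bounds(label)
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Core equations
# ---------------------------------------------------------------------------


def discrimination(d13c_air, d13c_tree):
    """Carbon isotope discrimination (permil) from air and plant d13C."""
    d13c_tree = np.asarray(d13c_tree, dtype=float)
    if np.any(d13c_tree <= -1000.0):
        raise ValueError("d13c_tree must exceed -1000 permil")
    out = (np.asarray(d13c_air, dtype=float) - d13c_tree) / (1.0 + d13c_tree / 1000.0)
    return out if out.ndim else float(out)


def d13c_tree_from_discrimination(delta, d13c_air):
    """Inverse of :func:`discrimination`: plant d13C given D13C and air."""
    delta = np.asarray(delta, dtype=float)
    out = (np.asarray(d13c_air, dtype=float) - delta) / (1.0 + delta / 1000.0)
    return out if out.ndim else float(out)


def ci_over_ca(delta):
    """Ci/Ca from (offset-adjusted) discrimination: (D - a) / (b - a).

    Values of D outside [a, b] produce ratios outside [0, 1]; they are
    returned as-is (callers flag them) rather than clipped.
    """
    delta = np.asarray(delta, dtype=float)
    out = (delta - A_DIFFUSION) / (B_CARBOXYLATION - A_DIFFUSION)
    return out if out.ndim else float(out)


def iwue(ca, ci):
    """Intrinsic water-use efficiency A/Gs = (Ca - Ci) / 1.6 (umol/mol)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("Ca must be positive")
    out = (ca - np.asarray(ci, dtype=float)) / 1.6
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Atmospheric reference handling
# ---------------------------------------------------------------------------


def extrapolate_reference(
    ref: pd.DataFrame,
    fit_span: tuple[int, int] = (1993, 2002),
    target_span: tuple[int, int] = (2003, 2012),
) -> pd.DataFrame:
    """Extend d13c_air and Ca by linear extrapolation of a recent trend.

    Fits ordinary least squares lines over ``fit_span`` (which must be
    gap-free) separately for ``d13c_air`` and ``ca`` and appends predicted
    values for ``target_span``, flagged ``extrapolated``.
    """
    ref = ref.sort_values("year").reset_index(drop=True)
    fit_years = np.arange(fit_span[0], fit_span[1] + 1)
    sub = ref[ref["year"].isin(fit_years)]
    if len(sub) != len(fit_years):
        missing = sorted(set(fit_years) - set(sub["year"]))
        raise ValueError(f"fit span has gaps: missing years {missing}")
    target_years = np.arange(target_span[0], target_span[1] + 1)
    target_years = target_years[~np.isin(target_years, ref["year"])]
    new = {"year": target_years}
    for col in ("d13c_air", "ca"):
        coef = np.polyfit(sub["year"].to_numpy(float), sub[col].to_numpy(float), 1)
        new[col] = np.polyval(coef, target_years.astype(float))
    if "extrapolated" not in ref.columns:
        ref = ref.assign(extrapolated=False)
    newf = pd.DataFrame(new).assign(extrapolated=True)
    return pd.concat([ref, newf], ignore_index=True).sort_values("year").reset_index(drop=True)


def _period_reference_means(ref: pd.DataFrame, periods: list[str]) -> pd.DataFrame:
    rows = []
    for label in periods:
        lo, hi = period_bounds(label)
        sub = ref[(ref["year"] >= lo) & (ref["year"] <= hi)]
        if len(sub) != hi - lo + 1:
            raise ValueError(f"reference series does not cover period {label}")
        rows.append(
            {"period": label, "d13c_air": sub["d13c_air"].mean(), "ca": sub["ca"].mean()}
        )
    return pd.DataFrame(rows).set_index("period")


# ---------------------------------------------------------------------------
# Ring-age adjustment
# ---------------------------------------------------------------------------


@dataclass
class AgeAdjustment:
    adjusted: pd.Series        # modeled D13C per period at the held age
    importances: pd.Series     # permutation importance: ring_age, period
    age_profile: pd.DataFrame  # modeled D13C vs ring age (periods averaged)


def age_adjustment(
    records: pd.DataFrame,
    hold_age: float = DEFAULT_HOLD_AGE,
    n_trees: int = 500,
    seed: int | None = 0,
) -> AgeAdjustment:
    """Separate ring-age and time-period effects on D13C with a random
    forest, and report period values with ring age held constant.

    ``records`` needs columns ``delta13c``, ``ring_age`` and ``period``
    (labels like ``"1930-1949"``; the period enters the model as its
    midpoint year).  Predictor importance is permutation importance
    (20 shuffles, seeded).
    """
    required = {"delta13c", "ring_age", "period"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    records = records.dropna(subset=list(required))
    periods = sorted(records["period"].unique(), key=period_midyear)
    if len(periods) < 2:
        raise ValueError("age adjustment needs at least two time periods")
    if len(records) < 10:
        raise ValueError("too few records for age adjustment")
    age_range = records["ring_age"].max() - records["ring_age"].min()
    if len(records) < 30 or len(periods) < 3 or age_range < 50:
        logger.warning(
            "age adjustment on a thin design (%d records, %d periods, "
            "age range %.0f yr); estimates may be unstable",
            len(records), len(periods), age_range,
        )
    X = np.column_stack(
        [
            records["ring_age"].to_numpy(float),
            records["period"].map(period_midyear).to_numpy(float),
        ]
    )
    y = records["delta13c"].to_numpy(float)
    # nodesize 5 is the regression default of the reference R implementation
    model = RandomForestRegressor(
        n_estimators=n_trees, min_samples_leaf=5, random_state=seed
    )
    model.fit(X, y)
    imp = permutation_importance(
        model, X, y, n_repeats=20, random_state=seed
    ).importances_mean
    importances = pd.Series(imp, index=["ring_age", "period"])
    adjusted = pd.Series(
        model.predict(
            np.column_stack(
                [np.full(len(periods), float(hold_age)),
                 [period_midyear(p) for p in periods]]
            )
        ),
        index=pd.Index(periods, name="period"),
        name="delta13c_adjusted",
    )
    ages = np.arange(
        int(records["ring_age"].min()), int(records["ring_age"].max()) + 1
    )
    mids = np.array([period_midyear(p) for p in periods])
    grid = np.column_stack(
        [np.repeat(ages.astype(float), mids.size), np.tile(mids, ages.size)]
    )
    prof = model.predict(grid).reshape(ages.size, mids.size).mean(axis=1)
    age_profile = pd.DataFrame({"ring_age": ages, "delta13c": prof})
    return AgeAdjustment(adjusted, importances, age_profile)


# ---------------------------------------------------------------------------
# Period-level physiology series
# ---------------------------------------------------------------------------


def physio_series(
    records: pd.DataFrame,
    ref: pd.DataFrame,
    hold_age: float = DEFAULT_HOLD_AGE,
    offset: float = CELLULOSE_OFFSET,
    by: list[str] | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Period-level D13C, Ci/Ca, Ci and iWUE per species (and optional
    further strata, e.g. habitat class).

    ``records`` columns: ``tree_id, species, period, d13c, ring_age`` and
    optionally the ``by`` columns.  For each stratum and period the raw
    discrimination mean and SE are computed from measured cellulose d13C
    against the period-mean atmospheric d13Ca; the age-adjusted value (at
    ``hold_age``) is then put on the leaf scale with ``offset`` and
    converted to Ci/Ca, Ci and iWUE using period-mean Ca.
    """
    group_cols = ["species"] + (by or [])
    rows = []
    for key, sub in records.groupby(group_cols):
        if not isinstance(key, tuple):
            key = (key,)
        periods = sorted(sub["period"].unique(), key=period_midyear)
        refmeans = _period_reference_means(ref, periods)
        work = sub.copy()
        work["delta13c"] = discrimination(
            refmeans.loc[work["period"], "d13c_air"].to_numpy(),
            work["d13c"].to_numpy(float),
        )
        adj = age_adjustment(work, hold_age=hold_age, seed=seed)
        for period in periods:
            p = work[work["period"] == period]
            n = len(p)
            mean_raw = float(p["delta13c"].mean())
            se = float(p["delta13c"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            if n <= 1:
                logger.warning(
                    "stratum %s period %s has a single record; SE undefined",
                    key, period,
                )
            d13ca = float(refmeans.loc[period, "d13c_air"])
            ca = float(refmeans.loc[period, "ca"])
            delta_adj = float(adj.adjusted.loc[period])
            # put the adjusted discrimination on the leaf scale via d13C
            d13c_tree = d13c_tree_from_discrimination(delta_adj, d13ca)
            delta_leaf = discrimination(d13ca, d13c_tree + offset)
            ratio = ci_over_ca(delta_leaf)
            ci = ratio * ca
            rows.append(
                dict(
                    zip(group_cols, key),
                    period=period,
                    n=n,
                    delta13c_raw=mean_raw,
                    delta13c_se=se,
                    delta13c_adjusted=delta_adj,
                    delta13c_leaf=float(delta_leaf),
                    d13c_air=d13ca,
                    ca=ca,
                    ci_over_ca=float(ratio),
                    ci=float(ci),
                    iwue=float(iwue(ca, ci)),
                    flagged=bool(ratio < 0 or ratio > 1 or ci > ca),
                )
            )
    return pd.DataFrame(rows)
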