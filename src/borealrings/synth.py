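"""Synthetic ring-width, climate, isotope and habitat data with known truth.

The generator emulates the statistical structure a boreal spruce
tree-ring study rests on: negative-exponential age trends with lognormal
per-tree growth rates, a shared year signal driven by a decreasing
sigmoidal response to growing-season temperature and a saturating
response to August precipitation (with a weaker carry-over response to
the previous year), habitat-dependent level and sensitivity differences,
multiplicative lognormal noise, and isotope series with a strong juvenile
discrimination decline over the first 50-70 rings.  Every dataset ships
its ground-truth tables so downstream recovery tests never re-derive
truth.

All randomness flows from ``SynthConfig.seed`` through per-stage
``numpy`` generators (PCG64 seed sequences), so regenerated datasets are
bit-identical under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .climate import ClimateTable, MONTHS
from .isotopes import (
    PERIOD_LABELS,
    d13c_tree_from_discrimination,
    period_bounds,
)
from .ringio import RingSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "CohortTruth",
    "synthetic_reference",
    "generate_climate",
    "generate_cohort",
    "generate_isotopes",
    "habitat_table",
]

# Fairbanks-like monthly climatology (deg C, mm)
T_CLIMATOLOGY = np.array([-23.0, -19.0, -11.0, 0.0, 9.0, 15.0, 17.0, 14.0,
                          7.0, -4.0, -16.0, -21.0])
P_CLIMATOLOGY = np.array([14.0, 11.0, 9.0, 8.0, 17.0, 35.0, 50.0, 55.0,
                          35.0, 22.0, 18.0, 16.0])
_SEASON = slice(4, 8)  # May..Aug


@dataclass
class SynthConfig:
    """Study conditions for one synthetic species cohort.

    Defaults describe the standard recovery cohort: 150 trees over the
    150-year span 1864-2013 with multiplicative lognormal noise of
    sigma = 0.2 on the ring-width indices.
    """

    species: str = "white_spruce"
    n_trees: int = 150
    span: tuple[int, int] = (1864, 2013)
    germination_width: int = 90   # germination years uniform over this window
    # age trend w(a) = alpha * exp(-beta a) + kappa, per-tree alpha lognormal
    alpha_mean: float = 1.8       # mm
    alpha_sigma: float = 0.12     # lognormal sigma of alpha
    beta: float = 0.03            # 1/yr
    kappa: float = 0.25           # mm
    # climate
    t_ar1_phi: float = 0.3
    t_anomaly_sigma: float = 0.9  # deg C, shared year anomaly
    t_month_sigma: float = 1.2    # deg C, independent month noise
    t_trend_onset: int = 1965
    t_trend_slope: float = 0.04   # deg C / yr after onset
    p_sigma: float = 0.55         # lognormal sigma of monthly precipitation
    # growth forcing
    t_mid_offset: float = 0.5     # sigmoid midpoint above climatological MJJA mean
    t_steepness: float = 1.5      # 1/degC (decline plays out over ~2-3 degC)
    t_floor: float = 0.5          # growth multiplier at the warm plateau
    p_lo: float = 40.0            # mm; growth limited below this August total
    p_hi: float = 80.0            # mm; saturated above this
    p_floor: float = 0.65
    t_lag_weight: float = 0.4     # previous-year temperature carry-over exponent
    p_lag_weight: float = 0.3     # previous-August precipitation carry-over
    # habitat structure
    habitat_fractions: dict = field(
        default_factory=lambda: {"good": 0.3, "neutral": 0.4, "poor": 0.3}
    )
    habitat_level: dict = field(
        default_factory=lambda: {"good": 1.1, "neutral": 1.0, "poor": 0.9}
    )
    habitat_t_sensitivity: dict = field(
        default_factory=lambda: {"good": 0.8, "neutral": 1.0, "poor": 1.3}
    )
    trees_per_plot: int = 5
    # noise and sampling artefacts
    noise_sigma: float = 0.2      # lognormal sigma of the index noise
    pith_missing_fraction: float = 0.3
    # isotopes
    iso_n_trees: int = 85
    iso_delta_base: float = 17.5       # permil, mature-ring discrimination
    iso_juvenile_depth: float = 1.5    # permil above base at age 1 (white spruce)
    iso_juvenile_tau: float = 25.0     # yr; decline mostly done by age 50-70
    iso_slow_rise: float = 0.0025      # permil / yr of ring age
    iso_period_effects: dict = field(
        default_factory=lambda: {
            "1895-1904": 0.0, "1930-1949": -0.2, "1950-1959": -0.1,
            "1993-2002": -0.3, "2003-2012": -0.2,
        }
    )
    iso_meas_sigma: float = 0.15       # permil
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("alpha_mean", "beta", "kappa", "noise_sigma",
                     "t_steepness", "p_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def paper_profile(cls, seed: int = 0) -> list["SynthConfig"]:
        """Two-species cohort at full field scale (339 + 213 trees)."""
        return [
            cls(species="white_spruce", n_trees=339, seed=seed,
                iso_juvenile_depth=1.5),
            cls(species="black_spruce", n_trees=213, seed=seed + 1,
                alpha_mean=1.0, iso_juvenile_depth=0.5),
        ]

    @classmethod
    def isotope_cohort(cls, seed: int = 0, period_effects: dict | None = None,
                       **overrides) -> "SynthConfig":
        """Cohort tailored to the isotope workflow: a 1750-2013 recruitment
        history, so every analysis period holds trees across a wide range
        of ring ages (including the held age of 100), and isotope sampling
        of 150 trees."""
        kw = dict(span=(1750, 2013), germination_width=240, iso_n_trees=150,
                  seed=seed)
        if period_effects is not None:
            kw["iso_period_effects"] = period_effects
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def ci_profile(cls, seed: int = 0) -> list["SynthConfig"]:
        """Small two-species cohort (60 trees/species) for quick runs."""
        return [
            cls(species="white_spruce", n_trees=60, seed=seed,
                iso_n_trees=40, iso_juvenile_depth=1.5),
            cls(species="black_spruce", n_trees=60, seed=seed + 1,
                alpha_mean=1.0, iso_n_trees=40, iso_juvenile_depth=0.5),
        ]


@dataclass
class CohortTruth:
    """Ground truth shipped with a generated cohort."""

    common_signal: pd.Series          # expected chronology (mean 1.0)
    class_signals: pd.DataFrame       # per-habitat-class signal (mean 1.0 each)
    curve_params: pd.DataFrame        # per-tree alpha, beta, kappa
    tree_table: pd.DataFrame          # tree -> plot, habitat class, germination
    plots: pd.DataFrame               # plot covariates incl. habitat class
    arcs: pd.DataFrame                # missing-pith arc geometry and truth


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


def generate_climate(config: SynthConfig) -> tuple[ClimateTable, pd.DataFrame]:
    """Monthly station climate: climatology + AR(1) year anomalies +
    post-onset linear warming trend; lognormal monthly precipitation.

    Returns the table and a truth frame holding the shared year anomaly
    and the trend component.
    """
    y0, y1 = config.span
    if y1 - y0 + 1 < 60:
        raise ValueError("climate span must cover at least 60 years")
    rng = _rng(config, 1)
    years = np.arange(y0, y1 + 1)
    n = years.size
    anomaly = np.empty(n)
    innov = rng.normal(0.0, config.t_anomaly_sigma, size=n)
    anomaly[0] = innov[0] / np.sqrt(1 - config.t_ar1_phi ** 2)
    for t in range(1, n):
        anomaly[t] = config.t_ar1_phi * anomaly[t - 1] + innov[t]
    trend = np.where(
        years >= config.t_trend_onset,
        (years - config.t_trend_onset) * config.t_trend_slope,
        0.0,
    )
    data = {}
    for j, m in enumerate(MONTHS):
        month_noise = rng.normal(0.0, config.t_month_sigma, size=n)
        data[f"t_{m}"] = T_CLIMATOLOGY[j] + anomaly + trend + month_noise
    for j, m in enumerate(MONTHS):
        mu = np.log(P_CLIMATOLOGY[j]) - config.p_sigma ** 2 / 2.0
        data[f"p_{m}"] = rng.lognormal(mu, config.p_sigma, size=n)
    table = ClimateTable(pd.DataFrame(data, index=pd.Index(years, name="year")))
    truth = pd.DataFrame({"year": years, "t_anomaly": anomaly, "t_trend": trend})
    return table, truth


# ---------------------------------------------------------------------------
# Growth forcing and cohort
# ---------------------------------------------------------------------------


def _forcing_components(config: SynthConfig, climate: ClimateTable):
    seas = climate.seasonal()
    t_mjja = seas["t_mjja"].to_numpy()
    p_aug = climate.data["p_aug"].to_numpy()
    t_mid = float(T_CLIMATOLOGY[_SEASON].mean()) + config.t_mid_offset
    f_t = config.t_floor + (1 - config.t_floor) * expit(
        -config.t_steepness * (t_mjja - t_mid)
    )
    ramp = np.clip((p_aug - config.p_lo) / (config.p_hi - config.p_lo), 0.0, 1.0)
    f_p = config.p_floor + (1 - config.p_floor) * ramp
    return f_t, f_p


def _class_signal(config: SynthConfig, f_t, f_p, t_sens: float) -> np.ndarray:
    log_ft = np.log(f_t) * t_sens
    log_ft_lag = np.roll(log_ft, 1) * config.t_lag_weight
    log_ft_lag[0] = log_ft[0] * config.t_lag_weight
    log_fp = np.log(f_p)
    log_fp_lag = np.roll(log_fp, 1) * config.p_lag_weight
    log_fp_lag[0] = log_fp[0] * config.p_lag_weight
    c = np.exp(log_ft + log_ft_lag + log_fp + log_fp_lag)
    return c / c.mean()


_ASPECTS = ["north", "south", "east", "west", "flat"]
_REGIONS = ["NW", "NC", "SC", "SE"]
_TOPO = ["upper", "mid", "lower", "alluvial_flat", "dry_flat", "wet_flat"]
_STAND_TYPES = ["black_spruce", "white_spruce", "paper_birch",
                "balsam_poplar", "trembling_aspen"]


def _draw_plot_covariates(rng, species: str, habitat: str) -> dict:
    """Covariates consistent with the species' good/poor threshold rules."""
    if species == "white_spruce":
        if habitat == "good":
            moss, duff = rng.uniform(5, 45), rng.uniform(1, 8)
        elif habitat == "poor":
            moss, duff = rng.uniform(55, 95), rng.uniform(12, 25)
        else:  # outside both rules
            moss, duff = rng.uniform(5, 45), rng.uniform(12, 25)
        slope = rng.uniform(0, 30)
    else:
        if habitat == "good":
            slope, moss = rng.uniform(16, 35), rng.uniform(65, 95)
        elif habitat == "poor":
            slope, moss = rng.uniform(0, 14), rng.uniform(10, 55)
        else:
            slope, moss = rng.uniform(16, 35), rng.uniform(10, 55)
        duff = rng.uniform(2, 20)
    return {
        "aspect": rng.choice(_ASPECTS),
        "basal_area": float(rng.lognormal(2.9, 0.4)),
        "duff_depth": float(duff),
        "elevation": float(rng.uniform(150, 900)),
        "litter_depth": float(rng.uniform(0.5, 6.0)),
        "moss_cover": float(moss),
        "region": rng.choice(_REGIONS),
        "slope": float(slope),
        "stand_age": float(rng.uniform(60, 200)),
        "stand_density": float(rng.lognormal(6.0, 0.5)),
        "topographic_position": rng.choice(_TOPO),
        "stand_type": species,
    }


def generate_cohort(
    config: SynthConfig, climate: ClimateTable
) -> tuple[list[RingSeries], CohortTruth]:
    """Ring-width series with known age trends, common signal and habitat.

    width(tree, y) = (alpha e^{-beta age} + kappa) * C_class(y) * level *
    eps, with eps lognormal (mean 1, sigma ``noise_sigma``).  A fraction
    of trees is truncated at the pith end to emulate cores that missed
    the pith; their arc geometry is generated from the true missing
    radius so the geometric estimate is exact by construction.
    """
    rng = _rng(config, 2)
    y0, y1 = config.span
    years = climate.years
    if years[0] > y0 or years[-1] < y1:
        raise ValueError("climate does not cover the cohort span")
    f_t, f_p = _forcing_components(config, climate)
    classes = list(config.habitat_fractions)
    probs = np.array([config.habitat_fractions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    class_sig = {
        c: _class_signal(config, f_t, f_p, config.habitat_t_sensitivity[c])
        for c in classes
    }

    n_plots = int(np.ceil(config.n_trees / config.trees_per_plot))
    plot_classes = rng.choice(classes, size=n_plots, p=probs)
    plots = []
    for i, hab in enumerate(plot_classes):
        cov = _draw_plot_covariates(rng, config.species, hab)
        cov.update(plot_id=f"P{i:03d}", habitat_class=hab)
        plots.append(cov)
    plots_df = pd.DataFrame(plots).set_index("plot_id")

    germination = rng.integers(y0, y0 + config.germination_width + 1,
                               size=config.n_trees)
    alphas = rng.lognormal(
        np.log(config.alpha_mean) - config.alpha_sigma ** 2 / 2,
        config.alpha_sigma, size=config.n_trees,
    )
    missing_pith = rng.random(config.n_trees) < config.pith_missing_fraction

    series_list, tree_rows, curve_rows, arc_rows = [], [], [], []
    year_pos = {int(y): i for i, y in enumerate(years)}
    for k in range(config.n_trees):
        tid = f"{config.species[:2].upper()}{k:04d}"
        plot_id = f"P{k // config.trees_per_plot:03d}"
        hab = plots_df.loc[plot_id, "habitat_class"]
        g = int(germination[k])
        tree_years = np.arange(g, y1 + 1)
        ages = np.arange(1, tree_years.size + 1)
        w_age = alphas[k] * np.exp(-config.beta * ages) + config.kappa
        sig = class_sig[hab][[year_pos[int(y)] for y in tree_years]]
        eps = rng.lognormal(-config.noise_sigma ** 2 / 2, config.noise_sigma,
                            size=tree_years.size)
        widths = np.round(
            w_age * sig * config.habitat_level[hab] * eps, 3
        )
        widths = np.maximum(widths, 0.001)
        pith = not missing_pith[k]
        drop = 0
        if not pith:
            drop = int(rng.integers(3, 12))
            drop = min(drop, widths.size - 15)  # keep a usable series
        if drop > 0:
            radius = float(np.sum(widths[:drop]))
            height = radius / 2.0
            chord = np.sqrt(8.0 * height * (radius - height / 2.0))
            arc_rows.append(
                {
                    "series_id": tid,
                    "chord_mm": chord,
                    "height_mm": height,
                    "true_missing_radius_mm": radius,
                    "true_missing_rings": drop,
                }
            )
            series = RingSeries(
                series_id=tid, first_year=g + drop, widths=widths[drop:],
                tree_id=tid, plot_id=plot_id, species=config.species,
                pith_present=False,
            )
        else:
            series = RingSeries(
                series_id=tid, first_year=g, widths=widths,
                tree_id=tid, plot_id=plot_id, species=config.species,
                pith_present=True,
            )
        series_list.append(series)
        tree_rows.append(
            {
                "tree_id": tid, "plot_id": plot_id, "species": config.species,
                "habitat_class": hab, "germination_year": g,
                "pith_present": pith, "rings_dropped": drop,
            }
        )
        curve_rows.append(
            {"tree_id": tid, "alpha": float(alphas[k]), "beta": config.beta,
             "kappa": config.kappa}
        )
    # realized expected chronology: per year, the mean class signal over the
    # series that cover it (this is what an unbiased chronology estimates)
    class_by_tree = {row["tree_id"]: row["habitat_class"] for row in tree_rows}
    sig_matrix = np.full((len(series_list), years.size), np.nan)
    for j, s in enumerate(series_list):
        i0 = year_pos[int(s.first_year)]
        sig_matrix[j, i0 : i0 + s.n_years] = class_sig[class_by_tree[s.tree_id]][
            i0 : i0 + s.n_years
        ]
    covered = np.any(np.isfinite(sig_matrix), axis=0)
    expected = np.full(years.size, np.nan)
    expected[covered] = np.nanmean(sig_matrix[:, covered], axis=0)
    expected = expected / np.nanmean(expected)
    common = pd.Series(expected, index=years, name="common_signal")
    truth = CohortTruth(
        common_signal=common,
        class_signals=pd.DataFrame(class_sig, index=years),
        curve_params=pd.DataFrame(curve_rows).set_index("tree_id"),
        tree_table=pd.DataFrame(tree_rows).set_index("tree_id"),
        plots=plots_df,
        arcs=pd.DataFrame(
            arc_rows,
            columns=["series_id", "chord_mm", "height_mm",
                     "true_missing_radius_mm", "true_missing_rings"],
        ).set_index("series_id"),
    )
    logger.info(
        "generated %d %s series (%d missing pith)",
        len(series_list), config.species, int(missing_pith.sum()),
    )
    return series_list, truth


# ---------------------------------------------------------------------------
# Isotopes and reference series
# ---------------------------------------------------------------------------


def synthetic_reference(start: int = 1850, end: int = 2002) -> pd.DataFrame:
    """Synthetic atmospheric d13Ca and Ca annual reference series.

    A smooth parametric stand-in for the published atmospheric record
    (this package does not redistribute it): d13Ca declines from about
    -6.3 permil in 1850 toward -8.1 permil by 2002 with an accelerating
    trend, and Ca rises from about 285 to 372 umol/mol.  Magnitudes and
    curvature match the ice-core + flask era record at the precision the
    period-mean workflow needs.
    """
    years = np.arange(start, end + 1)
    # pre-industrial plateau before 1850, accelerating change after
    u = np.clip((years - 1850) / 162.0, 0.0, None)  # 0 at 1850, 1 at 2012
    d13c_air = -6.3 - 2.2 * u ** 2.5
    ca = 284.0 + 112.0 * u ** 2.2
    return pd.DataFrame(
        {"year": years, "d13c_air": d13c_air, "ca": ca, "provenance": "synthetic"}
    )


def generate_isotopes(
    config: SynthConfig,
    series_list: Sequence[RingSeries],
    truth: CohortTruth,
    ref: pd.DataFrame,
    periods: Sequence[str] = tuple(PERIOD_LABELS),
    min_rings_in_period: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tree, per-period cellulose d13C records with known effects.

    True discrimination is base + juvenile(age) + slow-rise + period
    effect + measurement noise, where juvenile(age) =
    depth * exp(-(age-1)/tau) raises discrimination in young rings.  The
    value is converted to cellulose d13C through the inverse
    discrimination equation against the period-mean atmospheric d13Ca.
    Returns (records, truth-per-record).
    """
    rng = _rng(config, 3)
    ref_by_year = ref.set_index("year")
    tree_meta = truth.tree_table
    n_pick = min(config.iso_n_trees, len(series_list))
    pick = rng.choice(len(series_list), size=n_pick, replace=False)
    rec_rows, truth_rows = [], []
    for i in pick:
        s = series_list[i]
        drop = int(tree_meta.loc[s.tree_id, "rings_dropped"])
        hab = tree_meta.loc[s.tree_id, "habitat_class"]
        for label in periods:
            lo, hi = period_bounds(label)
            in_period = (s.years >= lo) & (s.years <= hi)
            if in_period.sum() < min_rings_in_period:
                continue
            # true mean cambial age of the pooled rings
            ages = (s.years[in_period] - s.first_year + 1) + drop
            ring_age = float(ages.mean())
            juvenile = config.iso_juvenile_depth * np.exp(
                -(ring_age - 1.0) / config.iso_juvenile_tau
            )
            delta_true = (
                config.iso_delta_base
                + juvenile
                + config.iso_slow_rise * ring_age
                + config.iso_period_effects.get(label, 0.0)
            )
            delta = delta_true + rng.normal(0.0, config.iso_meas_sigma)
            period_years = np.arange(lo, hi + 1)
            d13ca = float(ref_by_year.loc[period_years, "d13c_air"].mean())
            d13c = d13c_tree_from_discrimination(delta, d13ca)
            rec_rows.append(
                {
                    "tree_id": s.tree_id, "species": s.species, "period": label,
                    "d13c": float(d13c), "ring_age": ring_age,
                    "habitat_class": hab,
                }
            )
            truth_rows.append(
                {
                    "tree_id": s.tree_id, "period": label,
                    "delta13c_true": float(delta_true),
                    "juvenile_component": float(juvenile),
                    "period_effect": config.iso_period_effects.get(label, 0.0),
                }
            )
    return pd.DataFrame(rec_rows), pd.DataFrame(truth_rows)


def habitat_table(truth: CohortTruth, recent_rwi: pd.DataFrame) -> pd.DataFrame:
    """Join per-tree recent mean growth index onto plot covariates."""
    t = truth.tree_table.join(recent_rwi, how="inner")
    return t.merge(
        truth.plots.drop(columns="habitat_class"),
        left_on="plot_id", right_index=True,
    )
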