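"""Habitat controls on recent growth and habitat-stratified climate response.

Per-tree ring-width indices are averaged over a recent decade and related
to plot locational and structural covariates with the same boosted
regression tree engine used for the climate analysis.  Plots are then
classed as good or poor habitat per species using fixed thresholds on the
most influential covariates (moss cover and duff depth for white spruce,
slope and moss cover for black spruce), and chronologies built separately
for the strata are correlated with the monthly climate variables.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .brt import BRTConfig, BRTResult, fit_brt
from .climate import MONTHLY_VARIABLES, static_correlations
from .detrend import RCSResult, subgroup_chronology
from .ringio import RingSeries

logger = logging.getLogger(__name__)

__all__ = [
    "HABITAT_NUMERIC",
    "HABITAT_CATEGORICAL",
    "recent_mean_rwi",
    "brt_habitat_model",
    "classify_habitat",
    "stratified_climate_sensitivity",
]

HABITAT_NUMERIC = [
    "basal_area", "duff_depth", "elevation", "litter_depth", "moss_cover",
    "slope", "stand_age", "stand_density", "delta13c",
]
HABITAT_CATEGORICAL = ["aspect", "region", "topographic_position", "stand_type"]

RECENT_SPAN = (2003, 2012)


def recent_mean_rwi(
    indices_by_tree: Mapping[str, pd.Series],
    span: tuple[int, int] = RECENT_SPAN,
) -> pd.DataFrame:
    """Per-tree mean ring-width index over the recent span.

    Trees with no index years in the span are excluded with a log entry.
    Returns columns ``mean_recent_rwi`` and ``n_years``.
    """
    rows = []
    for tree, idx in indices_by_tree.items():
        sub = idx[(idx.index >= span[0]) & (idx.index <= span[1])].dropna()
        if sub.empty:
            logger.info("tree %s has no rings in %d-%d; excluded", tree, *span)
            continue
        rows.append(
            {"tree_id": tree, "mean_recent_rwi": float(sub.mean()), "n_years": len(sub)}
        )
    return pd.DataFrame(rows).set_index("tree_id")


def brt_habitat_model(
    records: pd.DataFrame,
    target: str = "mean_recent_rwi",
    config: BRTConfig | None = None,
) -> BRTResult:
    """BRT of recent growth on habitat covariates.

    Same engine and contract as the climate model; categorical predictors
    are handled natively (one-hot encoded, influence re-aggregated per
    variable).  Constant predictors are dropped with a warning.
    """
    predictors = [
        c for c in HABITAT_NUMERIC + HABITAT_CATEGORICAL if c in records.columns
    ]
    X = records[predictors].copy()
    for c in HABITAT_CATEGORICAL:
        if c in X.columns:
            X[c] = X[c].astype("object")
    return fit_brt(X, records[target], config)


def classify_habitat(record: Mapping, species: str) -> str:
    """Good/poor/unclassified habitat from fixed covariate thresholds.

    White spruce: good when moss cover < 50% and duff depth < 10 cm; poor
    when moss cover > 50% and duff depth > 10 cm.  Black spruce: good when
    slope > 15% and moss cover > 60%; poor when slope < 15% and moss
    cover < 60%.  Any other combination, boundary equality, or a missing
    field yields ``unclassified``.
    """

    def get(name):
        v = record.get(name) if hasattr(record, "get") else record[name]
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    try:
        if species == "white_spruce":
            moss, duff = get("moss_cover"), get("duff_depth")
            if moss is None or duff is None:
                logger.info("missing moss/duff; unclassified")
                return "unclassified"
            if moss < 50 and duff < 10:
                return "good"
            if moss > 50 and duff > 10:
                return "poor"
        elif species == "black_spruce":
            slope, moss = get("slope"), get("moss_cover")
            if slope is None or moss is None:
                logger.info("missing slope/moss; unclassified")
                return "unclassified"
            if slope > 15 and moss > 60:
                return "good"
            if slope < 15 and moss < 60:
                return "poor"
        else:
            raise ValueError(f"unknown species {species!r}")
    except KeyError:
        return "unclassified"
    return "unclassified"


def stratified_climate_sensitivity(
    series_list: Sequence[RingSeries],
    variables: pd.DataFrame,
    classification: Mapping[str, str],
    species: Sequence[str] = ("white_spruce", "black_spruce"),
    min_n: int = 25,
    truncation_n: int | None = None,
    span: tuple[int, int] | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
    variable_subset: Sequence[str] = tuple(MONTHLY_VARIABLES),
) -> tuple[pd.DataFrame, dict[tuple[str, str], RCSResult]]:
    """Climate correlations of good/poor habitat chronologies per species.

    ``classification`` maps tree id to habitat class.  For each species x
    habitat stratum with at least ``min_n`` trees, a signal-free RCS
    chronology is built and correlated (with bootstrap significance)
    against the monthly climate variables.  Undersized strata are omitted
    with a warning.  Returns a tidy grid (species, habitat, variable, r,
    significant) and the stratum chronologies.
    """
    rows = []
    chronologies: dict[tuple[str, str], RCSResult] = {}
    for sp in species:
        for habitat in ("good", "poor"):

            def pick(s: RingSeries, sp=sp, habitat=habitat) -> bool:
                return s.species == sp and classification.get(s.tree_id) == habitat

            count = sum(pick(s) for s in series_list)
            if count < min_n:
                logger.warning(
                    "stratum %s/%s has %d trees (< %d); column omitted",
                    sp, habitat, count, min_n,
                )
                continue
            result = subgroup_chronology(
                series_list, pick, min_n=min_n, truncation_n=truncation_n,
                n_boot=0, seed=seed,
            )
            chronologies[(sp, habitat)] = result
            corr = static_correlations(
                result.chronology, variables[list(variable_subset)],
                span=span, n_boot=n_boot, seed=seed,
            )
            for var, row in corr.iterrows():
                rows.append(
                    {
                        "species": sp,
                        "habitat": habitat,
                        "variable": var,
                        "r": row["r"],
                        "significant": bool(row["significant"]),
                    }
                )
    return pd.DataFrame(rows), chronologies
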