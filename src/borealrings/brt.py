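"""Boosted regression tree engine shared by the climate and habitat analyses.

Wraps scikit-learn gradient boosting with the conventions ecologists use
with gbm/dismo: shallow trees (tree complexity 2), a slow learning rate,
stochastic bagging, the number of trees chosen by cross-validation up to
a cap, relative influence normalized to sum to 100, one-dimensional
partial dependence, and a pairwise interaction screen (Friedman's H^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = ["BRTConfig", "BRTResult", "fit_brt", "partial_dependence", "interaction_screen"]


@dataclass
class BRTConfig:
    tree_complexity: int = 2        # max tree depth (two-way interactions)
    learning_rate: float = 0.001
    bag_fraction: float = 0.5
    max_trees: int = 30000
    min_trees: int = 1000           # BRT convention: <1000 trees is unreliable
    cv_folds: int = 10
    min_rows: int = 50
    seed: int = 0


@dataclass
class BRTResult:
    model: GradientBoostingRegressor
    n_trees: int
    relative_influence: pd.Series     # per original variable, sums to 100
    r2: float                         # variance explained on training data
    cv_mse: np.ndarray                # mean CV MSE per number of trees
    feature_map: dict[str, list[str]] # original variable -> encoded columns
    X: pd.DataFrame = field(repr=False, default=None)  # encoded training frame


def _encode(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode non-numeric columns, remembering the grouping."""
    feature_map: dict[str, list[str]] = {}
    parts = []
    for col in X.columns:
        if pd.api.types.is_numeric_dtype(X[col]):
            feature_map[col] = [col]
            parts.append(X[[col]].astype(float))
        else:
            dummies = pd.get_dummies(X[col], prefix=col).astype(float)
            feature_map[col] = list(dummies.columns)
            parts.append(dummies)
    return pd.concat(parts, axis=1), feature_map


def fit_brt(X: pd.DataFrame, y: pd.Series, config: BRTConfig | None = None) -> BRTResult:
    """Fit a gradient-boosted regression with CV-selected tree count.

    Complete-case rows only; refuses fewer than ``config.min_rows`` rows.
    Constant predictors are dropped with a warning.
    """
    config = config or BRTConfig()
    data = pd.concat([X, y.rename("_target_")], axis=1).dropna()
    if len(data) < config.min_rows:
        raise ValueError(
            f"only {len(data)} complete rows; at least {config.min_rows} required"
        )
    Xc = data.drop(columns="_target_")
    constant = [c for c in Xc.columns if Xc[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant predictors: %s", constant)
        Xc = Xc.drop(columns=constant)
    yv = data["_target_"].to_numpy()
    Xe, feature_map = _encode(Xc)
    Xm = Xe.to_numpy()

    def make(n_estimators):
        return GradientBoostingRegressor(
            n_estimators=n_estimators,
            learning_rate=config.learning_rate,
            max_depth=config.tree_complexity,
            subsample=config.bag_fraction,
            random_state=config.seed,
        )

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    cv_mse = np.zeros(config.max_trees)
    for train, test in kf.split(Xm):
        model = make(config.max_trees).fit(Xm[train], yv[train])
        for stage, pred in enumerate(model.staged_predict(Xm[test])):
            cv_mse[stage] += np.mean((yv[test] - pred) ** 2)
    cv_mse /= config.cv_folds
    n_trees = int(np.argmin(cv_mse)) + 1
    n_trees = min(max(n_trees, config.min_trees), config.max_trees)
    model = make(n_trees).fit(Xm, yv)
    r2 = float(model.score(Xm, yv))
    raw = pd.Series(model.feature_importances_, index=Xe.columns)
    influence = pd.Series(
        {var: raw[cols].sum() for var, cols in feature_map.items()}
    ).sort_values(ascending=False)
    total = influence.sum()
    influence = influence * (100.0 / total) if total > 0 else influence
    logger.info("BRT: %d trees (CV), training R^2 = %.3f", n_trees, r2)
    return BRTResult(model, n_trees, influence, r2, cv_mse, feature_map, Xe)


def partial_dependence(
    result: BRTResult, variable: str, grid_size: int = 50
) -> pd.DataFrame:
    """Marginal response to one variable, others averaged over the data.

    Numeric variables are evaluated on an evenly spaced grid across the
    observed range; categorical variables at each level.
    """
    cols = result.feature_map[variable]
    Xe = result.X.copy()
    rows = []
    if len(cols) == 1 and not cols[0].startswith(f"{variable}_"):
        values = np.linspace(Xe[cols[0]].min(), Xe[cols[0]].max(), grid_size)
        for v in values:
            Xe[cols[0]] = v
            rows.append({"value": v, "response": float(result.model.predict(Xe.to_numpy()).mean())})
    else:
        for col in cols:
            for c in cols:
                Xe[c] = 0.0
            Xe[col] = 1.0
            level = col[len(variable) + 1:]
            rows.append({"value": level, "response": float(result.model.predict(Xe.to_numpy()).mean())})
    return pd.DataFrame(rows)


def interaction_screen(
    result: BRTResult,
    variables: list[str] | None = None,
    sample_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Friedman H^2 statistic for each variable pair (numeric variables).

    Estimated on a subsample of rows: the two-way partial dependence is
    compared with the sum of the one-way partial dependences; H^2 is the
    fraction of the two-way variance not explained additively.  Values
    near 0 indicate additive effects.
    """
    if variables is None:
        variables = [
            v for v, cols in result.feature_map.items()
            if len(cols) == 1 and not cols[0].startswith(f"{v}_")
        ]
        variables = [v for v in result.relative_influence.index if v in variables][:5]
    rng = np.random.default_rng(seed)
    Xe = result.X
    idx = rng.choice(len(Xe), size=min(sample_size, len(Xe)), replace=False)
    sample = Xe.iloc[idx].reset_index(drop=True)
    m = len(sample)

    def pd_vals(fix_cols):
        out = np.empty(m)
        for i in range(m):
            Xmod = Xe.copy()
            for c in fix_cols:
                Xmod[c] = sample.at[i, c]
            out[i] = result.model.predict(Xmod.to_numpy()).mean()
        return out - out.mean()

    rows = []
    cache = {v: pd_vals(result.feature_map[v]) for v in variables}
    for a, b in combinations(variables, 2):
        joint = pd_vals(result.feature_map[a] + result.feature_map[b])
        resid = joint - cache[a] - cache[b]
        denom = float(np.sum(joint ** 2))
        h2 = float(np.sum(resid ** 2) / denom) if denom > 0 else 0.0
        rows.append({"var_a": a, "var_b": b, "h2": h2})
    return pd.DataFrame(rows).sort_values("h2", ascending=False).reset_index(drop=True)
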