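"""Climate variable construction, correlation analyses and the BRT engine."""

import numpy as np
import pandas as pd
import pytest

from borealrings import synth
from borealrings.brt import BRTConfig
from borealrings.climate import (
    ClimateTable,
    MONTHS,
    build_variable_set,
    brt_climate_model,
    is_precip_variable,
    log_precip,
    low_frequency_test,
    moving_correlations,
    static_correlations,
)


@pytest.fixture(scope="module")
def climate_table():
    table, _ = synth.generate_climate(synth.SynthConfig(seed=21))
    return table


@pytest.fixture(scope="module")
def variables(climate_table):
    return build_variable_set(climate_table)


# ---------------------------------------------------------------------------
# Tables and variable sets
# ---------------------------------------------------------------------------


def test_winter_total_spans_year_boundary():
    years = np.arange(2000, 2003)
    data = {f"t_{m}": np.zeros(3) for m in MONTHS}
    data.update({f"p_{m}": np.zeros(3) for m in MONTHS})
    df = pd.DataFrame(data, index=years)
    df.loc[2000, "p_oct"] = 30.0   # October 2000 belongs to winter 2001
    df.loc[2001, "p_jan"] = 12.0
    seas = ClimateTable(df).seasonal()
    assert seas.loc[2001, "p_oct_apr"] == pytest.approx(42.0)
    assert np.isnan(seas.loc[2000, "p_oct_apr"])  # no previous October


def test_previous_year_variables_lagged_exactly_one_year(climate_table, variables):
    d = climate_table.data
    assert np.allclose(
        variables["t_prev_jul"].iloc[1:], d["t_jul"].iloc[:-1], equal_nan=True
    )


def test_negative_precipitation_rejected(climate_table):
    bad = climate_table.data.copy()
    bad.iloc[0, bad.columns.get_loc("p_jun")] = -1.0
    with pytest.raises(ValueError, match="negative"):
        ClimateTable(bad)


def test_log_transform_flags_precip_only(variables):
    precip = [v for v in variables.columns if is_precip_variable(v)]
    temp = [v for v in variables.columns if not is_precip_variable(v)]
    assert all(v.startswith("p_") for v in precip)
    assert all(v.startswith("t_") for v in temp)
    assert log_precip(0.0) == pytest.approx(np.log(0.1))


# ---------------------------------------------------------------------------
# Static and moving correlations
# ---------------------------------------------------------------------------


def test_self_correlation_is_one_and_significant(climate_table, variables):
    years = variables.dropna().index
    chron = pd.Series(variables.loc[years, "t_jul"].to_numpy(), index=years)
    out = static_correlations(chron, variables[["t_jul"]], n_boot=300, seed=0)
    assert out.loc["t_jul", "r"] == pytest.approx(1.0)
    assert bool(out.loc["t_jul", "significant"])


def test_constant_variable_reported_missing(climate_table, variables):
    years = variables.dropna().index
    chron = pd.Series(np.random.default_rng(0).normal(size=len(years)), index=years)
    vs = variables.copy()
    vs["t_jul"] = 5.0
    out = static_correlations(chron, vs[["t_jul"]], n_boot=100, seed=0)
    assert np.isnan(out.loc["t_jul", "r"])
    assert not bool(out.loc["t_jul", "significant"])


def test_insufficient_overlap_rejected(variables):
    chron = pd.Series(1.0, index=np.arange(2000, 2010))
    with pytest.raises(ValueError, match="overlap"):
        static_correlations(chron, variables, n_boot=100, seed=0)


def test_full_length_window_equals_static(climate_table, variables):
    rng = np.random.default_rng(1)
    years = variables.dropna().index
    chron = pd.Series(rng.normal(size=len(years)), index=years)
    static = static_correlations(chron, variables[["t_jun", "p_aug"]],
                                 n_boot=100, seed=0)
    moving = moving_correlations(chron, variables[["t_jun", "p_aug"]],
                                 window=len(years), n_boot=100, seed=0)
    assert len(moving) == 2
    for var in ("t_jun", "p_aug"):
        got = moving.loc[moving["variable"] == var, "r"].iloc[0]
        assert got == pytest.approx(static.loc[var, "r"], abs=1e-12)


def test_moving_r_matches_slice_oracle(climate_table, variables):
    rng = np.random.default_rng(2)
    years = variables.dropna().index
    chron = pd.Series(
        0.4 * variables.loc[years, "t_jul"].to_numpy() + rng.normal(size=len(years)),
        index=years,
    )
    window = 25
    moving = moving_correlations(chron, variables[["t_jul", "p_aug"]],
                                 window=window, n_boot=0, seed=0)
    yv = chron.to_numpy()
    for var in ("t_jul", "p_aug"):
        xv = variables.loc[years, var].to_numpy()
        if is_precip_variable(var):
            xv = log_precip(xv)
        sub = moving[moving["variable"] == var].reset_index(drop=True)
        for i, row in sub.iterrows():
            sl = slice(i, i + window)
            oracle = np.corrcoef(xv[sl], yv[sl])[0, 1]
            assert row["r"] == pytest.approx(oracle, abs=1e-12)


def test_window_longer_than_record_rejected(variables):
    chron = pd.Series(1.0, index=variables.dropna().index)
    with pytest.raises(ValueError, match="window"):
        moving_correlations(chron, variables, window=10_000)


def test_identical_series_every_window_r_one(climate_table, variables):
    years = variables.dropna().index
    chron = pd.Series(variables.loc[years, "t_may"].to_numpy(), index=years)
    moving = moving_correlations(chron, variables[["t_may"]], window=25,
                                 n_boot=0, seed=0)
    assert np.allclose(moving["r"], 1.0)


def test_null_significance_rate_near_nominal():
    rng = np.random.default_rng(9)
    n = 98
    hits = 0
    trials = 400
    from borealrings.climate import _bootstrap_significant

    for _ in range(trials):
        hits += _bootstrap_significant(
            rng.normal(size=n), rng.normal(size=n), 400, rng
        )
    rate = hits / trials
    assert 0.02 <= rate <= 0.08  # 5% within Monte-Carlo slack at 400 trials


# ---------------------------------------------------------------------------
# Low-frequency variation test
# ---------------------------------------------------------------------------


def test_constant_moving_r_gives_p_one():
    rng = np.random.default_rng(4)
    x = rng.normal(size=98)
    p = low_frequency_test(2.0 * x, x, window=25, n_boot=200, seed=0)
    assert p == 1.0


def test_sign_flip_detected():
    rng = np.random.default_rng(5)
    n = 98
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    y = 0.5 * x + np.sqrt(1 - 0.25) * e
    y[n // 2:] = -0.5 * x[n // 2:] + np.sqrt(1 - 0.25) * e[n // 2:]
    p = low_frequency_test(y, x, window=25, n_boot=300, seed=0)
    assert p < 0.05


def test_stationary_relation_rarely_rejected():
    rng = np.random.default_rng(6)
    n = 98
    rejections = 0
    reps = 40
    for _ in range(reps):
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(0.75) * rng.normal(size=n)
        p = low_frequency_test(y, x, window=25, n_boot=200,
                               seed=int(rng.integers(2 ** 31)))
        rejections += p < 0.05
    assert rejections / reps <= 0.10


def test_low_frequency_test_refuses_small_nboot():
    x = np.random.default_rng(0).normal(size=98)
    with pytest.raises(ValueError, match="n_boot"):
        low_frequency_test(x, x, n_boot=50)


# ---------------------------------------------------------------------------
# Boosted regression trees
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def brt_config():
    return BRTConfig(learning_rate=0.02, max_trees=800, cv_folds=5, seed=0)


def test_informative_predictor_ranked_first(brt_config):
    rng = np.random.default_rng(7)
    n = 150
    X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(6)})
    y = pd.Series(1.5 * X["x3"] + 0.3 * rng.normal(size=n))
    result = brt_climate_model(y, X, brt_config)
    assert result.relative_influence.index[0] == "x3"
    assert result.relative_influence.sum() == pytest.approx(100.0, abs=1e-6)


def test_sigmoid_response_partial_dependence_monotone(brt_config):
    from borealrings.brt import partial_dependence
    from scipy.special import expit

    rng = np.random.default_rng(8)
    n = 300
    X = pd.DataFrame({"t": rng.normal(15, 1.5, n), "noise": rng.normal(size=n)})
    y = pd.Series(expit(-2.0 * (X["t"] - 15)) + 0.03 * rng.normal(size=n))
    # learning rate slow enough that the CV optimum exceeds the 1000-tree
    # floor, per standard BRT practice
    result = brt_climate_model(
        y, X, BRTConfig(learning_rate=0.005, max_trees=3000, cv_folds=5, seed=0)
    )
    curve = partial_dependence(result, "t")["response"].to_numpy()
    rises = np.diff(curve).clip(min=0).sum()
    total_range = curve.max() - curve.min()
    assert rises <= 0.02 * total_range  # monotone non-increasing within 2%


def test_brt_refuses_few_rows(brt_config):
    X = pd.DataFrame({"a": np.arange(10.0)})
    y = pd.Series(np.arange(10.0))
    with pytest.raises(ValueError, match="rows"):
        brt_climate_model(y, X, brt_config)


def test_interaction_screen_low_for_additive_truth(brt_config):
    from borealrings.brt import fit_brt, interaction_screen

    rng = np.random.default_rng(10)
    n = 200
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    y = pd.Series(X["a"] + X["b"] + 0.1 * rng.normal(size=n))
    result = fit_brt(X, y, brt_config)
    h2 = interaction_screen(result, ["a", "b"], sample_size=30)
    assert h2["h2"].iloc[0] < 0.1
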