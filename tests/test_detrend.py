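"""RCS grouping, regional curves, robust chronologies and signal-free iteration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealrings.detrend import (
    assign_rcs_groups,
    biweight_mean,
    build_chronology,
    fit_regional_curve,
    ratio_indices,
    signal_free_rcs,
    single_pass_rcs,
    subgroup_chronology,
)
from borealrings.ringio import RingSeries
from borealrings.robust import biweight_rows


def _cohort(n, rng, first_years=None, signal=None, alpha=1.5, noise=0.0):
    """Small synthetic cohort with a shared negative-exponential age trend."""
    series = []
    for k in range(n):
        g = int(first_years[k]) if first_years is not None else 1900
        years = np.arange(g, 2014)
        ages = np.arange(1, years.size + 1)
        w = alpha * np.exp(-0.03 * ages) + 0.3
        if signal is not None:
            w = w * signal.loc[years].to_numpy()
        if noise > 0:
            w = w * rng.lognormal(-noise ** 2 / 2, noise, size=years.size)
        series.append(
            RingSeries(series_id=f"T{k:03d}", first_year=g, widths=np.maximum(w, 1e-3))
        )
    return series


# ---------------------------------------------------------------------------
# Tukey biweight
# ---------------------------------------------------------------------------


def _biweight_oracle(values, c=9.0):
    """Independent direct iteration of the biweight weighting formula."""
    x = np.asarray(values, dtype=float)
    if x.size == 1:
        return float(x[0])
    med = float(np.median(x))
    if x.size <= 3:
        return med
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        return med
    t = med
    for _ in range(200):
        u = (x - t) / (c * mad)
        keep = np.abs(u) < 1
        w = np.zeros_like(x)
        w[keep] = (1 - u[keep] ** 2) ** 2
        if w.sum() == 0:
            return med
        t_next = float(np.sum(w * x) / np.sum(w))
        if abs(t_next - t) < 1e-9:
            return t_next
        t = t_next
    return t


@pytest.mark.parametrize(
    "values, expected",
    [([1.0, 1.0, 1.0], 1.0), ([0.8, 1.0, 1.2], 1.0), ([5.0], 5.0)],
)
def test_biweight_trivial_cases(values, expected):
    assert biweight_mean(values) == pytest.approx(expected)


def test_biweight_downweights_outlier():
    vals = [0.9, 1.0, 1.1, 1.0, 5.0]
    m = biweight_mean(vals)
    assert 0.9 < m < 1.1
    assert m < np.mean(vals)


def test_biweight_matches_independent_iteration(rng):
    for _ in range(300):
        n = int(rng.integers(1, 40))
        x = rng.normal(0, 1, n)
        if rng.random() < 0.3 and n > 4:
            x[: max(1, n // 10)] += rng.choice([-1, 1]) * 10  # contaminate
        assert biweight_mean(x) == pytest.approx(_biweight_oracle(x), abs=1e-9)


@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1, max_size=50))
@settings(max_examples=100, deadline=None)
def test_biweight_bounded_by_extremes(values):
    m = biweight_mean(values)
    assert min(values) - 1e-12 <= m <= max(values) + 1e-12


def test_biweight_rows_matches_scalar(rng):
    m = rng.normal(size=(50, 17))
    rows = biweight_rows(m)
    for i in range(50):
        assert rows[i] == pytest.approx(biweight_mean(m[i]), abs=1e-9)


def test_biweight_empty_rejected():
    with pytest.raises(ValueError):
        biweight_mean([])


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n, requested, expected_groups",
    [(200, 4, 4), (100, 4, 2), (30, 4, 1), (41, 1, 1)],
)
def test_group_count_rule(n, requested, expected_groups, rng):
    series = _cohort(n, rng, noise=0.3)
    groups = assign_rcs_groups(series, requested)
    assert groups.nunique() == expected_groups
    # partition: every series in exactly one group, sizes near-equal
    assert len(groups) == n
    sizes = groups.value_counts()
    assert sizes.max() - sizes.min() <= 1


def test_groups_track_growth_rate(rng):
    fast = _cohort(50, rng, alpha=3.0, noise=0.05)
    slow = _cohort(50, rng, alpha=0.8, noise=0.05)
    for i, s in enumerate(slow):
        s.series_id = f"SLOW{i}"
    series = fast + slow
    groups = assign_rcs_groups(series, 2, min_group_size=40)
    fast_groups = {groups[s.series_id] for s in fast}
    slow_groups = {groups[s.series_id] for s in slow}
    assert fast_groups == {1} and slow_groups == {0}


# ---------------------------------------------------------------------------
# Regional curve and indices
# ---------------------------------------------------------------------------


def test_identical_cohort_curve_matches_series(rng):
    series = _cohort(10, rng)
    curve = fit_regional_curve(series)
    expected = 1.5 * np.exp(-0.03 * curve.ages) + 0.3
    # spline endpoints allowed ~1% play
    assert np.allclose(curve.expected_width, expected, rtol=0.01)


def test_curve_recovery_under_noise(rng):
    series = _cohort(100, rng, first_years=rng.integers(1880, 1920, 100),
                     alpha=2.0, noise=0.05)
    for s in series:
        s.widths = (2.0 * np.exp(-0.03 * s.cambial_ages) + 0.2) * rng.lognormal(
            -0.05 ** 2 / 2, 0.05, s.n_years
        )
    curve = fit_regional_curve(series)
    truth = 2.0 * np.exp(-0.03 * curve.ages) + 0.2
    ok = curve.n_per_age >= 20
    rel = (curve.expected_width[ok] - truth[ok]) / truth[ok]
    assert np.sqrt(np.mean(rel ** 2)) < 0.05


def test_negexp_curve_recovers_parameters(rng):
    series = _cohort(60, rng, noise=0.02)
    curve = fit_regional_curve(series, method="negexp")
    truth = 1.5 * np.exp(-0.03 * curve.ages) + 0.3
    assert np.allclose(curve.expected_width, truth, rtol=0.02)


def test_ratio_indices_values():
    s = RingSeries(series_id="A", first_year=2000, widths=np.array([0.6, 0.4, 0.002]))
    curve = fit_regional_curve([RingSeries(series_id="B", first_year=2000,
                                           widths=np.array([0.4, 0.4, 0.001]))])
    idx = ratio_indices(s, curve)
    assert idx.loc[2000] == pytest.approx(0.6 / curve.expected_width[0])
    assert (idx > 0).all()


def test_ratio_indices_age_outside_support_errors():
    long = RingSeries(series_id="A", first_year=1990, widths=np.full(20, 0.5))
    short_curve = fit_regional_curve(
        [RingSeries(series_id="B", first_year=2000, widths=np.full(5, 0.5))]
    )
    with pytest.raises(ValueError, match="age"):
        ratio_indices(long, short_curve)


# ---------------------------------------------------------------------------
# Chronology
# ---------------------------------------------------------------------------


def test_identical_trees_chronology_equals_series(rng):
    years = np.arange(1950, 2014)
    vals = rng.lognormal(0, 0.2, years.size)
    indices = {f"T{k}": pd.Series(vals, index=years) for k in range(5)}
    chron = build_chronology(indices, truncation_n=5, n_boot=200, rng=rng)
    expected = vals / vals.mean()
    assert np.allclose(chron.index, expected)
    assert np.allclose(chron.ci_low, chron.index)  # zero spread across trees
    assert np.allclose(chron.ci_high, chron.index)


def test_single_tree_chronology_rescaled(rng):
    years = np.arange(1990, 2014)
    vals = rng.lognormal(0, 0.2, years.size)
    chron = build_chronology({"T0": pd.Series(vals, index=years)},
                             truncation_n=1, n_boot=0, rng=rng)
    assert np.allclose(chron.index, vals / vals.mean())
    assert abs(chron.index.mean() - 1.0) < 1e-9


def test_truncation_removes_shallow_ends(rng):
    idx = {
        "A": pd.Series(1.0, index=np.arange(1900, 2014)),
        "B": pd.Series(1.0, index=np.arange(1950, 2014)),
    }
    chron = build_chronology(idx, truncation_n=2, n_boot=0, rng=rng)
    assert chron.years[0] == 1950
    assert (chron.sample_depth >= 2).all()


def test_no_year_reaching_threshold_gives_empty(rng):
    idx = {"A": pd.Series(1.0, index=np.arange(2000, 2010))}
    chron = build_chronology(idx, truncation_n=5, n_boot=0, rng=rng)
    assert chron.empty


def test_chronology_signal_recovery(recovery_cohort):
    cfg, climate, series, truth = recovery_cohort
    result = signal_free_rcs(series, seed=0, n_boot=0)
    chron = result.chronology
    target = truth.common_signal.loc[chron.years].to_numpy()
    target = target / target.mean()
    assert np.corrcoef(chron.index, target)[0, 1] >= 0.9


# ---------------------------------------------------------------------------
# Signal-free iteration
# ---------------------------------------------------------------------------


def test_flat_truth_converges_fast(rng):
    series = _cohort(60, rng, first_years=rng.integers(1880, 1950, 60), noise=0.1)
    result = signal_free_rcs(series, truncation_n=30, seed=0, n_boot=0)
    assert result.converged
    assert result.iterations <= 3
    assert np.all(np.abs(result.chronology.index - 1.0) < 0.15)


def test_bump_recovery_beats_single_pass(rng):
    years = np.arange(1864, 2014)
    bump = 1 + 0.3 * np.exp(-0.5 * ((years - 1940) / 10.0) ** 2)
    signal = pd.Series(bump / bump.mean(), index=years)
    series = _cohort(150, rng, first_years=rng.integers(1864, 1980, 150),
                     signal=signal, noise=0.1)
    sf = signal_free_rcs(series, seed=0, n_boot=0)
    sp = single_pass_rcs(series, seed=0, n_boot=0)

    def bump_amplitude(chron):
        t = signal.loc[chron.years].to_numpy()
        peak = np.searchsorted(chron.years, 1940)
        return chron.index[peak] - np.median(chron.index)

    true_amp = 0.3 / bump.mean()
    assert abs(bump_amplitude(sf.chronology) - true_amp) / true_amp < 0.15
    assert (true_amp - bump_amplitude(sp.chronology)) / true_amp > 0.25


def test_signal_free_idempotent_on_converged_output(recovery_cohort):
    cfg, climate, series, truth = recovery_cohort
    first = signal_free_rcs(series, seed=0, n_boot=0)
    again = signal_free_rcs(series, seed=0, n_boot=0)
    assert np.array_equal(first.chronology.index, again.chronology.index)
    if first.converged:
        assert first.index_deltas[-1] < 0.002


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------


def test_subgroup_with_all_trees_equals_global(recovery_cohort):
    cfg, climate, series, truth = recovery_cohort
    full = signal_free_rcs(series, truncation_n=50, seed=0, n_boot=0)
    sub = subgroup_chronology(series, lambda s: True, min_n=25,
                              truncation_n=50, seed=0, n_boot=0)
    assert np.allclose(full.chronology.index, sub.chronology.index)


def test_subgroup_level_difference_preserved(rng):
    a = _cohort(40, rng, first_years=rng.integers(1880, 1960, 40), noise=0.05)
    b = _cohort(40, rng, first_years=rng.integers(1880, 1960, 40), noise=0.05)
    for s in b:
        s.series_id = "B" + s.series_id
        s.widths = s.widths * np.where(s.years >= 1970, 1.2, 1.0)
    both = a + b
    ca = subgroup_chronology(both, lambda s: not s.series_id.startswith("B"),
                             min_n=25, truncation_n=25, seed=0, n_boot=0)
    cb = subgroup_chronology(both, lambda s: s.series_id.startswith("B"),
                             min_n=25, truncation_n=25, seed=0, n_boot=0)

    def post_over_pre(res):
        ch = res.chronology
        post = ch.index[ch.years >= 1970].mean()
        pre = ch.index[ch.years < 1970].mean()
        return post / pre

    # chronologies are mean-1 over their own spans, so the injected 1.2x
    # post-1970 elevation shows up in the post/pre contrast of B relative to A
    assert post_over_pre(cb) / post_over_pre(ca) == pytest.approx(1.2, rel=0.05)


def test_subgroup_too_small_refused(recovery_cohort):
    cfg, climate, series, truth = recovery_cohort
    with pytest.raises(ValueError, match="0 trees"):
        subgroup_chronology(series, lambda s: False, min_n=25)
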