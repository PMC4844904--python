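"""Correlation filter, p-value transform, and the MCFS / A-MCFS plans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vocalvote import (
    FeatureSelectionResult,
    SyntheticSpec,
    build_selection_plan,
    feature_frequencies,
    generate,
    pearson_r,
    r_to_pvalue,
    select_features,
    separate_by_test,
)
from vocalvote.feature_selection import ConstantVectorError
from vocalvote.preprocessing import VocalTestSubset


# -- pearson_r --------------------------------------------------------------

@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 0, 0, 1], 0.0),
    ],
)
def test_pearson_r_known_values(x, y, expected):
    assert pearson_r(np.array(x), np.array(y)) == pytest.approx(expected, abs=1e-12)


def test_pearson_r_constant_vector_degenerate():
    with pytest.raises(ConstantVectorError):
        pearson_r(np.array([2.0, 2.0, 2.0]), np.array([0.0, 1.0, 0.0]))


def test_pearson_matches_scipy():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(40)
    y = np.array([1.0] * 20 + [0.0] * 20)
    r_ref, p_ref = stats.pearsonr(x, y)
    assert pearson_r(x, y) == pytest.approx(r_ref, abs=1e-12)
    assert r_to_pvalue(pearson_r(x, y), 40) == pytest.approx(p_ref, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=4, max_size=20),
    st.floats(0.1, 50),
    st.floats(-10, 10),
    st.integers(0, 2**31 - 1),
)
def test_pearson_symmetry_and_affine_invariance(xs, slope, shift, seed):
    x = np.asarray(xs)
    y = np.random.default_rng(seed).standard_normal(len(x))
    try:
        r = pearson_r(x, y)
    except ConstantVectorError:
        return
    assert pearson_r(y, x) == pytest.approx(r, abs=1e-9)
    assert pearson_r(slope * x + shift, y) == pytest.approx(r, abs=1e-6)


# -- r_to_pvalue ------------------------------------------------------------

def test_pvalue_boundaries():
    assert r_to_pvalue(0.0, 40) == pytest.approx(1.0)
    assert r_to_pvalue(1.0, 10) == 0.0
    assert r_to_pvalue(-1.0, 10) == 0.0
    with pytest.raises(ValueError):
        r_to_pvalue(0.5, 2)


def test_pvalue_monotone_in_abs_r():
    rs = np.linspace(0, 0.99, 50)
    ps = [r_to_pvalue(r, 40) for r in rs]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert r_to_pvalue(-0.4, 40) == pytest.approx(r_to_pvalue(0.4, 40))


def test_critical_r_at_n40():
    """The smallest selectable |r| at n=40 brackets the df=38 two-sided 5% point."""
    r_crit = None
    t_crit = stats.t.ppf(0.975, df=38)
    expected = t_crit / np.sqrt(38 + t_crit**2)
    assert r_to_pvalue(expected * 1.001, 40) < 0.05 < r_to_pvalue(expected * 0.999, 40)
    r_crit = expected
    assert 0.30 < r_crit < 0.32


# -- select_features --------------------------------------------------------

def subset_from_matrix(matrix, labels):
    matrix = np.asarray(matrix, dtype=float)
    return VocalTestSubset(
        1, matrix, np.asarray(labels), tuple(f"S{i}" for i in range(matrix.shape[0]))
    )


def test_perfect_separator_selected():
    labels = np.array([1] * 5 + [0] * 5)
    rng = np.random.default_rng(1)
    m = rng.standard_normal((10, 4))
    m[:, 2] = labels
    res = select_features(subset_from_matrix(m, labels))
    assert 3 in res.selected_features
    assert res.correlations[2].p_value < 1e-6


def test_alpha_zero_is_unsuccessful():
    labels = np.array([1] * 5 + [0] * 5)
    m = np.random.default_rng(2).standard_normal((10, 3))
    res = select_features(subset_from_matrix(m, labels), alpha=0.0)
    assert not res.successful


def test_constant_feature_never_selected():
    labels = np.array([1] * 5 + [0] * 5)
    m = np.random.default_rng(3).standard_normal((10, 2))
    m[:, 0] = 7.0
    res = select_features(subset_from_matrix(m, labels), alpha=1.0)
    assert 1 not in res.selected_features
    assert np.isnan(res.correlations[0].r)


def test_selection_scale_invariant():
    labels = np.array([1] * 8 + [0] * 8)
    m = np.random.default_rng(4).standard_normal((16, 5))
    base = select_features(subset_from_matrix(m, labels))
    scaled = select_features(subset_from_matrix(m * 13.7 + 4.2, labels))
    assert base.selected_features == scaled.selected_features


def test_power_on_strong_effect():
    """A 2-SD shifted feature at n=40 passes the filter in >= 95% of seeds."""
    hits = 0
    for seed in range(100):
        spec = SyntheticSpec(
            n_subjects=40, n_tests=1, n_features=3,
            informative_tests=frozenset({1}), informative_features=frozenset({1}),
            effect=2.0, seed=seed,
        )
        subset = separate_by_test(generate(spec))[0]
        if 1 in select_features(subset).selected_features:
            hits += 1
    assert hits >= 95


# -- frequencies and plans --------------------------------------------------

def res(test_id, feats, n_features=6):
    return FeatureSelectionResult(test_id, tuple(feats))


def test_feature_frequencies_counts():
    results = [res(1, [2, 4]), res(2, [2]), res(3, [])]
    freqs = feature_frequencies(results)
    assert freqs[2] == 2 and freqs[4] == 1
    assert sum(freqs.values()) == 3


def test_feature_frequencies_empty():
    assert all(v == 0 for v in feature_frequencies([res(1, []), res(2, [])]).values())


def test_amcfs_drops_unsuccessful():
    plan = build_selection_plan([res(1, [2]), res(2, []), res(3, [5])], mode="a-mcfs")
    assert set(plan.per_test_features) == {1, 3}


def test_amcfs_identity_when_all_successful():
    results = [res(1, [2]), res(2, [3, 4])]
    plan = build_selection_plan(results, mode="a-mcfs")
    assert plan.per_test_features == {1: (2,), 2: (3, 4)}


def test_mcfs_fallback_truncates_to_available():
    plan = build_selection_plan([res(1, [7]), res(2, []), res(3, [])], mode="mcfs", fallback_k=4)
    assert plan.fallback_features == (7,)
    assert plan.per_test_features[2] == (7,) and plan.per_test_features[3] == (7,)
    assert plan.per_test_features[1] == (7,)


def test_mcfs_fallback_ranking_and_tie_break():
    results = [res(1, [2, 4, 9]), res(2, [2, 9]), res(3, [4]), res(4, []), res(5, [6])]
    plan = build_selection_plan(results, mode="mcfs", fallback_k=3)
    # counts: 2->2, 9->2, 4->2, 6->1; tie among {2,4,9} broken by lower index
    assert plan.fallback_features == (2, 4, 9)


def test_mcfs_all_unsuccessful_is_error():
    with pytest.raises(ValueError):
        build_selection_plan([res(1, []), res(2, [])], mode="mcfs")


def test_amcfs_tests_subset_of_mcfs(study_table):
    from vocalvote import select_features as sf, zscore_normalize

    results = [sf(zscore_normalize(s)) for s in separate_by_test(study_table)]
    a = build_selection_plan(results, mode="a-mcfs")
    m = build_selection_plan(results, mode="mcfs")
    assert set(a.per_test_features) <= set(m.per_test_features)
    for t, feats in a.per_test_features.items():
        assert m.per_test_features[t] == feats
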