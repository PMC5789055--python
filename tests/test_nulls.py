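"""Resampling null models against closed-form and enumeration oracles."""

import numpy as np
import pytest

from spinedyn.nulls import (null_cluster_positional, null_cluster_uniform,
                            null_concordance, null_nnd_turnover,
                            summarize_null)

from conftest import make_map, spine

R = 10000


def mc_se(nd):
    return nd.gaussian_sigma / np.sqrt(nd.R)


def single_segment_map(spines, length=50.0):
    return make_map({"a1": [(length, spines)]})


def test_uniform_null_matches_closed_form():
    """P(|U1 - U2| <= d) = 1 - (1 - d/L)^2 for two uniform positions."""
    m = single_segment_map([spine("n1", 10, (0, 0, 1)),
                            spine("n2", 30, (0, 0, 1))])
    nd = null_cluster_uniform(m, d=5.0, R=R, seed=11, min_formed=0)
    expected = 100.0 * (1 - (1 - 5 / 50) ** 2)
    assert abs(nd.gaussian_mu - expected) <= 3 * mc_se(nd)


def test_uniform_null_single_spine_contributes_zero():
    m = make_map({"a1": [(50.0, [spine("n1", 10, (0, 0, 1)),
                                 spine("n2", 30, (0, 0, 1))]),
                         (40.0, [spine("n3", 5, (0, 0, 1))])]})
    nd = null_cluster_uniform(m, d=5.0, R=500, seed=0, min_formed=0)
    # the singleton segment can never produce a clustered spine, so the
    # per-resample clustered count is at most 2 of 3 new spines
    assert nd.values.max() <= 100.0 * 2 / 3 + 1e-9


def test_uniform_null_threshold_covering_segment_gives_100():
    m = single_segment_map([spine("n1", 10, (0, 0, 1)),
                            spine("n2", 30, (0, 0, 1))])
    nd = null_cluster_uniform(m, d=50.0, R=200, seed=1, min_formed=0)
    assert np.all(nd.values == 100.0)


def test_uniform_null_without_new_spines_errors():
    m = single_segment_map([spine("b", 10, (1, 1, 1))])
    with pytest.raises(ValueError):
        null_cluster_uniform(m, R=10, seed=0, min_formed=0)


def test_positional_null_matches_enumeration():
    """4 candidates {0,2,20,40}, k=2: only {0,2} clusters -> mean 1/6."""
    m = single_segment_map([spine("n1", 0, (0, 0, 1)),
                            spine("n2", 2, (0, 0, 1)),
                            spine("c1", 20, (1, 1, 1)),
                            spine("c2", 40, (1, 1, 1))])
    nd = null_cluster_positional(m, d=5.0, R=R, seed=12, min_formed=0)
    assert abs(nd.gaussian_mu - 100 / 6) <= 3 * mc_se(nd)


def test_positional_null_all_candidates_close_gives_100():
    m = single_segment_map([spine("n1", 0, (0, 0, 1)),
                            spine("n2", 2, (0, 0, 1)),
                            spine("c1", 4, (1, 1, 1))])
    nd = null_cluster_positional(m, d=5.0, R=300, seed=0, min_formed=0)
    assert np.all(nd.values == 100.0)


def test_nnd_null_matches_quarter_length():
    """E|U - L/2| = L/4 for a clustered spine at mid-segment."""
    L = 50.0
    m = single_segment_map([spine("n1", 25, (0, 0, 1)),
                            spine("n2", 25, (0, 0, 1)),   # coincident pair
                            spine("t1", 5, (1, 0, 0))], length=L)
    nd = null_nnd_turnover(m, "uniform", d=5.0, R=R, seed=13, min_formed=0)
    assert abs(nd.gaussian_mu - L / 4) <= 3 * mc_se(nd)


def test_nnd_null_positional_single_candidate_degenerate():
    """With spines at a single shared locus the positional NND null is 0."""
    m = single_segment_map([spine("n1", 10, (0, 0, 1)),
                            spine("n2", 10, (0, 0, 1)),
                            spine("t1", 10, (1, 0, 0))])
    nd = null_nnd_turnover(m, "positional", d=5.0, R=100, seed=0, min_formed=0)
    assert np.all(nd.values == 0.0) and nd.observed == 0.0


def test_concordance_null_matches_enumeration():
    """c=(1,0,0), t=(1,0,0): E[both%] over permutations = 100/9."""
    segs = [
        (50.0, [spine("n1", 10, (0, 0, 1)), spine("n2", 12, (0, 0, 1)),
                spine("t1", 30, (1, 0, 0))]),
        (50.0, [spine("b1", 10, (1, 1, 1))]),
        (50.0, [spine("b2", 10, (1, 1, 1))]),
    ]
    nds = null_concordance(make_map({"a1": segs}), d=5.0, R=R, seed=14,
                           min_formed=0)
    both = nds["both"]
    # per permutation both% is 100/3 with prob 1/3 else 0
    assert abs(both.gaussian_mu - 100 / 9) <= 3 * mc_se(both)
    assert both.observed == pytest.approx(100 / 3)
    p_expected = 1 / 3  # concordant permutations
    frac_at_obs = np.mean(both.values >= both.observed - 1e-9)
    assert abs(frac_at_obs - p_expected) <= 3 * np.sqrt(p_expected * (1 - p_expected) / R)


def test_concordance_all_cluster_counts_zero_is_constant():
    segs = [
        (50.0, [spine("t1", 10, (1, 0, 0)), spine("b", 20, (1, 1, 1))]),
        (50.0, [spine("b2", 10, (1, 1, 1))]),
    ]
    nds = null_concordance(make_map({"a1": segs}), R=50, seed=0, min_formed=0)
    for nd in nds.values():
        assert np.ptp(nd.values) == 0.0


def test_same_seed_reproduces_bitwise(synthetic_map):
    m, _ = synthetic_map
    a = null_cluster_uniform(m, R=100, seed=7)
    b = null_cluster_uniform(m, R=100, seed=7)
    assert np.array_equal(a.values, b.values) and a.observed == b.observed


def test_summarize_null_empirical_p_rules():
    vals = np.arange(10000, dtype=float)
    beyond = summarize_null(vals, observed=2e4, sidedness="one")
    assert beyond.p_empirical == pytest.approx(1 / 10001)
    const = summarize_null(np.full(100, 5.0), observed=5.0)
    assert const.p_empirical == 1.0 and not const.degenerate
    degen = summarize_null(np.full(100, 5.0), observed=7.0)
    assert degen.degenerate and degen.p_empirical == pytest.approx(1 / 101)
    mid = summarize_null(vals, observed=float(np.median(vals)), sidedness="one")
    assert mid.p_empirical == pytest.approx(0.5, abs=0.01)


def test_per_resample_percentages_bounded(synthetic_map):
    m, _ = synthetic_map
    nd = null_cluster_uniform(m, R=300, seed=3)
    assert np.all((nd.values >= 0) & (nd.values <= 100))
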