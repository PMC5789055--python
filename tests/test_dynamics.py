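"""Turnover, clustering, NND, KS, survival, and behavior statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn.dynamics import (cluster_new_spines, ks_two_sample,
                               learning_rate, nnd, segment_densities,
                               suppression_ratio, survival_rate,
                               turnover_ratio)

from conftest import SCHEDULE_5, make_map, spine


def two_session_map(n_stable, n_formed, n_lost, length=100.0):
    spines = []
    pos = iter(np.linspace(1, length - 1, n_stable + n_formed + n_lost))
    for i in range(n_stable):
        spines.append(spine(f"st{i}", next(pos), (1, 1, 1)))
    for i in range(n_formed):
        spines.append(spine(f"f{i}", next(pos), (0, 1, 1)))
    for i in range(n_lost):
        spines.append(spine(f"l{i}", next(pos), (1, 0, 0)))
    return make_map({"a1": [(length, spines)]})


@pytest.mark.parametrize("stable,formed,lost,expected", [
    (9, 1, 1, 2 / 20),   # 10 spines each session, 1 formed + 1 lost
    (10, 0, 0, 0.0),     # identical sessions
    (0, 5, 5, 1.0),      # full replacement
])
def test_turnover_ratio_formula(stable, formed, lost, expected):
    m = two_session_map(stable, formed, lost)
    t = turnover_ratio(m.animals["a1"], -3, 0)
    assert t.ratio == pytest.approx(expected)
    assert t.n_formed == formed and t.n_lost == lost


def test_turnover_empty_is_undefined():
    m = make_map({"a1": [(50.0, [spine("x", 1.0, (0, 0, 1))])]})
    with pytest.raises(ZeroDivisionError):
        turnover_ratio(m.animals["a1"], -3, 0)


def new_spine_segment(positions, length=60.0, extra=()):
    spines = [spine(f"n{i}", p, (0, 0, 1)) for i, p in enumerate(positions)]
    spines += [spine(f"e{i}", p, (1, 1, 1)) for i, p in enumerate(extra)]
    m = make_map({"a1": [(length, spines)]})
    return m.animals["a1"].segments[0]


@pytest.mark.parametrize("positions,n_clustered,sizes", [
    ((1.0, 3.0, 20.0), 2, (2,)),      # pair at 2 um, singleton at 17/19 um
    ((7.0,), 0, ()),                   # single spine cannot cluster
    ((0.0, 4.0, 8.0), 3, (3,)),       # chained transitive component
])
def test_cluster_components(positions, n_clustered, sizes):
    asg = cluster_new_spines(new_spine_segment(positions), d=5.0)
    assert asg.n_clustered == n_clustered
    assert tuple(sorted(len(c) for c in asg.clusters)) == tuple(sorted(sizes))
    assert asg.n_new == len(positions)


def test_cluster_threshold_is_inclusive():
    asg = cluster_new_spines(new_spine_segment((0.0, 5.0)), d=5.0)
    assert asg.n_clustered == 2


@given(st.lists(st.floats(0, 60), min_size=1, max_size=12),
       st.floats(0.5, 10))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_cluster_ratio_reflection_invariant(positions, d):
    """Clustering is unchanged by reflecting the position axis."""
    seg = new_spine_segment(positions)
    ref = new_spine_segment([60.0 - p for p in positions])
    a, b = cluster_new_spines(seg, d), cluster_new_spines(ref, d)
    assert a.n_clustered == b.n_clustered
    assert sorted(len(c) for c in a.clusters) == sorted(len(c) for c in b.clusters)


def test_cluster_degenerate_thresholds():
    seg = new_spine_segment((3.0, 17.0, 42.0))
    assert cluster_new_spines(seg, d=0.0).n_clustered == 0
    assert cluster_new_spines(seg, d=60.0).n_clustered == 3


@pytest.mark.parametrize("src,tgt,self_excl,expected", [
    ((0, 4, 12), (0, 4, 12), True, (4, 4, 8)),
    ((), (1, 2), False, ()),
    ((10,), (7, 30), False, (3,)),
])
def test_nnd_examples(src, tgt, self_excl, expected):
    res = nnd(src, tgt, exclude_self=self_excl)
    assert res.distances == pytest.approx(expected)


def test_ks_examples():
    x = [1.0, 2.0, 3.0]
    assert ks_two_sample(x, x)[0] == 0.0
    assert ks_two_sample([1, 2], [5, 6])[0] == 1.0
    d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
    assert d == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        ks_two_sample([], x)


@given(st.lists(st.integers(-100, 100), min_size=2, max_size=15),
       st.lists(st.integers(-100, 100), min_size=2, max_size=15))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_ks_invariant_under_common_monotone_transform(x, y):
    d1, _ = ks_two_sample(x, y)
    f = lambda v: [np.exp(t / 50.0) for t in v]
    d2, _ = ks_two_sample(f(x), f(y))
    assert d1 == pytest.approx(d2)


def survival_map(cl_present, ncl_present):
    """4 new spines: clustered pair at 1,3; singletons at 30, 50."""
    spines = [
        spine("c1", 1.0, (0, 0, 1, 1, cl_present[0])),
        spine("c2", 3.0, (0, 0, 1, 1, cl_present[1])),
        spine("u1", 30.0, (0, 0, 1, 1, ncl_present[0])),
        spine("u2", 50.0, (0, 0, 1, 1, ncl_present[1])),
    ]
    return make_map({"a1": [(60.0, spines)]}, schedule=SCHEDULE_5)


def test_survival_rates_per_cohort():
    m = survival_map((1, 0), (0, 0))
    a = m.animals["a1"]
    assert survival_rate(a, "clustered", 35) == 0.5
    assert survival_rate(a, "non-clustered", 35) == 0.0
    m2 = survival_map((1, 1), (1, 1))
    assert survival_rate(m2.animals["a1"], "clustered", 35) == 1.0


def test_survival_union_is_weighted_mean():
    m = survival_map((1, 0), (1, 0))
    a = m.animals["a1"]
    s_cl = survival_rate(a, "clustered", 35)
    s_ncl = survival_rate(a, "non-clustered", 35)
    union = (2 * s_cl + 2 * s_ncl) / 4
    assert union == pytest.approx(0.5)


def test_survival_empty_cohort_errors():
    m = survival_map((1, 1), (1, 1))
    spines = m.animals["a1"].segments[0].spines
    for sp in spines[2:]:
        sp.fate = None  # leave only the clustered pair as new spines
    with pytest.raises(ZeroDivisionError):
        survival_rate(m.animals["a1"], "non-clustered", 35)


def test_segment_densities():
    spines = [spine("l1", 5.0, (1, 0, 0)), spine("f1", 12.0, (0, 1, 1)),
              spine("n1", 20.0, (0, 0, 1)), spine("n2", 23.0, (0, 0, 1)),
              spine("n3", 27.0, (0, 0, 1))]
    m = make_map({"a1": [(40.0, spines)]})
    d = segment_densities(m.animals["a1"].segments[0])
    assert d["turnover_density"] == pytest.approx(2 / 40)
    assert d["cluster_density"] == pytest.approx(3 / 40)


@pytest.mark.parametrize("trace,expected", [
    ({0: 10, 1: 25, 2: 40, 3: 55, 4: 60}, 12.5),
    ({0: 20, 1: 20, 2: 20}, 0.0),
    ({0: 10, 1: 30, 2: 50, 3: 40, 4: 70}, 20.0),  # first max at day 2
])
def test_learning_rate(trace, expected):
    assert learning_rate(trace) == pytest.approx(expected)


def test_learning_rate_requires_baseline():
    with pytest.raises(ValueError):
        learning_rate({1: 10, 2: 20})


@pytest.mark.parametrize("test,base,expected", [
    (0.0, 5.0, 0.0), (3.0, 3.0, 0.5), (2.0, 6.0, 0.25),
])
def test_suppression_ratio(test, base, expected):
    assert suppression_ratio(test, base) == pytest.approx(expected)


def test_suppression_both_zero_undefined():
    with pytest.raises(ZeroDivisionError):
        suppression_ratio(0.0, 0.0)
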