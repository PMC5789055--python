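"""Engram readouts of the network simulator.

Synapse-pair clustering fractions, new-synapse clustering, Treves-Rolls
population sparsity, and the linear-trend statistic used to summarize how
these readouts scale with the number of high-turnover dendritic subunits.

Positions are only comparable within one dendritic subunit, so "total
number of synapse pairs" means all same-subunit pairs, aggregated over
subunits and neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "clustered_pair_fraction",
    "new_pair_fraction",
    "treves_rolls_sparsity",
    "linear_trend",
    "TrendResult",
]


def _pair_counts(neuron, subunit, pos, select, radius) -> tuple[int, int]:
    """(selected pairs closer than radius, all same-subunit pairs)."""
    comp = np.asarray(neuron, dtype=np.int64) * (np.max(subunit) + 1 if len(subunit) else 1) \
        + np.asarray(subunit, dtype=np.int64)
    pos = np.asarray(pos, dtype=float)
    select = np.asarray(select, dtype=bool)
    total = clustered = 0
    for c in np.unique(comp):
        idx = np.flatnonzero(comp == c)
        k = idx.size
        total += k * (k - 1) // 2
        sel = idx[select[idx]]
        if sel.size >= 2:
            ps = pos[sel]
            d = np.abs(ps[:, None] - ps[None, :])
            clustered += int(np.count_nonzero(np.triu(d < radius, k=1)))
    return clustered, total


def clustered_pair_fraction(network, w_thresh: float = 0.8,
                            radius: float = 0.2) -> float:
    """Fraction of same-subunit synapse pairs that are potentiated clusters.

    Numerator: pairs of potentiated synapses (w > ``w_thresh``) on the same
    subunit with position difference < ``radius``; denominator: all
    same-subunit pairs, aggregated over the population.
    """
    syn = network.syn
    num, den = _pair_counts(syn.neuron, syn.subunit, syn.pos,
                            syn.w > w_thresh, radius)
    if den == 0:
        raise ZeroDivisionError("no same-subunit synapse pairs")
    return num / den


def new_pair_fraction(network, birth_cutoff: int = 1,
                      radius: float = 0.2) -> float:
    """Fraction of same-subunit pairs that are clustered *new* synapses.

    New = inserted after simulated day ``birth_cutoff`` (the first encoding
    day).  Same denominator as :func:`clustered_pair_fraction`.
    """
    syn = network.syn
    num, den = _pair_counts(syn.neuron, syn.subunit, syn.pos,
                            syn.birth_day > birth_cutoff, radius)
    if den == 0:
        raise ZeroDivisionError("no same-subunit synapse pairs")
    return num / den


def treves_rolls_sparsity(rates) -> float:
    """Treves-Rolls population sparsity a = (mean r)^2 / mean(r^2).

    1 for uniform rates, 1/N for a single active neuron; lower values mean
    sparser engrams.  Scale-invariant.
    """
    r = np.asarray(rates, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("rates must be a non-empty 1-D vector")
    if np.all(r == 0):
        raise ValueError("all-zero rate vector: sparsity undefined")
    return float((r.mean() ** 2) / np.mean(r ** 2))


@dataclass(frozen=True)
class TrendResult:
    slope: float        # least-squares slope of y on x
    intercept: float
    r2: float           # of the regression over all points
    F_anova: float      # one-way ANOVA across levels
    p_anova: float
    F_trend: float      # post-test for linear trend (single-df contrast)
    p_trend: float


def linear_trend(levels, groups) -> TrendResult:
    """One-way ANOVA with post-test for linear trend across ordered levels.

    ``levels`` are the x values (>= 3 levels); ``groups`` the per-level
    samples (>= 2 each).  The trend post-test uses the contrast with
    centered level coefficients, L = sum(c_i * mean_i), tested on 1 and
    N - k degrees of freedom against the within-group mean square.  The
    slope and r^2 come from the least-squares regression over all points.
    """
    x = np.asarray(levels, dtype=float)
    ys = [np.asarray(g, dtype=float) for g in groups]
    if len(x) < 3 or len(ys) != len(x):
        raise ValueError("need >= 3 levels with one sample per level")
    if any(len(g) < 2 for g in ys):
        raise ValueError("need >= 2 values per level")
    ns = np.array([len(g) for g in ys])
    means = np.array([g.mean() for g in ys])
    N, k = int(ns.sum()), len(x)
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in ys))
    df_within = N - k
    ms_within = ss_within / df_within
    if np.ptp(x) == 0:
        raise ValueError("degenerate level values: all x equal")
    xs_all = np.concatenate([np.full(n, xi) for xi, n in zip(x, ns)])
    ys_all = np.concatenate(ys)
    reg = sstats.linregress(xs_all, ys_all)
    if ms_within == 0:
        if np.ptp(ys_all) == 0:
            # globally constant response: no trend by definition
            return TrendResult(slope=0.0, intercept=float(means[0]), r2=0.0,
                               F_anova=0.0, p_anova=1.0, F_trend=0.0,
                               p_trend=1.0)
        # noiseless separation between levels: trend F diverges
        return TrendResult(slope=float(reg.slope), intercept=float(reg.intercept),
                           r2=float(reg.rvalue ** 2), F_anova=np.inf,
                           p_anova=0.0, F_trend=np.inf, p_trend=0.0)
    F_anova, p_anova = sstats.f_oneway(*ys)
    c = x - x.mean()
    L = float((c * means).sum())
    ss_trend = L ** 2 / float((c ** 2 / ns).sum())
    F_trend = ss_trend / ms_within
    p_trend = float(sstats.f.sf(F_trend, 1, df_within))
    return TrendResult(slope=float(reg.slope), intercept=float(reg.intercept),
                       r2=float(reg.rvalue ** 2),
                       F_anova=float(F_anova), p_anova=float(p_anova),
                       F_trend=float(F_trend), p_trend=p_trend)
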