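"""Monte-Carlo and permutation null models for spine clustering statistics.

Four resampling schemes, each yielding a :class:`NullDistribution` of a
scalar statistic under a randomized-position null:

* :func:`null_cluster_uniform` - new-spine positions redrawn uniformly along
  each segment; statistic = grand mean over animals of the per-animal
  clustering percentage.
* :func:`null_cluster_positional` - new-spine *identity* permuted: positions
  drawn without replacement from each segment's ever-observed spine
  positions, so resampled spines can only sit where spines are known to
  occur.
* :func:`null_nnd_turnover` - pre-learning turnover positions randomized
  (uniform or positional variant); statistic = mean nearest-neighbor
  distance from each clustered spine to the nearest turnover position,
  averaged per animal then across animals.
* :func:`null_concordance` - per animal, the vector of clustered-spine
  counts is permuted across segments while turnover counts stay fixed;
  statistic = percentage of segments in each of the four
  turnover x clustering categories.

Empirical p-values use the add-one estimator (1 + #{at least as extreme}) /
(R + 1); a Gaussian moment fit (mean, SD of the resamples) is carried for
display parity with the usual histogram-plus-fit figures.  All randomness
comes from a single seeded numpy Generator, so a fixed seed reproduces the
distribution bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import SpineMap
from .dynamics import (
    MIN_FORMED_FOR_CLUSTERING,
    _n_formed_learning,
    cluster_new_spines,
    clustered_spine_ids,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "summarize_null",
    "null_cluster_uniform",
    "null_cluster_positional",
    "null_nnd_turnover",
    "null_concordance",
]


@dataclass(frozen=True)
class NullDistribution:
    """Observed statistic plus its resampled null distribution."""

    statistic: str
    observed: float
    values: np.ndarray
    seed: int | None
    sidedness: str = "one"
    degenerate: bool = field(default=False)

    @property
    def R(self) -> int:
        return len(self.values)

    @property
    def gaussian_mu(self) -> float:
        return float(np.mean(self.values))

    @property
    def gaussian_sigma(self) -> float:
        return float(np.std(self.values))

    @property
    def p_empirical(self) -> float:
        return _empirical_p(self.values, self.observed, self.sidedness)


def _empirical_p(values: np.ndarray, observed: float, sidedness: str) -> float:
    mu = float(np.mean(values))
    if sidedness == "two":
        extreme = np.abs(values - mu) >= abs(observed - mu)
    elif sidedness == "one":
        if observed >= mu:
            extreme = values >= observed
        else:
            extreme = values <= observed
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    return (1 + int(np.count_nonzero(extreme))) / (len(values) + 1)


def summarize_null(values, observed: float, sidedness: str = "one",
                   statistic: str = "statistic",
                   seed: int | None = None) -> NullDistribution:
    """Wrap raw resamples into a :class:`NullDistribution`.

    The Gaussian fit is moments-based (mean, SD); the p-value is the add-one
    empirical estimator.  A zero-variance null with observed != mean is
    flagged degenerate (its p saturates at 1/(R+1)).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 resamples to summarize a null")
    degenerate = bool(np.std(values) == 0.0 and observed != np.mean(values))
    if degenerate:
        logger.warning("degenerate null: zero variance, observed %.4g != mean %.4g",
                       observed, float(np.mean(values)))
    return NullDistribution(statistic=statistic, observed=float(observed),
                           values=values, seed=seed, sidedness=sidedness,
                           degenerate=degenerate)


# ---------------------------------------------------------------------------
# shared helpers

def _eligible_animals(spine_map: SpineMap, min_formed: int):
    out = []
    for animal in spine_map:
        if _n_formed_learning(animal) >= min_formed:
            out.append(animal)
    return out


def _clustered_counts_1d(pos: np.ndarray, d: float) -> np.ndarray:
    """Per-row count of points having a neighbor within d, for (R, k) rows."""
    if pos.shape[1] < 2:
        return np.zeros(pos.shape[0], dtype=np.int64)
    s = np.sort(pos, axis=1)
    gaps = np.diff(s, axis=1) <= d
    # a point is clustered iff the gap to its left or right neighbor is <= d
    left = np.concatenate([np.zeros((pos.shape[0], 1), bool), gaps], axis=1)
    right = np.concatenate([gaps, np.zeros((pos.shape[0], 1), bool)], axis=1)
    return np.count_nonzero(left | right, axis=1)


def _sample_without_replacement(rng, candidates: np.ndarray, k: int,
                                R: int) -> np.ndarray:
    """(R, k) positions drawn without replacement from the candidate set."""
    m = len(candidates)
    idx = np.argsort(rng.random((R, m)), axis=1)[:, :k]
    return candidates[idx]


# ---------------------------------------------------------------------------
# clustering nulls

def _animal_cluster_layout(animal, d):
    """(segments' (L, k, candidates), n_new, observed clustered count)."""
    segs = []
    n_new = n_clustered = 0
    for seg in animal.segments:
        asg = cluster_new_spines(seg, d)
        n_new += asg.n_new
        n_clustered += asg.n_clustered
        if asg.n_new >= 1:
            candidates = np.array([sp.position for sp in seg.spines], dtype=float)
            segs.append((seg.length, asg.n_new, candidates))
    return segs, n_new, n_clustered


def _null_cluster(spine_map: SpineMap, d: float, R: int, seed, min_formed: int,
                  positional: bool) -> NullDistribution:
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    per_animal_null = []
    per_animal_obs = []
    for animal in _eligible_animals(spine_map, min_formed):
        segs, n_new, n_clustered = _animal_cluster_layout(animal, d)
        if n_new == 0:
            continue
        counts = np.zeros(R, dtype=np.int64)
        for length, k, candidates in segs:
            if positional:
                if k > len(candidates):
                    raise ValueError(
                        f"segment of animal {animal.animal_id}: {k} resampled "
                        f"spines exceed {len(candidates)} candidate positions")
                pos = _sample_without_replacement(rng, candidates, k, R)
            else:
                pos = rng.uniform(0.0, length, size=(R, k))
            counts += _clustered_counts_1d(pos, d)
        per_animal_null.append(100.0 * counts / n_new)
        per_animal_obs.append(100.0 * n_clustered / n_new)
    if not per_animal_null:
        raise ValueError("no animal with new stable spines: clustering null undefined")
    values = np.mean(per_animal_null, axis=0)
    observed = float(np.mean(per_animal_obs))
    name = "clustering_pct_positional" if positional else "clustering_pct_uniform"
    return summarize_null(values, observed, sidedness="one",
                          statistic=name, seed=seed)


def null_cluster_uniform(spine_map: SpineMap, d: float = 5.0, R: int = 10000,
                         seed: int | None = None,
                         min_formed: int = MIN_FORMED_FOR_CLUSTERING) -> NullDistribution:
    """Clustering percentage under uniformly redrawn new-spine positions.

    Per resample and segment, k i.i.d. uniform positions on [0, L] replace
    the segment's k new stable spines; the per-animal clustering percentage
    is recomputed (counts pooled over segments) and averaged across animals.
    """
    return _null_cluster(spine_map, d, R, seed, min_formed, positional=False)


def null_cluster_positional(spine_map: SpineMap, d: float = 5.0, R: int = 10000,
                            seed: int | None = None,
                            min_formed: int = MIN_FORMED_FOR_CLUSTERING) -> NullDistribution:
    """Clustering percentage with new-spine identity permuted.

    Resampled positions are drawn without replacement from each segment's
    full set of ever-observed spine positions, confining the null to loci
    that demonstrably support spines.
    """
    return _null_cluster(spine_map, d, R, seed, min_formed, positional=True)


# ---------------------------------------------------------------------------
# NND-to-turnover null

def null_nnd_turnover(spine_map: SpineMap, variant: str = "uniform",
                      d: float = 5.0, R: int = 10000,
                      seed: int | None = None,
                      min_formed: int = MIN_FORMED_FOR_CLUSTERING) -> NullDistribution:
    """Mean clustered-spine-to-turnover NND under randomized turnover sites.

    Per resample and segment, the segment's pre-learning turnover positions
    are redrawn (``variant="uniform"``: i.i.d. uniform on [0, L];
    ``"positional"``: without replacement from ever-observed positions); each
    clustered spine's distance to the nearest redrawn position is recorded,
    per-spine values are averaged within animal, then across animals.
    """
    if variant not in ("uniform", "positional"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    per_animal_null = []
    per_animal_obs = []
    for animal in _eligible_animals(spine_map, min_formed):
        clustered = clustered_spine_ids(animal, d)
        seg_null = []   # per segment: (R, c) resampled NNDs
        seg_obs = []    # per segment: (c,) observed NNDs
        for seg in animal.segments:
            cpos = np.array([sp.position for sp in seg.spines
                             if sp.spine_id in clustered], dtype=float)
            tpos = np.array([sp.position for sp in seg.spines
                             if sp.fate is not None and sp.fate.baseline_turnover],
                            dtype=float)
            if cpos.size == 0 or tpos.size == 0:
                continue
            m = tpos.size
            if variant == "uniform":
                rand = rng.uniform(0.0, seg.length, size=(R, m))
            else:
                candidates = np.array([sp.position for sp in seg.spines], dtype=float)
                rand = _sample_without_replacement(rng, candidates, m, R)
            # (R, m, c) -> min over turnover positions
            diff = np.abs(rand[:, :, None] - cpos[None, None, :])
            seg_null.append(diff.min(axis=1))
            seg_obs.append(np.abs(tpos[:, None] - cpos[None, :]).min(axis=0))
        if not seg_null:
            continue
        per_animal_null.append(np.concatenate(seg_null, axis=1).mean(axis=1))
        per_animal_obs.append(float(np.concatenate(seg_obs).mean()))
    if not per_animal_null:
        raise ValueError("no segment with both clustered and turnover spines")
    values = np.mean(per_animal_null, axis=0)
    observed = float(np.mean(per_animal_obs))
    return summarize_null(values, observed, sidedness="one",
                          statistic=f"mean_nnd_um_{variant}", seed=seed)


# ---------------------------------------------------------------------------
# concordance null

_CATEGORIES = ("both", "neither", "turnover_only", "cluster_only")


def _category_percentages(c: np.ndarray, t: np.ndarray) -> dict[str, np.ndarray]:
    """Percentages of segments per category; inputs (..., n_seg)."""
    n_seg = c.shape[-1]
    has_c = c > 0
    has_t = t > 0
    return {
        "both": 100.0 * np.count_nonzero(has_c & has_t, axis=-1) / n_seg,
        "neither": 100.0 * np.count_nonzero(~has_c & ~has_t, axis=-1) / n_seg,
        "turnover_only": 100.0 * np.count_nonzero(~has_c & has_t, axis=-1) / n_seg,
        "cluster_only": 100.0 * np.count_nonzero(has_c & ~has_t, axis=-1) / n_seg,
    }


def null_concordance(spine_map: SpineMap, d: float = 5.0, R: int = 10000,
                     seed: int | None = None,
                     min_formed: int = MIN_FORMED_FOR_CLUSTERING) -> dict[str, NullDistribution]:
    """Segment-category percentages under within-animal permutation.

    Each segment is categorized by presence of pre-learning turnover and of
    learning-related clustered spines ("both", "neither", "turnover_only",
    "cluster_only").  The null permutes each animal's vector of
    clustered-spine counts across its segments, leaving turnover counts in
    place.  Animals with < 2 segments are skipped with a warning.  Returns
    one NullDistribution per category, all from the same permutations.
    """
    rng = np.random.default_rng(seed)
    per_animal_null = {cat: [] for cat in _CATEGORIES}
    per_animal_obs = {cat: [] for cat in _CATEGORIES}
    for animal in _eligible_animals(spine_map, min_formed):
        if len(animal.segments) < 2:
            logger.warning("animal %s has < 2 segments; skipped from concordance",
                           animal.animal_id)
            continue
        c = np.array([cluster_new_spines(seg, d).n_clustered
                      for seg in animal.segments])
        t = np.array([sum(1 for sp in seg.spines
                          if sp.fate is not None and sp.fate.baseline_turnover)
                      for seg in animal.segments])
        obs = _category_percentages(c, t)
        perm_idx = np.argsort(rng.random((R, len(c))), axis=1)
        perm = _category_percentages(c[perm_idx], t[None, :].repeat(R, axis=0))
        for cat in _CATEGORIES:
            per_animal_obs[cat].append(obs[cat])
            per_animal_null[cat].append(perm[cat])
    if not per_animal_null["both"]:
        raise ValueError("no animal with >= 2 segments: concordance undefined")
    out = {}
    for cat in _CATEGORIES:
        values = np.mean(per_animal_null[cat], axis=0)
        observed = float(np.mean(per_animal_obs[cat]))
        out[cat] = summarize_null(values, observed, sidedness="one",
                                  statistic=f"pct_segments_{cat}", seed=seed)
    return out
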