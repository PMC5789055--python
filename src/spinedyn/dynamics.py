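"""Spine and behavior statistics: turnover, clustering, NND, survival.

Conventions, following the field's standard definitions:

* turnover ratio = (formed + lost) / (spines at session A + spines at B);
  per-animal values pool raw counts over all the animal's segments before
  dividing.
* clustered spine = a new stable spine (absent at learning start, present at
  learning end) lying within ``d`` micrometres (default 5, inclusive) of
  another new stable spine on the same segment; clusters are connected
  components of the <=d adjacency graph, so membership is transitive.
* animals with fewer than 5 spines formed during the learning phase are
  excluded from clustering statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .data import AnimalRecord, DendriteSegment, SpineMap

__all__ = [
    "TurnoverStats",
    "ClusterAssignment",
    "NNDSet",
    "turnover_ratio",
    "animal_turnover",
    "cluster_new_spines",
    "animal_clustering_ratio",
    "clustering_percentages",
    "clustered_spine_ids",
    "nnd",
    "ks_two_sample",
    "survival_rate",
    "segment_densities",
    "learning_rate",
    "suppression_ratio",
    "MIN_FORMED_FOR_CLUSTERING",
]

#: exclusion rule: animals with <5 spines formed during learning are dropped
#: from clustering statistics
MIN_FORMED_FOR_CLUSTERING = 5


@dataclass(frozen=True)
class TurnoverStats:
    n_formed: int
    n_lost: int
    n_t1: int
    n_t2: int

    @property
    def ratio(self) -> float:
        return (self.n_formed + self.n_lost) / (self.n_t1 + self.n_t2)


@dataclass(frozen=True)
class ClusterAssignment:
    threshold: float
    clusters: tuple[tuple[str, ...], ...]  # spine ids, each cluster >= 2 members
    n_new: int                             # new stable spines considered

    @property
    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def clustering_ratio(self) -> float:
        if self.n_new == 0:
            raise ZeroDivisionError("no new stable spines: clustering undefined")
        return self.n_clustered / self.n_new


@dataclass(frozen=True)
class NNDSet:
    distances: tuple[float, ...]
    source_class: str = ""
    target_class: str = ""


def _segments_with(animal: AnimalRecord, *days: int):
    """Segments of an animal that were imaged on all the given days."""
    return [s for s in animal.segments
            if not any(d in s.missing_sessions for d in days)]


def turnover_ratio(segments, day_a: int, day_b: int,
                   schedule=None) -> TurnoverStats:
    """Pooled turnover between two sessions over a set of segments.

    formed = absent at ``day_a`` and present at ``day_b``; lost = the
    converse.  The ratio is (formed + lost) / (count at a + count at b).
    """
    if isinstance(segments, AnimalRecord):
        schedule = segments.schedule
        segments = _segments_with(segments, day_a, day_b)
    if schedule is None:
        raise ValueError("schedule required when passing bare segments")
    ia, ib = schedule.index(day_a), schedule.index(day_b)
    formed = lost = n1 = n2 = 0
    for seg in segments:
        for sp in seg.spines:
            a, b = bool(sp.presence[ia]), bool(sp.presence[ib])
            n1 += a
            n2 += b
            formed += (not a) and b
            lost += a and (not b)
    if n1 + n2 == 0:
        raise ZeroDivisionError(
            f"no spines present at day {day_a} or {day_b}: turnover undefined")
    return TurnoverStats(formed, lost, n1, n2)


def animal_turnover(spine_map: SpineMap, day_a: int, day_b: int) -> dict[str, TurnoverStats]:
    """Per-animal pooled turnover between two sessions."""
    return {a.animal_id: turnover_ratio(a, day_a, day_b) for a in spine_map}


def _cluster_components(positions: np.ndarray, d: float) -> list[list[int]]:
    """Connected components (size >= 2) of the <=d adjacency graph on a line.

    Sorting makes components exactly the maximal runs of consecutive gaps
    <= d, so no general graph machinery is needed.
    """
    n = len(positions)
    if n < 2:
        return []
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    comps: list[list[int]] = []
    current = [int(order[0])]
    for i in range(1, n):
        if pos[i] - pos[i - 1] <= d:
            current.append(int(order[i]))
        else:
            if len(current) >= 2:
                comps.append(current)
            current = [int(order[i])]
    if len(current) >= 2:
        comps.append(current)
    return comps


def cluster_new_spines(segment: DendriteSegment, d: float = 5.0) -> ClusterAssignment:
    """Partition a segment's new stable spines into <=d clusters.

    Requires fates annotated (:func:`spinedyn.data.annotate_fates`).
    """
    new = [sp for sp in segment.spines if sp.fate is not None and sp.fate.new_stable]
    positions = np.array([sp.position for sp in new], dtype=float)
    comps = _cluster_components(positions, d)
    clusters = tuple(tuple(new[i].spine_id for i in comp) for comp in comps)
    return ClusterAssignment(threshold=d, clusters=clusters, n_new=len(new))


def clustered_spine_ids(animal: AnimalRecord, d: float = 5.0) -> set[str]:
    """Ids of the animal's clustered new stable spines."""
    out: set[str] = set()
    for seg in animal.segments:
        for cluster in cluster_new_spines(seg, d).clusters:
            out.update(cluster)
    return out


def animal_clustering_ratio(animal: AnimalRecord, d: float = 5.0) -> float:
    """Animal-level clustering ratio, pooling counts over segments.

    Raises ``ZeroDivisionError`` when the animal has no new stable spines.
    """
    n_clustered = n_new = 0
    for seg in animal.segments:
        asg = cluster_new_spines(seg, d)
        n_clustered += asg.n_clustered
        n_new += asg.n_new
    if n_new == 0:
        raise ZeroDivisionError(
            f"animal {animal.animal_id} has no new stable spines")
    return n_clustered / n_new


def _n_formed_learning(animal: AnimalRecord) -> int:
    return sum(1 for sp in animal.all_spines()
               if sp.fate is not None and sp.fate.formed)


def eligible_for_clustering(animal: AnimalRecord) -> bool:
    """Exclusion rule: >=5 spines formed during the learning phase."""
    return _n_formed_learning(animal) >= MIN_FORMED_FOR_CLUSTERING


def clustering_percentages(spine_map: SpineMap, d: float = 5.0) -> dict[str, float]:
    """Per-animal clustering percentage (0-100) after the exclusion rule."""
    out = {}
    for animal in spine_map:
        if not eligible_for_clustering(animal):
            continue
        try:
            out[animal.animal_id] = 100.0 * animal_clustering_ratio(animal, d)
        except ZeroDivisionError:
            continue
    return out


def nnd(source_positions, target_positions, exclude_self: bool = False) -> NNDSet:
    """Nearest-neighbor distances from each source to the target set.

    Positions are path coordinates on one segment.  When source and target
    are the same class, pass ``exclude_self=True`` to skip each spine's own
    position (one occurrence removed per source).  Sources with no eligible
    target are skipped.
    """
    src = np.asarray(list(source_positions), dtype=float)
    tgt = np.asarray(list(target_positions), dtype=float)
    dists = []
    for i, p in enumerate(src):
        others = tgt
        if exclude_self:
            # remove a single occurrence of this source position
            hit = np.flatnonzero(others == p)
            if hit.size:
                others = np.delete(others, hit[0])
        if others.size == 0:
            continue
        dists.append(float(np.min(np.abs(others - p))))
    return NNDSet(distances=tuple(dists))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires two non-empty samples")
    res = sstats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def survival_rate(animal: AnimalRecord, cohort: str, t_follow: int,
                  d: float = 5.0) -> float:
    """Fraction of the animal's new stable spines surviving to ``t_follow``.

    ``cohort`` is ``"clustered"`` or ``"non-clustered"``, partitioned by the
    <=d clustering of new stable spines.  Raises ``ZeroDivisionError`` on an
    empty cohort (caller skips the animal).
    """
    if cohort not in ("clustered", "non-clustered"):
        raise ValueError(f"unknown cohort {cohort!r}")
    clustered = clustered_spine_ids(animal, d)
    i_follow = animal.schedule.index(t_follow)
    n = surv = 0
    for seg in animal.segments:
        if t_follow in seg.missing_sessions:
            continue
        for sp in seg.spines:
            if sp.fate is None or not sp.fate.new_stable:
                continue
            is_cl = sp.spine_id in clustered
            if (cohort == "clustered") != is_cl:
                continue
            n += 1
            surv += bool(sp.presence[i_follow])
    if n == 0:
        raise ZeroDivisionError(f"animal {animal.animal_id}: empty {cohort} cohort")
    return surv / n


def segment_densities(segment: DendriteSegment, d: float = 5.0) -> dict[str, float]:
    """Per-length densities of pre-learning turnover and clustered spines.

    Returns events per micrometre, normalizing counts by segment length so
    segments of different size are comparable.
    """
    if not segment.length > 0:
        raise ValueError("segment length must be > 0")
    n_turnover = sum(1 for sp in segment.spines
                     if sp.fate is not None and sp.fate.baseline_turnover)
    n_clustered = cluster_new_spines(segment, d).n_clustered
    return {
        "turnover_density": n_turnover / segment.length,
        "cluster_density": n_clustered / segment.length,
    }


def learning_rate(trace: dict[int, float]) -> float:
    """Learning-rate slope of a freezing trace, in % freezing per day.

    The asymptote is the chronologically first maximum before any decrease;
    slope = (asymptote - baseline) / (day of asymptote - day of baseline),
    with baseline the pre-shock freezing on the first training day.
    """
    days = sorted(int(d) for d in trace if int(d) >= 0)
    if len(days) < 2 or days[0] != 0:
        raise ValueError("trace needs a day-0 baseline and >= 1 training day")
    values = [float(trace[d]) for d in days]
    # first maximum before any decrease
    i_asym = len(values) - 1
    for i in range(1, len(values)):
        if values[i] < values[i - 1]:
            i_asym = i - 1
            break
    if days[i_asym] == days[0]:
        return 0.0
    return (values[i_asym] - values[0]) / (days[i_asym] - days[0])


def suppression_ratio(activity_test: float, activity_baseline: float) -> float:
    """Activity suppression ratio: test / (baseline + test), in [0, 1]."""
    if activity_test < 0 or activity_baseline < 0:
        raise ValueError("activities must be non-negative")
    total = activity_test + activity_baseline
    if total == 0:
        raise ZeroDivisionError("both activities zero: suppression undefined")
    return activity_test / total
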