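"""Synthetic spine maps and behavior traces with known ground truth.

The generator emulates the statistical structure of longitudinal two-photon
spine imaging around an episodic learning task: per-animal variability in
baseline turnover, chance-level spatial clustering of new spines under
uniform placement, optional hotspot enrichment (new spines placed near
prior-turnover sites), differential follow-up survival of clustered vs
non-clustered spines, and saturating freezing curves whose asymptote grows
with the animal's baseline turnover.

Every stochastic event is recorded in a ground-truth table so downstream
fate annotation can be reconciled exactly, and the per-animal turnover
probabilities are returned for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (AnimalRecord, DendriteSegment, ImagingSchedule, Spine,
                   SpineMap)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_map", "generate_behavior"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic imaging experiment.

    Defaults follow the imaging regime the analyses assume: 17 animals,
    ~34 segments each, ~0.4 spines/um baseline density, per-animal baseline
    turnover centred near 9%, and uniform new-spine placement spiked with
    hotspot placement (probability ``kappa`` within ``h`` um of a
    pre-learning turnover site).
    """

    n_animals: int = 17
    group: str = "trained"
    genotype: str = "WT"
    schedule: tuple[int, ...] = (-3, 0, 2, 5, 35)

    segments_per_animal: float = 34.0       # Poisson mean, min 1
    segment_length_shape: float = 4.0       # Gamma shape; mean = shape*scale
    segment_length_scale: float = 10.0      # um
    min_segment_length: float = 15.0        # um
    baseline_density: float = 0.4           # spines per um

    rho_mean: float = 0.09                  # per-animal baseline turnover prob
    rho_sd: float = 0.03
    rho_bounds: tuple[float, float] = (0.02, 0.25)

    new_rate_per_um: float = 0.025          # learning-phase additions per um
    p_appear_midway: float = 0.6            # new spine visible already at day 2
    learning_loss_prob: float = 0.05        # baseline-stable spine lost in learning
    kappa: float = 1.0                      # hotspot placement probability
    h: float = 2.5                          # um, hotspot radius
    cluster_threshold: float = 5.0          # um, used to label clustered spines

    survival_clustered: float = 0.676       # follow-up survival probabilities
    survival_nonclustered: float = 0.49
    survival_stable: float = 0.95

    baseline_freezing: float = 5.0          # % on day 0 (pre-shock)
    asymptote_base: float = 20.0            # % at rho = 0
    freezing_gain: float = 250.0            # % freezing per unit turnover prob
    freezing_noise_sd: float = 8.0          # % (on the asymptote)
    learning_tau_days: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must be in [0, 1]")
        for name in ("baseline_density", "new_rate_per_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        max_len = self.segment_length_shape * self.segment_length_scale * 4
        if self.h > max_len:
            raise ValueError(f"hotspot radius h={self.h} exceeds plausible "
                             f"segment length {max_len}")
        for name in ("survival_clustered", "survival_nonclustered",
                     "survival_stable", "p_appear_midway", "learning_loss_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability")


@dataclass
class GroundTruth:
    """Per-event and per-animal ground truth emitted alongside a map."""

    events: pd.DataFrame   # one row per formation/loss event
    animals: pd.DataFrame  # per-animal rho, freezing asymptote

    @property
    def rho(self) -> dict[str, float]:
        return dict(zip(self.animals["animal"], self.animals["rho"]))


def _clustered_flags(positions: np.ndarray, d: float) -> np.ndarray:
    """Which of the positions have a neighbor within d (vector of bool)."""
    n = len(positions)
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    order = np.argsort(positions)
    pos = positions[order]
    gaps = np.diff(pos) <= d
    near = np.zeros(n, dtype=bool)
    near[:-1] |= gaps
    near[1:] |= gaps
    flags[order] = near
    return flags


def generate_map(config: GeneratorConfig | None = None,
                 seed: int | None = None) -> tuple[SpineMap, GroundTruth]:
    """Generate a SpineMap plus its ground-truth event table.

    Baseline spines are Poisson along each segment; the baseline session
    pair realizes per-spine loss and Poisson formation at the animal's rate
    ``rho_i``; learning-phase additions are placed uniformly with
    probability 1 - kappa or within +-h um of a random pre-learning
    turnover site (clipped to the segment) with probability kappa; new
    spines survive to follow-up with a clustered-status-dependent
    probability.  Deterministic for a fixed seed.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    schedule = ImagingSchedule(cfg.schedule)
    n_sessions = len(schedule)
    # session indices for the canonical 5-session design
    i_pre, i0 = 0, 1
    i_mid = 2 if n_sessions >= 4 else None
    i_end = n_sessions - 2
    i_follow = n_sessions - 1

    animals: dict[str, AnimalRecord] = {}
    event_rows = []
    animal_rows = []
    lo, hi = cfg.rho_bounds
    for ai in range(cfg.n_animals):
        animal_id = f"a{ai:02d}"
        rho = float(np.clip(rng.normal(cfg.rho_mean, cfg.rho_sd), lo, hi))
        n_seg = max(1, int(rng.poisson(cfg.segments_per_animal)))
        segments = []
        for si in range(n_seg):
            seg_id = f"{animal_id}_s{si:03d}"
            length = max(cfg.min_segment_length,
                         float(rng.gamma(cfg.segment_length_shape,
                                         cfg.segment_length_scale)))
            spines: list[Spine] = []
            counter = 0

            def new_spine(pos, presence):
                nonlocal counter
                sp = Spine(f"{seg_id}_sp{counter:03d}", float(pos),
                           np.asarray(presence, dtype=bool))
                counter += 1
                spines.append(sp)
                return sp

            n0 = rng.poisson(cfg.baseline_density * length)
            base_pos = np.sort(rng.uniform(0, length, n0))
            lost_baseline = rng.random(n0) < rho
            turnover_sites = []
            stable_spines = []
            for pos, lost in zip(base_pos, lost_baseline):
                if lost:
                    pres = np.zeros(n_sessions, bool)
                    pres[i_pre] = True
                    sp = new_spine(pos, pres)
                    turnover_sites.append(pos)
                    event_rows.append((animal_id, seg_id, sp.spine_id,
                                       "baseline_lost", pos, False))
                else:
                    pres = np.ones(n_sessions, bool)
                    stable_spines.append(new_spine(pos, pres))
            n_formed_base = rng.poisson(n0 * rho) if n0 else 0
            for pos in rng.uniform(0, length, n_formed_base):
                pres = np.zeros(n_sessions, bool)
                pres[i0:] = True
                sp = new_spine(pos, pres)
                turnover_sites.append(pos)
                event_rows.append((animal_id, seg_id, sp.spine_id,
                                   "baseline_formed", pos, False))
            # learning-phase losses among baseline-stable spines
            for sp in stable_spines:
                if rng.random() < cfg.learning_loss_prob:
                    gone_from = i_mid if (i_mid is not None
                                          and rng.random() < 0.5) else i_end
                    sp.presence[gone_from:] = False
                    event_rows.append((animal_id, seg_id, sp.spine_id,
                                       "learning_lost", sp.position, False))
                elif rng.random() > cfg.survival_stable:
                    sp.presence[i_follow] = False
            # learning-phase additions (new stable spines)
            sites = np.asarray(turnover_sites)
            n_new = rng.poisson(cfg.new_rate_per_um * length)
            new_positions = np.empty(n_new)
            from_hotspot = np.zeros(n_new, dtype=bool)
            for k in range(n_new):
                if sites.size and rng.random() < cfg.kappa:
                    site = sites[rng.integers(sites.size)]
                    new_positions[k] = np.clip(
                        site + rng.uniform(-cfg.h, cfg.h), 0, length)
                    from_hotspot[k] = True
                else:
                    new_positions[k] = rng.uniform(0, length)
            clustered = _clustered_flags(new_positions, cfg.cluster_threshold)
            for pos, hot, cl in zip(new_positions, from_hotspot, clustered):
                pres = np.zeros(n_sessions, bool)
                appears = (i_mid if (i_mid is not None and
                                     rng.random() < cfg.p_appear_midway)
                           else i_end)
                pres[appears:] = True
                p_surv = (cfg.survival_clustered if cl
                          else cfg.survival_nonclustered)
                if rng.random() > p_surv:
                    pres[i_follow] = False
                    survived = False
                else:
                    survived = True
                sp = new_spine(pos, pres)
                event_rows.append((animal_id, seg_id, sp.spine_id,
                                   "learning_formed", pos, bool(hot)))
                if not survived:
                    event_rows.append((animal_id, seg_id, sp.spine_id,
                                       "followup_lost", pos, bool(hot)))
            segments.append(DendriteSegment(seg_id, animal_id, length, spines))
        animals[animal_id] = AnimalRecord(
            animal_id=animal_id, group=cfg.group, genotype=cfg.genotype,
            schedule=schedule, segments=segments)
        animal_rows.append({"animal": animal_id, "rho": rho})

    events = pd.DataFrame(event_rows, columns=[
        "animal", "segment", "spine_id", "event", "position_um", "hotspot"])
    truth = GroundTruth(events=events, animals=pd.DataFrame(animal_rows))
    spine_map = SpineMap(animals)
    behavior = generate_behavior(cfg, truth.rho, seed=None, rng=rng)
    for animal_id, trace in behavior.items():
        spine_map.animals[animal_id].behavior = trace
    truth.animals["asymptote"] = [
        max(behavior[a][d] for d in behavior[a]) for a in truth.animals["animal"]]
    return spine_map, truth


def generate_behavior(config: GeneratorConfig, rho: dict[str, float],
                      seed: int | None = None, rng=None) -> dict[str, dict[int, float]]:
    """Monotone saturating freezing traces whose asymptote grows with rho.

    Day 0 carries the pre-shock baseline; days 1-5 follow
    ``a_i * (1 - exp(-d / tau))`` plus the baseline, with the animal-level
    asymptote ``a_i = asymptote_base + gain * rho_i + noise``.  With zero
    noise and positive gain the rho -> mean-freezing map is strictly
    monotone.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(seed)
    out: dict[str, dict[int, float]] = {}
    for animal_id, r in rho.items():
        asym = (cfg.asymptote_base + cfg.freezing_gain * r
                + rng.normal(0.0, cfg.freezing_noise_sd))
        asym = float(np.clip(asym, 0.0, 100.0 - cfg.baseline_freezing))
        trace = {0: cfg.baseline_freezing}
        for d in range(1, 6):
            f = cfg.baseline_freezing + asym * (1 - np.exp(-d / cfg.learning_tau_days))
            trace[d] = float(np.clip(f, 0.0, 100.0))
        out[animal_id] = trace
    return out
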