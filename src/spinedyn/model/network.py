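"""Network state and simulation protocol for the memory-allocation model.

A :class:`Network` holds an excitatory population of two-layer neurons
(soma + ``n_subunits`` dendritic subunits carrying positioned synapses) in
struct-of-arrays form, a lumped inhibitory unit, and a pool of presynaptic
inputs from which memory ensembles are drawn.  The daily protocol is:

1. a 4 s stimulation episode (Poisson activation of the memory's inputs)
   integrated at fixed ``dt``, accumulating per-synapse calcium;
2. episode-end tagging and PRP synthesis from accumulated calcium;
3. between-episode consolidation: tagged synapses capture PRPs from
   neighbors within ``capture_radius`` on the same subunit and move toward
   their tag direction at a rate set by the captured protein;
4. homeostatic scaling of the neuron's summed weight toward
   ``w_init * N_syn`` (closed-form exponential over the day);
5. stochastic structural turnover: non-potentiated synapses (w <= w_init)
   are removed with probability rate x Theta_removal and replaced one-for-
   one at random positions/subunits/inputs, conserving synapse count.

Input spike trains are generated as continuous Poisson times and binned to
``dt``, so halving the step leaves spike placement consistent.  Per-purpose
random streams are derived from the master seed, making recall of the same
memory bitwise repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import _episode_python, episode_kernel
from .params import ModelParams

__all__ = ["Network", "SynapseTable", "build_network"]

TAG_NONE, TAG_POT, TAG_DEP = 0, 1, -1


@dataclass
class SynapseTable:
    """Struct-of-arrays synapse state; one row per synapse."""

    neuron: np.ndarray     # int32, postsynaptic neuron
    subunit: np.ndarray    # int32, dendritic subunit on that neuron
    pre: np.ndarray        # int32, presynaptic input id
    w: np.ndarray          # float64 weight in [0, 1]
    pos: np.ndarray        # float64 position in [0, 1] a.u.
    prp: np.ndarray        # float64 local PRP level in [0, 1]
    tag: np.ndarray        # int8: 0 none, +1 potentiation, -1 depotentiation
    ca: np.ndarray         # float64 episode calcium accumulator
    birth_day: np.ndarray  # int32, simulated day of insertion (0 = initial)

    def __len__(self) -> int:
        return len(self.w)


class Network:
    def __init__(self, params: ModelParams, seed: int):
        self.params = params
        self.master_seed = int(seed)
        self.rng = np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(0,)))
        p = params
        n_total = p.n_exc * p.n_syn_init
        rng = self.rng
        self.syn = SynapseTable(
            neuron=np.repeat(np.arange(p.n_exc, dtype=np.int32), p.n_syn_init),
            subunit=rng.integers(0, p.n_subunits, n_total).astype(np.int32),
            pre=rng.integers(0, p.n_pre, n_total).astype(np.int32),
            w=np.full(n_total, p.w_init),
            pos=rng.random(n_total),
            prp=np.zeros(n_total),
            tag=np.zeros(n_total, dtype=np.int8),
            ca=np.zeros(n_total),
            birth_day=np.zeros(n_total, dtype=np.int32),
        )
        # turnover class per dendritic subunit: True = high rate
        self.high_turnover = np.zeros((p.n_exc, p.n_subunits), dtype=bool)
        self.V = np.full(p.n_exc, p.E_L)
        self.g_ahp = np.zeros(p.n_exc)
        self.day = 0

    # ------------------------------------------------------------------
    def set_high_turnover_subunits(self, n_high: int, per_neuron_random: bool = True):
        """Mark ``n_high`` of each neuron's subunits as high-turnover."""
        p = self.params
        if not 0 <= n_high <= p.n_subunits:
            raise ValueError(f"n_high must be in [0, {p.n_subunits}]")
        self.high_turnover[:] = False
        rng = np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(1,)))
        for n in range(p.n_exc):
            if per_neuron_random:
                idx = rng.choice(p.n_subunits, size=n_high, replace=False)
            else:
                idx = np.arange(n_high)
            self.high_turnover[n, idx] = True

    def sample_memories(self, n_memories: int) -> list[np.ndarray]:
        """Disjoint presynaptic input ensembles, one per memory."""
        p = self.params
        need = n_memories * p.n_inputs_per_memory
        if need > p.n_pre:
            raise ValueError(f"{n_memories} memories need {need} inputs "
                             f"but the pool has {p.n_pre}")
        rng = np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(2,)))
        perm = rng.permutation(p.n_pre)[:need]
        return [np.sort(perm[i * p.n_inputs_per_memory:(i + 1) * p.n_inputs_per_memory])
                for i in range(n_memories)]

    # ------------------------------------------------------------------
    def _input_spikes(self, ensemble: np.ndarray, stream_key: tuple[int, ...],
                      dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Poisson spike trains for an ensemble, binned to dt steps.

        Spike times are drawn in continuous ms (exponential gaps) so the
        raster is consistent across integration steps.
        """
        p = self.params
        rng = np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=stream_key))
        T = p.episode_s * 1e3
        rate = p.input_rate_hz / 1e3  # spikes per ms
        steps, pres = [], []
        for input_id in ensemble:
            t = rng.exponential(1.0 / rate)
            while t < T:
                steps.append(int(t / dt))
                pres.append(input_id)
                t += rng.exponential(1.0 / rate)
        steps = np.asarray(steps, dtype=np.int64)
        pres = np.asarray(pres, dtype=np.int32)
        order = np.argsort(steps, kind="stable")
        return steps[order], pres[order]

    def _presyn_csr(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        order = np.argsort(self.syn.pre, kind="stable").astype(np.int64)
        counts = np.bincount(self.syn.pre, minlength=p.n_pre)
        ptr = np.zeros(p.n_pre + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        return ptr, order

    def run_episode(self, ensemble: np.ndarray, stream_key: tuple[int, ...],
                    collect_ca: bool = True, dt: float | None = None,
                    use_numba: bool = True) -> np.ndarray:
        """One stimulation episode; returns per-neuron firing rates (Hz).

        Transient state (somatic and dendritic voltages, adaptation, bAP,
        inhibition) is reset at episode start: episodes are separated by a
        day, far beyond every membrane time constant.
        """
        p = self.params
        dt = p.dt if dt is None else dt
        n_steps = int(round(p.episode_s * 1e3 / dt))
        spike_step, spike_pre = self._input_spikes(ensemble, stream_key, dt)
        ptr, order = self._presyn_csr()
        V = np.full(p.n_exc, p.E_L)
        g_ahp = np.zeros(p.n_exc)
        Vb = np.zeros((p.n_exc, p.n_subunits))
        bap = np.zeros(p.n_exc)
        spike_counts = np.zeros(p.n_exc, dtype=np.int64)
        fn = episode_kernel if use_numba else _episode_python
        fn(n_steps, dt, V, g_ahp, Vb, bap, spike_counts,
           self.syn.neuron, self.syn.subunit, self.syn.w, self.syn.ca,
           ptr, order, spike_step, spike_pre,
           p.C, p.g_L, p.E_L, p.E_K, p.theta_soma, p.a_AHP,
           p.g_syn, p.k_inh, p.tau_inh,
           p.E_syn / p.tau_b, p.a_Ca if collect_ca else 0.0, p.E_bAP,
           np.exp(-dt / p.tau_b), np.exp(-dt / p.tau_bAP),
           np.exp(-dt / p.tau_AHP), np.exp(-dt / p.tau_inh),
           0.0, collect_ca)
        if not np.all(np.isfinite(V)):
            raise FloatingPointError("non-finite somatic state; simulation aborted")
        return spike_counts / p.episode_s

    # ------------------------------------------------------------------
    def apply_tags_and_prp(self) -> None:
        """Episode-end tagging and PRP synthesis from accumulated calcium."""
        p = self.params
        ca = self.syn.ca
        tag = np.zeros(len(self.syn), dtype=np.int8)
        tag[ca >= p.ca_low] = TAG_DEP
        tag[ca >= p.ca_high] = TAG_POT
        self.syn.tag = tag
        self.syn.prp[ca > p.Theta_PRP] = 1.0
        self.syn.ca = np.zeros(len(self.syn))

    def consolidate(self, duration_ms: float | None = None) -> None:
        """Between-episode consolidation of tags by captured PRPs.

        Each tagged synapse captures the PRP of all same-subunit synapses
        within ``capture_radius`` (itself included); the time-integrated
        captured protein sets the exponential rate at which the weight moves
        toward 1 (potentiation tag) or 0 (depotentiation tag).  Tags are
        cleared afterwards (tag lifetime = one between-episode interval) and
        PRP decays.
        """
        p = self.params
        T = p.day_ms if duration_ms is None else duration_ms
        syn = self.syn
        tagged = np.flatnonzero(syn.tag != TAG_NONE)
        if tagged.size:
            # time-integral of a unit PRP over the interval
            unit_integral = p.tau_PRP * (1.0 - np.exp(-T / p.tau_PRP))
            comp = syn.neuron.astype(np.int64) * p.n_subunits + syn.subunit
            order = np.argsort(comp, kind="stable")
            bounds = np.flatnonzero(np.diff(comp[order])) + 1
            group_by_comp = {int(comp[g[0]]): g for g in np.split(order, bounds)}
            new_w = syn.w.copy()
            for j in tagged:
                g = group_by_comp[int(comp[j])]
                near = np.abs(syn.pos[g] - syn.pos[j]) <= p.capture_radius
                captured = float(syn.prp[g][near].sum())
                target = 1.0 if syn.tag[j] == TAG_POT else 0.0
                f = np.exp(-p.consolidation_rate * captured * unit_integral)
                new_w[j] = target + (syn.w[j] - target) * f
            syn.w = np.clip(new_w, 0.0, 1.0)
        syn.tag = np.zeros(len(syn), dtype=np.int8)
        syn.prp = syn.prp * np.exp(-T / p.tau_PRP)

    def homeostasis_step(self, duration_ms: float | None = None) -> None:
        """Closed-form homeostatic scaling over an inter-episode interval.

        The neuron's summed weight relaxes exponentially toward
        ``w_init * N_syn`` with time constant ``tau_H * w_init``; the change
        is distributed as an identical additive drift over all synapses.
        """
        p = self.params
        T = p.day_ms if duration_ms is None else duration_ms
        syn = self.syn
        decay = np.exp(-T / (p.tau_H * p.w_init))
        for n in range(p.n_exc):
            idx = np.flatnonzero(syn.neuron == n)
            if idx.size == 0:
                continue
            s0 = float(syn.w[idx].sum())
            s_star = p.w_init * idx.size
            s_new = s_star + (s0 - s_star) * decay
            syn.w[idx] = np.clip(syn.w[idx] + (s_new - s0) / idx.size, 0.0, 1.0)

    def turnover_step(self, day: int | None = None) -> int:
        """Daily structural turnover; returns the number of synapses replaced.

        Synapses never potentiated beyond ``w_init`` are removed with
        probability rate(subunit) x Theta_removal and replaced one-for-one
        (same neuron, random subunit/position/input, weight ``w_init``),
        conserving each neuron's synapse count exactly.
        """
        p = self.params
        day = self.day if day is None else day
        syn = self.syn
        rate = np.where(self.high_turnover[syn.neuron, syn.subunit],
                        p.turnover_high, p.turnover_low)
        p_rem = np.minimum(rate * p.Theta_removal, 1.0)
        eligible = syn.w <= p.w_init
        removed = eligible & (self.rng.random(len(syn)) < p_rem)
        n_removed_per_neuron = np.bincount(syn.neuron[removed], minlength=p.n_exc)
        keep = ~removed
        n_new = int(removed.sum())
        if n_new == 0:
            return 0
        new_neuron = np.repeat(np.arange(p.n_exc, dtype=np.int32),
                               n_removed_per_neuron)
        self.syn = SynapseTable(
            neuron=np.concatenate([syn.neuron[keep], new_neuron]),
            subunit=np.concatenate([syn.subunit[keep],
                                    self.rng.integers(0, p.n_subunits, n_new).astype(np.int32)]),
            pre=np.concatenate([syn.pre[keep],
                                self.rng.integers(0, p.n_pre, n_new).astype(np.int32)]),
            w=np.concatenate([syn.w[keep], np.full(n_new, p.w_init)]),
            pos=np.concatenate([syn.pos[keep], self.rng.random(n_new)]),
            prp=np.concatenate([syn.prp[keep], np.zeros(n_new)]),
            tag=np.concatenate([syn.tag[keep], np.zeros(n_new, dtype=np.int8)]),
            ca=np.concatenate([syn.ca[keep], np.zeros(n_new)]),
            birth_day=np.concatenate([syn.birth_day[keep],
                                      np.full(n_new, day, dtype=np.int32)]),
        )
        return n_new

    # ------------------------------------------------------------------
    def encode_memory(self, ensemble: np.ndarray, memory_id: int = 0,
                      n_days: int | None = None, plasticity: bool = True,
                      turnover: bool = True) -> list[np.ndarray]:
        """Encode one memory over daily episodes; returns per-day rates."""
        p = self.params
        n_days = p.encoding_days if n_days is None else n_days
        rates = []
        for _ in range(n_days):
            self.day += 1
            r = self.run_episode(ensemble, stream_key=(3, memory_id, self.day),
                                 collect_ca=plasticity)
            rates.append(r)
            if plasticity:
                self.apply_tags_and_prp()
                self.consolidate()
                self.homeostasis_step()
            if turnover:
                self.turnover_step()
        return rates

    def encode_serial(self, ensembles: list[np.ndarray],
                      days_per_memory: int = 1) -> np.ndarray:
        """Serially encode memories (1 day ISI); returns recall rate matrix.

        Each memory is encoded for ``days_per_memory`` consecutive days;
        after all encoding, every ensemble is re-activated with plasticity
        frozen and the (n_memories, n_exc) recall firing-rate matrix in Hz
        is returned.
        """
        for m, ens in enumerate(ensembles):
            self.encode_memory(ens, memory_id=m, n_days=days_per_memory)
        return np.stack([self.recall(ens, memory_id=m)
                         for m, ens in enumerate(ensembles)])

    def recall(self, ensemble: np.ndarray, memory_id: int = 0,
               dt: float | None = None, use_numba: bool = True) -> np.ndarray:
        """Re-activate an ensemble with plasticity frozen; rates in Hz.

        Uses a stream derived only from (seed, memory id), so repeated
        recalls of the same memory are identical.
        """
        return self.run_episode(ensemble, stream_key=(4, memory_id),
                                collect_ca=False, dt=dt, use_numba=use_numba)


def build_network(params: ModelParams | None = None, seed: int = 0,
                  n_high_turnover: int = 0) -> Network:
    """Convenience constructor: network with n_high high-turnover subunits."""
    net = Network(params or ModelParams(), seed)
    net.set_high_turnover_subunits(n_high_turnover)
    return net
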