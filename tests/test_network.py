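"""Unit rules and conservation laws of the network simulator."""

import math

import numpy as np
import pytest

from spinedyn.model import ModelParams, build_network, ops
from spinedyn.model.kernels import _episode_python

P = ModelParams()
SMALL = ModelParams().replace(n_exc=4, n_syn_init=30, n_pre=100,
                              n_inputs_per_memory=20)


# --------------------------------------------------------------- elemental ops

def test_subunit_decay_and_impulse():
    v = ops.step_subunit(5.0, [], dt=1.0, p=P)
    assert v == pytest.approx(5.0 * math.exp(-1.0 / P.tau_b))
    v = ops.step_subunit(0.0, [0.5], dt=1e-9, p=P)
    assert v == pytest.approx(0.5 * P.E_syn / P.tau_b, rel=1e-6)
    v2 = ops.step_subunit(0.0, [0.5, 0.5], dt=1e-9, p=P)
    assert v2 == pytest.approx(2 * v, rel=1e-6)


def test_soma_fixed_point_and_adaptation_impulse():
    V, g, spiked = ops.step_soma(P.E_L, 0.0, 0.0, dt=0.1, p=P)
    assert V == P.E_L and g == 0.0 and not spiked
    V, g, spiked = ops.step_soma(P.theta_soma + 1.0, 0.2, 0.0, dt=1e-9, p=P)
    assert spiked and V == P.E_L
    assert g == pytest.approx(0.2 + P.a_AHP, rel=1e-6)


def test_adaptation_lengthens_interspike_intervals():
    """Constant suprathreshold drive: ISIs are non-decreasing."""
    V, g = P.E_L, 0.0
    spikes = []
    dt = 0.01
    for i in range(int(400 / dt)):
        V, g, sp = ops.step_soma(V, g, 2.5, dt, P)
        if sp:
            spikes.append(i * dt)
    assert len(spikes) >= 4
    isis = np.diff(spikes)
    # non-decreasing up to the one-step quantization of threshold crossing
    assert np.all(np.diff(isis) >= -dt - 1e-9)
    assert isis[-1] > isis[0]


def test_synaptic_current_combinations():
    vb = np.zeros(P.n_subunits)
    assert ops.synaptic_current(vb, 0.0, P) == 0.0
    vb[3] = 2.0
    assert ops.synaptic_current(vb, 0.0, P) == pytest.approx(P.g_syn * 2.0)
    assert ops.synaptic_current(vb, P.g_syn * 2.0, P) == pytest.approx(0.0)


def test_bap_closed_form():
    assert ops.bap_trace(0.0, P) == P.E_bAP
    assert ops.bap_trace(P.tau_bAP, P) == pytest.approx(P.E_bAP / math.e)
    assert ops.bap_trace(50 * P.tau_bAP, P) == pytest.approx(0.0, abs=1e-12)


def test_calcium_sigmoid():
    assert ops.calcium_influx(30.0, P) == pytest.approx(P.a_Ca / 2)
    assert ops.calcium_influx(-1e3, P) == pytest.approx(0.0, abs=1e-12)
    assert ops.calcium_influx(35.0, P) == pytest.approx(
        P.a_Ca / (1 + math.exp(-1)), rel=1e-12)


def test_tag_rule_thresholds():
    tags = ops.update_tags([0.0, P.ca_low, (P.ca_low + P.ca_high) / 2,
                            P.ca_high, 2 * P.ca_high], P)
    assert list(tags) == [0, -1, -1, 1, 1]


def test_homeostasis_drift_signs():
    n = 50
    at_target = np.full(n, P.w_init)
    assert ops.homeostasis_drift(at_target, P) == pytest.approx(0.0)
    assert ops.homeostasis_drift(np.full(n, 0.9), P) < 0
    assert ops.homeostasis_drift(np.zeros(n), P) == pytest.approx(1.0 / P.tau_H)


# ------------------------------------------------------------------- network

def test_quiescent_network_is_fixed_point():
    net = build_network(SMALL, seed=0)
    w0 = net.syn.w.copy()
    rates = net.run_episode(np.array([], dtype=np.int64), (99,))
    assert np.all(rates == 0.0)
    assert np.all(net.V == SMALL.E_L)
    net.apply_tags_and_prp()
    net.consolidate()
    net.homeostasis_step()
    assert np.allclose(net.syn.w, w0, atol=1e-12)


def test_turnover_conserves_count_and_protects_potentiated():
    net = build_network(SMALL.replace(Theta_removal=0.5), seed=1,
                        n_high_turnover=10)
    rng = np.random.default_rng(0)
    protected = rng.choice(len(net.syn), 12, replace=False)
    net.syn.w[protected] = 0.9
    protected_ids = {(int(net.syn.neuron[j]), round(float(net.syn.pos[j]), 12))
                     for j in protected}
    counts0 = np.bincount(net.syn.neuron, minlength=SMALL.n_exc)
    for day in range(200):
        net.turnover_step(day)
        counts = np.bincount(net.syn.neuron, minlength=SMALL.n_exc)
        assert np.array_equal(counts, counts0)
    kept = {(int(n), round(float(p), 12))
            for n, p, w in zip(net.syn.neuron, net.syn.pos, net.syn.w)
            if w > SMALL.w_init}
    assert protected_ids <= kept


def test_turnover_zero_rate_is_identity():
    params = SMALL.replace(Theta_removal=0.0)
    net = build_network(params, seed=2)
    pos0 = net.syn.pos.copy()
    assert net.turnover_step(1) == 0
    assert np.array_equal(net.syn.pos, pos0)


def test_removal_probability_matches_rate():
    """Empirical removal frequency ~ rate x Theta_removal (binomial error)."""
    params = SMALL.replace(Theta_removal=0.2)
    net = build_network(params, seed=3, n_high_turnover=0)
    n_trials, removed = 300, 0
    n_syn = len(net.syn)
    for day in range(n_trials):
        before = set(zip(net.syn.neuron.tolist(),
                         np.round(net.syn.pos, 12).tolist()))
        net.turnover_step(day)
        after = set(zip(net.syn.neuron.tolist(),
                        np.round(net.syn.pos, 12).tolist()))
        removed += len(before - after)
    p_expected = params.turnover_low * params.Theta_removal
    n_total = n_trials * n_syn
    se = math.sqrt(p_expected * (1 - p_expected) / n_total)
    assert abs(removed / n_total - p_expected) < 4 * se


def test_homeostasis_relaxes_sum_monotonically():
    net = build_network(SMALL, seed=4)
    net.syn.w = np.full(len(net.syn), 0.6)  # sum above target
    target = SMALL.w_init * np.bincount(net.syn.neuron, minlength=SMALL.n_exc)
    sums = []
    for _ in range(6):
        net.homeostasis_step()
        sums.append(np.array([net.syn.w[net.syn.neuron == n].sum()
                              for n in range(SMALL.n_exc)]))
    total = np.array([s.sum() for s in sums])
    assert np.all(np.diff(total) < 0)          # decreasing toward target
    assert np.all(sums[-1] >= target - 1e-9)   # never overshoots


def test_consolidation_capture_radius_rule():
    net = build_network(SMALL, seed=5)
    syn = net.syn
    # isolate a controlled subunit: synapses 0 and 1 on neuron 0 subunit 0
    syn.neuron[:3] = 0
    syn.subunit[:3] = 0
    syn.pos[0], syn.pos[1], syn.pos[2] = 0.10, 0.20, 0.55
    syn.w[:] = SMALL.w_init
    syn.tag[:] = 0
    syn.prp[:] = 0.0
    syn.tag[0] = 1          # tagged, no PRP of its own
    syn.prp[1] = 1.0        # neighbor within 0.1 supplies protein
    syn.tag[2] = 1          # tagged but isolated (0.35 away from PRP)
    w0 = syn.w.copy()
    net.consolidate()
    assert net.syn.w[0] > SMALL.w_potentiated        # captured, consolidates
    assert net.syn.w[2] == pytest.approx(w0[2])      # outside radius: no change
    assert np.all(net.syn.tag == 0)                  # tags cleared


def test_plasticity_disabled_keeps_weights_at_init():
    net = build_network(SMALL.replace(Theta_removal=0.0), seed=6)
    ens = net.sample_memories(1)[0]
    net.encode_memory(ens, n_days=2, plasticity=False, turnover=False)
    assert np.all(net.syn.w == SMALL.w_init)


def test_encode_memory_deterministic():
    def run():
        net = build_network(SMALL, seed=7, n_high_turnover=5)
        ens = net.sample_memories(1)[0]
        net.encode_memory(ens, n_days=2)
        return net.syn.w.copy(), net.syn.pos.copy()
    w1, p1 = run()
    w2, p2 = run()
    assert np.array_equal(w1, w2) and np.array_equal(p1, p2)


def test_kernel_matches_python_reference():
    net = build_network(SMALL, seed=8)
    ens = net.sample_memories(1)[0]
    ca0 = net.syn.ca.copy()
    r_nb = net.run_episode(ens, (5,), use_numba=True)
    ca_nb = net.syn.ca.copy()
    net.syn.ca = ca0
    r_py = net.run_episode(ens, (5,), use_numba=False)
    assert np.array_equal(r_nb, r_py)
    assert np.allclose(ca_nb, net.syn.ca, rtol=1e-12, atol=1e-12)


def test_recall_repeatable_and_nonnegative():
    net = build_network(SMALL, seed=9)
    ens = net.sample_memories(2)
    net.encode_memory(ens[0], n_days=2)
    r1 = net.recall(ens[0], memory_id=0)
    r2 = net.recall(ens[0], memory_id=0)
    assert np.array_equal(r1, r2)
    assert np.all(np.isfinite(r1)) and np.all(r1 >= 0)


def test_dt_halving_changes_rates_little():
    net = build_network(SMALL, seed=10)
    ens = net.sample_memories(1)[0]
    net.encode_memory(ens, n_days=2)
    r1 = net.recall(ens, memory_id=0)
    r2 = net.recall(ens, memory_id=0, dt=SMALL.dt / 2)
    assert abs(r1.mean() - r2.mean()) / r1.mean() < 0.05
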