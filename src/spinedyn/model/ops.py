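"""Elemental update rules of the two-layer neuron model.

These are the single-step operations the episode kernel is built from,
exposed separately so each rule can be exercised and checked in isolation.
Dirac-delta inputs are implemented as instantaneous state increments: a
presynaptic spike at synapse j adds ``w_j * E_syn / tau_b`` to its subunit's
depolarization, and a somatic spike adds ``a_AHP`` to the adaptation
conductance.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParams

__all__ = [
    "step_subunit",
    "step_soma",
    "synaptic_current",
    "bap_trace",
    "calcium_influx",
    "update_tags",
    "homeostasis_drift",
]


def step_subunit(v_b: float, spike_weights, dt: float, p: ModelParams) -> float:
    """One step of the dendritic leaky integrator.

    Exponential decay toward 0 with time constant ``tau_b``; every incoming
    spike (one entry of ``spike_weights`` per spike, the synapse's weight)
    adds an impulse ``w * E_syn / tau_b``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = v_b * math.exp(-dt / p.tau_b)
    for w in np.atleast_1d(np.asarray(spike_weights, dtype=float)):
        v += w * p.E_syn / p.tau_b
    return v


def step_soma(V: float, g_ahp: float, I_syn: float, dt: float,
              p: ModelParams) -> tuple[float, float, bool]:
    """One Euler step of the adaptive integrate-and-fire soma.

    Returns (V, g_AHP, spiked).  On threshold crossing V resets to ``E_L``
    and the adaptation conductance jumps by ``a_AHP``; g_AHP otherwise
    decays exponentially with ``tau_AHP``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    V = V + dt / p.C * (-p.g_L * (V - p.E_L) - g_ahp * (V - p.E_K) + I_syn)
    g_ahp = g_ahp * math.exp(-dt / p.tau_AHP)
    if not (math.isfinite(V) and math.isfinite(g_ahp)):
        raise FloatingPointError("non-finite somatic state; simulation aborted")
    if V >= p.theta_soma:
        return p.E_L, g_ahp + p.a_AHP, True
    return V, g_ahp, False


def synaptic_current(v_b_subunits, ipsc: float, p: ModelParams) -> float:
    """Somatic drive: coupling times summed subunit depolarizations minus IPSC."""
    return p.g_syn * float(np.sum(v_b_subunits)) - ipsc


def bap_trace(t_since_spike: float, p: ModelParams) -> float:
    """Backpropagating-AP depolarization ``E_bAP * exp(-t / tau_bAP)``."""
    if t_since_spike < 0:
        raise ValueError("t since spike must be >= 0")
    return p.E_bAP * math.exp(-t_since_spike / p.tau_bAP)


def calcium_influx(V, p: ModelParams):
    """Per-presynaptic-spike calcium influx, a sigmoid of local depolarization.

    ``a_Ca / (1 + exp(-(V - 30 mV) / 5 mV))`` with V the subunit
    depolarization plus the bAP component; mimics NMDA voltage dependence.
    """
    V = np.asarray(V, dtype=float)
    out = p.a_Ca / (1.0 + np.exp(-(V - 30.0) / 5.0))
    return float(out) if out.ndim == 0 else out


def update_tags(calcium, p: ModelParams):
    """Episode-end tag from accumulated calcium.

    < ca_low: no tag (0); [ca_low, ca_high): depotentiation (-1);
    >= ca_high: potentiation (+1).
    """
    ca = np.asarray(calcium, dtype=float)
    tag = np.zeros(ca.shape, dtype=np.int8)
    tag[ca >= p.ca_low] = -1
    tag[ca >= p.ca_high] = 1
    return tag if tag.ndim else np.int8(tag)


def homeostasis_drift(weights, p: ModelParams) -> float:
    """Instantaneous per-synapse homeostatic drift rate.

    ``dw/dt = (1 - sum(w) / (w_init * N_syn)) / tau_H``; identical for every
    synapse of the neuron, with fixed point at sum(w) = w_init * N_syn.
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    if n == 0:
        raise ValueError("neuron has no synapses")
    return (1.0 - float(w.sum()) / (p.w_init * n)) / p.tau_H
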