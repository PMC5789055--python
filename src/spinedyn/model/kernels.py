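"""Compiled inner loop for a stimulation episode.

The kernel advances the whole excitatory population at fixed step ``dt``:
dendritic subunit decay plus impulse inputs, adaptive integrate-and-fire
somata, bAP reset/decay, per-presynaptic-spike calcium accumulation, and a
lumped inhibitory unit that low-pass filters population spiking into a
nonnegative IPSC shared by all neurons.  State arrays are updated in place;
the function returns the final inhibitory drive so consecutive calls can be
chained.

A step-for-step numpy implementation with identical semantics lives in
``_episode_python`` and is used to cross-check the compiled path in tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["episode_kernel", "_episode_python"]


@njit(cache=False)
def episode_kernel(n_steps, dt,
                   V, g_ahp, Vb, bap, spike_counts,
                   syn_nrn, syn_sub, syn_w, syn_ca,
                   pre_ptr, pre_syn,
                   spike_step, spike_pre,
                   C, g_L, E_L, E_K, theta, a_AHP,
                   g_syn, k_inh, tau_inh,
                   E_syn_over_tau_b, a_Ca, E_bAP,
                   db, dbap, dahp, dinh,
                   s_inh, collect_ca):
    n_exc, n_sub = Vb.shape
    sp_i = 0
    n_spikes = spike_step.shape[0]
    for t in range(n_steps):
        for n in range(n_exc):
            bap[n] *= dbap
            for b in range(n_sub):
                Vb[n, b] *= db
        while sp_i < n_spikes and spike_step[sp_i] == t:
            pidx = spike_pre[sp_i]
            for q in range(pre_ptr[pidx], pre_ptr[pidx + 1]):
                j = pre_syn[q]
                n = syn_nrn[j]
                b = syn_sub[j]
                Vb[n, b] += syn_w[j] * E_syn_over_tau_b
                if collect_ca:
                    vloc = Vb[n, b] + bap[n]
                    syn_ca[j] += a_Ca / (1.0 + math.exp(-(vloc - 30.0) / 5.0))
            sp_i += 1
        ipsc = k_inh * s_inh
        nsp = 0
        for n in range(n_exc):
            svb = 0.0
            for b in range(n_sub):
                svb += Vb[n, b]
            I = g_syn * svb - ipsc
            V[n] += dt / C * (-g_L * (V[n] - E_L) - g_ahp[n] * (V[n] - E_K) + I)
            g_ahp[n] *= dahp
            if V[n] >= theta:
                V[n] = E_L
                g_ahp[n] += a_AHP
                bap[n] = E_bAP
                spike_counts[n] += 1
                nsp += 1
        s_inh = s_inh * dinh + nsp / tau_inh
    return s_inh


def _episode_python(n_steps, dt,
                    V, g_ahp, Vb, bap, spike_counts,
                    syn_nrn, syn_sub, syn_w, syn_ca,
                    pre_ptr, pre_syn,
                    spike_step, spike_pre,
                    C, g_L, E_L, E_K, theta, a_AHP,
                    g_syn, k_inh, tau_inh,
                    E_syn_over_tau_b, a_Ca, E_bAP,
                    db, dbap, dahp, dinh,
                    s_inh, collect_ca):
    """Reference implementation; must match :func:`episode_kernel` exactly."""
    n_exc, n_sub = Vb.shape
    sp_i = 0
    n_spikes = spike_step.shape[0]
    for t in range(n_steps):
        bap *= dbap
        Vb *= db
        while sp_i < n_spikes and spike_step[sp_i] == t:
            pidx = spike_pre[sp_i]
            for q in range(pre_ptr[pidx], pre_ptr[pidx + 1]):
                j = pre_syn[q]
                n, b = syn_nrn[j], syn_sub[j]
                Vb[n, b] += syn_w[j] * E_syn_over_tau_b
                if collect_ca:
                    vloc = Vb[n, b] + bap[n]
                    syn_ca[j] += a_Ca / (1.0 + math.exp(-(vloc - 30.0) / 5.0))
            sp_i += 1
        ipsc = k_inh * s_inh
        I = g_syn * Vb.sum(axis=1) - ipsc
        V += dt / C * (-g_L * (V - E_L) - g_ahp * (V - E_K) + I)
        g_ahp *= dahp
        fired = V >= theta
        nsp = int(np.count_nonzero(fired))
        V[fired] = E_L
        g_ahp[fired] += a_AHP
        bap[fired] = E_bAP
        spike_counts[fired] += 1
        s_inh = s_inh * dinh + nsp / tau_inh
    return s_inh
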