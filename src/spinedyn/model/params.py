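"""Parameters of the synaptic tagging & capture network model.

Single source of truth for every constant of the two-layer neuron model
(dendritic subunits + adaptive integrate-and-fire soma), the calcium/tag/
PRP plasticity cascade, homeostatic scaling, structural turnover, and the
simulation protocol.  Times are in milliseconds, voltages in millivolts,
synaptic positions in arbitrary units on [0, 1] per dendritic subunit
(0.2 a.u. corresponds to roughly 10 um of dendrite).

Defaults are package-chosen to make the cascade operate as described (a
fully tagged synapse with full local PRP consolidates past the potentiation
threshold within one between-episode interval); every value can be
overridden from a flat YAML/JSON mapping via :meth:`ModelParams.from_yaml`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["ModelParams", "DAY_MS"]

DAY_MS = 24.0 * 3600.0 * 1e3


@dataclass(frozen=True)
class ModelParams:
    # --- dendritic subunit (leaky integrator of weighted input impulses)
    tau_b: float = 10.0         # ms, dendritic time constant
    E_syn: float = 70.0         # mV*ms, synaptic impulse scale: dVb = w*E_syn/tau_b

    # --- soma (integrate-and-fire with spike-frequency adaptation)
    C: float = 1.0              # membrane capacitance (a.u.)
    g_L: float = 0.1            # leak conductance; tau_m = C/g_L = 10 ms
    E_L: float = 0.0            # mV, resting potential
    E_K: float = -10.0          # mV, AHP reversal
    tau_AHP: float = 80.0       # ms, adaptation decay
    a_AHP: float = 0.06         # conductance increment per spike
    g_syn: float = 0.4          # dendro-somatic coupling
    theta_soma: float = 15.0    # mV, spike threshold

    # --- backpropagating action potential
    E_bAP: float = 40.0         # mV, bAP peak
    tau_bAP: float = 15.0       # ms, bAP decay

    # --- calcium and synaptic tags
    a_Ca: float = 1.0           # max Ca influx per presynaptic spike
    ca_low: float = 8.0         # tag thresholds on episode-accumulated Ca:
    ca_high: float = 25.0       # [ca_low, ca_high) -> depotentiation; >= ca_high -> potentiation

    # --- plasticity-related proteins and consolidation
    Theta_PRP: float = 25.0     # Ca threshold triggering PRP synthesis
    tau_PRP: float = 3.6e6      # ms (60 min), PRP decay
    capture_radius: float = 0.2  # a.u., protein capture distance
    consolidation_rate: float = 8.3e-7  # per (ms * unit PRP)
    w_init: float = 0.2
    w_potentiated: float = 0.8

    # --- homeostatic scaling (sum of weights relaxes to w_init * N_syn)
    tau_H: float = 8.64e8       # ms (10 days); sum decays with tau_H * w_init

    # --- structural turnover
    Theta_removal: float = 0.3  # removal probability scale (per day step)
    turnover_low: float = 0.1
    turnover_high: float = 1.0

    # --- architecture
    n_exc: int = 40
    n_subunits: int = 20
    n_syn_init: int = 100       # synapses per neuron
    n_pre: int = 500            # presynaptic input pool
    n_inputs_per_memory: int = 50

    # --- inhibitory pool (lumped divisive-feedback surrogate)
    tau_inh: float = 10.0       # ms, low-pass of population spiking
    k_inh: float = 2.0          # IPSC gain

    # --- protocol
    dt: float = 0.1             # ms, integration step during episodes
    episode_s: float = 4.0      # s, stimulation episode length
    input_rate_hz: float = 50.0  # presynaptic Poisson rate during episodes
    day_ms: float = DAY_MS      # between-episode interval
    encoding_days: int = 4

    def __post_init__(self) -> None:
        for name in ("tau_b", "tau_AHP", "tau_bAP", "tau_PRP", "tau_H",
                     "tau_inh", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.w_init < self.w_potentiated <= 1):
            raise ValueError("require 0 < w_init < w_potentiated <= 1")
        if not (0 < self.capture_radius <= 1):
            raise ValueError("capture_radius must be in (0, 1]")
        if not self.turnover_low < self.turnover_high:
            raise ValueError("require turnover_low < turnover_high")
        if self.ca_low > self.ca_high:
            raise ValueError("require ca_low <= ca_high")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**raw)
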