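"""Turnover-sweep experiment: network readouts vs high-turnover subunits.

For each level of ``n_high`` (number of high-turnover dendritic subunits
per neuron, 0..20) and each trial, a fresh network encodes a first memory
over the standard multi-day protocol, yielding the potentiated-pair and
new-synapse-pair clustering fractions; the same network then serially
encodes further memories (1 day each) and every memory is recalled with
plasticity frozen, yielding the mean Treves-Rolls sparsity of the recall
rates.  The three readouts are summarized across levels with the ANOVA /
linear-trend statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..engram import (clustered_pair_fraction, linear_trend, new_pair_fraction,
                      treves_rolls_sparsity)
from .network import build_network
from .params import ModelParams

__all__ = ["run_turnover_sweep", "sweep_trends"]


def run_turnover_sweep(levels=(0, 5, 10, 15, 20), n_trials: int = 5,
                       n_memories: int = 10, params: ModelParams | None = None,
                       seed: int = 0, progress=None) -> pd.DataFrame:
    """Run the sweep; one row per (n_high, trial) with the three readouts.

    Clustering fractions are reported as percentages of same-subunit
    synapse pairs; sparsity is the mean Treves-Rolls value over the
    serially encoded memories' recall responses.
    """
    params = params or ModelParams()
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(len(levels) * n_trials) % (2 ** 31)
    rows = []
    i = 0
    for n_high in levels:
        for trial in range(n_trials):
            net = build_network(params, seed=int(trial_seeds[i]),
                                n_high_turnover=int(n_high))
            i += 1
            ensembles = net.sample_memories(n_memories)
            net.encode_memory(ensembles[0], memory_id=0)
            cpf = clustered_pair_fraction(net, w_thresh=params.w_potentiated,
                                          radius=params.capture_radius)
            npf = new_pair_fraction(net, birth_cutoff=1,
                                    radius=params.capture_radius)
            for m, ens in enumerate(ensembles[1:], start=1):
                net.encode_memory(ens, memory_id=m, n_days=1)
            recall = np.stack([net.recall(ens, memory_id=m)
                               for m, ens in enumerate(ensembles)])
            spars = [treves_rolls_sparsity(r) for r in recall if r.any()]
            rows.append({
                "n_high": int(n_high),
                "trial": trial,
                "clustered_pair_pct": 100.0 * cpf,
                "new_pair_pct": 100.0 * npf,
                "sparsity": float(np.mean(spars)) if spars else np.nan,
                "mean_recall_hz": float(recall.mean()),
            })
            if progress is not None:
                progress(rows[-1])
    return pd.DataFrame(rows)


def sweep_trends(df: pd.DataFrame):
    """Linear-trend statistics of each readout vs n_high level.

    Returns {readout: TrendResult}; levels are scaled to tens of subunits
    so slopes are per 10 high-turnover subunits.
    """
    levels = sorted(df["n_high"].unique())
    out = {}
    for col in ("clustered_pair_pct", "new_pair_pct", "sparsity"):
        groups = [df.loc[df["n_high"] == lv, col].dropna().to_numpy()
                  for lv in levels]
        out[col] = linear_trend(levels, groups)
    return out
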