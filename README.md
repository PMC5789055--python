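# spinedyn

Statistics and simulation tools for **clustered structural plasticity of
dendritic spines**: longitudinal spine turnover/clustering analysis with
Monte-Carlo null models, and a synaptic tagging-and-capture network
simulator linking spine turnover to memory-engram properties.

## The scientific problem

In vivo two-photon imaging tracks individual dendritic spines across days
while an animal learns. Two observations organize such datasets: spines
turn over spontaneously (a per-animal turnover ratio of roughly 5–15%
between baseline sessions), and learning adds new spines that tend to
appear in *clusters* — within ~5 µm of another new spine — preferentially
near sites of prior turnover ("hotspots"). `spinedyn` provides:

* **Spine statistics** on per-segment position/presence tables: the
  turnover ratio *(formed + lost) / (N₁ + N₂)*; the clustering ratio
  (#clustered new stable spines / #new stable spines, clusters being
  connected components of the ≤*d* adjacency on the 1-D segment,
  *d* = 5 µm); nearest-neighbor distances between fate classes;
  per-cohort survival at follow-up; learning-rate and activity-suppression
  behavior metrics.
* **Four resampling null models** with Gaussian fits and add-one empirical
  p-values *(1 + #extreme)/(R + 1)*: uniformly randomized new-spine
  positions; identity-permuted positions restricted to observed spine
  loci; randomized turnover sites for the clustered-spine NND; and
  within-animal permutation of per-segment clustered counts for the
  turnover × clustering concordance of segments.
* **A network simulator** of two-layer neurons — 20 leaky dendritic
  subunits (τ_b dV_b/dt = Σ w_j E_syn δ(t − t_ij) − V_b) feeding an
  adaptive integrate-and-fire soma (C dV/dt = −g_L(V − E_L) −
  g_AHP(V − E_K) + I_syn) — with bAP-gated calcium influx, synaptic
  tags, plasticity-related proteins captured within 0.2 a.u., homeostatic
  scaling (dw_j/dt = (1 − Σw_j / w_init N_syn)/τ_H), and daily stochastic
  synapse turnover. Readouts: potentiated/new synapse-pair clustering
  fractions and the Treves–Rolls population sparsity
  a = (Σrᵢ/N)² / (Σrᵢ²/N) of recalled memory engrams.
* **A synthetic-data generator** that emulates the imaging regime
  (per-animal turnover variability, chance clustering ≈ 20–25% under the
  5 µm rule, hotspot enrichment, survival advantage of clustered spines,
  turnover-coupled learning curves), with a ground-truth event table.

It is written for systems-neuroscience labs analyzing longitudinal spine
data and for modelers studying structural plasticity.

## Worked example

```bash
python examples/clustering_null.py
```

```
hotspot-enriched:
  observed clustering       36.3% of new spines
  uniform null              18.8% (sd 2.11), empirical p = 9.999e-05
  positional-permutation    20.0% (sd 2.09), empirical p = 9.999e-05
uniform control:
  observed clustering       22.6% of new spines
  uniform null              21.8% (sd 2.05), empirical p = 0.3533
  positional-permutation    22.3% (sd 2.06), empirical p = 0.4453
```

On a hotspot-enriched synthetic map, 36.3% of the new stable spines have
another new spine within 5 µm, while redrawing their positions at random
10,000 times yields only ~19–20% — the observed value exceeds every
resample (p < 10⁻⁴). On a uniform-placement control map the observed
22.6% is indistinguishable from chance. The other scripts in `examples/`
demonstrate per-animal statistics, hotspot localization (NND and
concordance nulls), behavior coupling, single-memory encoding, and the
turnover sweep; each prints a short interpretation of its numbers.

The same functionality is scriptable from the shell:

```bash
spinedyn generate --seed 1 --out data/
spinedyn analyze-spines --table data/spine_table.csv --out results/
spinedyn null --table data/spine_table.csv --model cluster-uniform \
    --reps 10000 --seed 1 --out results/
```

Every command writes tidy CSVs plus a JSON manifest (parameters, seed,
version) sufficient to re-run bit-identically.

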