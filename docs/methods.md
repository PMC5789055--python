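# Methods

## Spine-map representation and fate classes

A dendritic segment is a rectifiable 1-D curve; spine positions are path
coordinates in µm from an arbitrary but fixed segment end, and every
inter-spine distance is `|Δposition|` within a segment (distances across
branch points are undefined and never computed). Presence is scored per
imaging session with no identity persistence across gaps: a spine that
disappears and reappears at the same position counts as a loss plus a
formation. A segment whose entire presence column is missing for a session
is excluded from any statistic touching that session (logged warning).

Given three analysis days — baseline pair (t_pre, t0) and learning end
t_end — each spine receives interval fates: baseline formed/lost/stable,
learning formed (absent at t0, present at some later session ≤ t_end),
learning lost (present at t0, absent at t_end), and **new stable** (absent
at t0, present at t_end), the substrate of all clustering statistics.
"Pre-learning turnover sites" are positions of spines formed *or* lost in
the baseline interval; both kinds count for hotspot analyses.

## Statistics

* **Turnover ratio** = (formed + lost) / (N(t₁) + N(t₂)). Animal-level
  values pool raw counts over segments before dividing (the definition is
  count-based, so pooling — not averaging per-segment ratios — is the
  faithful aggregation; per-segment ratios would be undefined on sparse
  segments and would weight a 10 µm segment like a 100 µm one).
* **Clustering**: two new stable spines are adjacent iff `|Δpos| ≤ d`
  (d = 5 µm default). Clusters are connected components of size ≥ 2, so
  membership is transitive (a chain 0–4–8 µm is one cluster of three).
  The inclusive ≤ is a convention choice; at float resolution it is
  immaterial and the threshold is configurable. On a line, components are
  maximal runs of consecutive sorted gaps ≤ d, which the implementation
  exploits. The clustering ratio is clustered/new-stable counts pooled per
  animal; animals with fewer than 5 spines formed during learning are
  excluded from clustering statistics.
* **NND**: per source spine, the distance to the nearest target-class
  spine on the same segment (sources without an on-segment target are
  skipped; self-matches removed when classes coincide). Distribution
  comparisons use the asymptotic two-sample Kolmogorov–Smirnov test.
* **Survival**: fraction of a cohort (clustered vs non-clustered new
  stable spines) still present at follow-up, per animal.
* **Behavior**: learning-rate slope = (asymptote − baseline)/(day of
  asymptote − day 0), the asymptote being the chronologically first
  maximum before any decrease; suppression ratio = test/(baseline + test).

## Resampling null models

All four nulls share a scheme: recompute the observed statistic under a
randomized spatial assignment, R = 10,000 times, per animal, then average
animals (equal-animal weighting, matching the observed statistic's
construction; how the original analyses weighted animals vs segments in
the concordance aggregate is not specified, so the same equal-animal rule
is used everywhere for consistency).

1. **Uniform clustering null**: per segment, the k new stable spines are
   replaced by k i.i.d. Uniform(0, L) positions; no exclusion zone around
   existing spines. For k = 2 the per-segment clustering probability has
   the closed form 1 − (1 − d/L)², used as a test oracle.
2. **Positional clustering null**: k positions drawn without replacement
   from the segment's ever-observed spine positions (new-spine identity
   permuted), confining the null to loci that demonstrably support spines.
   Verified against exhaustive enumeration on ≤ 6 candidates.
3. **NND null**: per segment with ≥ 1 clustered and ≥ 1 turnover spine,
   turnover positions are redrawn (uniform or positional variant); each
   clustered spine's NND to the redrawn set is averaged within animal,
   then across animals. Oracle: E|U − L/2| = L/4.
4. **Concordance null**: per animal with ≥ 2 segments, the vector of
   per-segment clustered-spine counts is permuted across segments with
   turnover counts fixed; segments are categorized as both / neither /
   turnover-only / cluster-only and the four percentages recomputed.
   Verified against the 3! enumeration on a 3-segment toy.

The empirical p uses the add-one estimator (1 + #{at least as extreme}) /
(R + 1) — never the Gaussian tail; the moments-based Gaussian fit (mean,
SD of resamples) is reported for display parity with the usual
histogram-plus-fit figure. One-sided direction defaults to the sign of
(observed − null mean). A zero-variance null with observed off the mean is
flagged degenerate (p saturates at 1/(R+1)).

Randomness: one seeded numpy PCG64 generator per null run, consumed by
vectorized draws in a fixed order, so a fixed seed reproduces the
distribution bitwise. (Counter-derived per-resample substreams would allow
deterministic parallelism; single-stream vectorization was chosen because
the vectorized nulls already run in milliseconds.)

## Network model

Excitatory neurons are two-layer units: `n_subunits = 20` independent
dendritic subunits, each a leaky integrator

    τ_b dV_b/dt = Σ_j w_j E_syn δ(t − t_ij) − V_b

whose Dirac inputs are applied as instantaneous increments
`w_j·E_syn/τ_b`, feeding an integrate-and-fire soma with
spike-frequency adaptation

    C dV/dt = −g_L(V − E_L) − g_AHP(V − E_K) + I_syn(t)
    τ_AHP dg_AHP/dt = a_AHP δ(t − t_spike) − g_AHP
    I_syn(t) = g_syn Σ_n V_b,n(t) − IPSC(t).

After each somatic spike a backpropagating depolarization
`V_bAP(t) = E_bAP e^(−t/τ_bAP)` (reset, not summed, at each spike) is
added to every subunit for plasticity purposes. Per presynaptic spike, a
synapse accumulates calcium `ΔC = a_Ca σ((V_b + V_bAP − 30 mV)/5 mV)`
(logistic σ), mimicking NMDA voltage dependence.

**Tags, PRPs, consolidation.** At episode end, accumulated calcium sets a
per-synapse tag: none below `ca_low`, depotentiation in
`[ca_low, ca_high)`, potentiation at `≥ ca_high`; calcium above
`Θ_PRP` sets the synapse's PRP level to 1.0, which decays with
`τ_PRP`. During the between-episode interval each tagged synapse captures
the PRP of all same-subunit synapses within 0.2 a.u. (itself included; PRP
is modeled per synapse, the natural reading of a locally synthesized,
locally captured resource) and its weight relaxes toward the tag target
(1 for potentiation, 0 for depotentiation) as
`w ← target + (w − target)·exp(−c·P·∫prp dt)`. Tags clear after one
interval (tag lifetime = inter-episode interval).

**Homeostasis** (dw_j/dt = (1 − Σw_j/(w_init N_syn))/τ_H) is applied in
closed form over each day: the summed weight relaxes exponentially toward
`w_init·N_syn` with time constant `τ_H·w_init`, distributed as an equal
additive drift (weights clipped to [0, 1]).

**Turnover**, once per simulated day after consolidation (the timescale on
which imaging resolves structural change): synapses never potentiated
beyond `w_init` are removed with probability rate(subunit)·Θ_removal,
where each subunit's rate is `turnover_low = 0.1` or
`turnover_high = 1.0`, and replaced one-for-one on the same neuron
(random subunit, uniform position, random presynaptic input, weight
`w_init`, birth day recorded), conserving the synapse count exactly.

**Inhibition.** IPSC(t) is a lumped divisive-feedback surrogate: total
excitatory population spiking, low-pass filtered with `τ_inh`, times gain
`k_inh`, delivered identically to every neuron; it is nonnegative by
construction. The interface is pluggable so a spiking inhibitory
population could substitute.

**Integration.** Fixed-step forward Euler at `dt = 0.1 ms` during 4-s
stimulation episodes (membrane time constants are ≥ 10 ms, two orders
above dt; halving dt changes recall rates by < 1%); between episodes no
spiking occurs and PRP decay, consolidation, and homeostasis advance by
closed-form exponential updates. Input spike times are drawn as
continuous-time Poisson processes and binned to dt, so the raster is
consistent when dt changes. The inner loop is a numba kernel with a
step-identical numpy reference implementation cross-checked in tests.
Dendritic regenerative events are not modeled; the subunits are linear
integrators (the capture radius, not dendritic spikes, carries the
compartmentalization here).

### Parameters

The constants are package-chosen (the original supplementary table is not
transcribed here) to satisfy the cascade's qualitative contract, all
overridable via a flat YAML file:

| group | values | rationale |
|---|---|---|
| membranes | τ_b = 10 ms, C/g_L = 10 ms, θ_soma = 15 mV, E_K = −10 mV, τ_AHP = 80 ms, a_AHP = 0.06 | standard cortical-range constants; adaptation visibly lengthens ISIs |
| drive | E_syn = 70 mV·ms, g_syn = 0.4, 50 Hz inputs, 50 inputs/memory of a 500-input pool | an active ensemble drives ~10–60 Hz heterogeneous firing |
| bAP/Ca | E_bAP = 40 mV, τ_bAP = 15 ms, a_Ca = 1/spike | coincidence of presynaptic spikes with bAPs is required to reach the sigmoid's dynamic range |
| tags/PRP | ca_low = 8, ca_high = 25, Θ_PRP = 25, τ_PRP = 60 min | active-ensemble synapses on co-active neurons straddle ca_high (episode totals ~10–40); inactive synapses stay at 0 |
| consolidation | radius 0.2 a.u., c = 8.3·10⁻⁷ /(ms·PRP) | a fully tagged synapse with one unit of captured PRP reaches w ≈ 0.96 > w_potentiated within one day (c·τ_PRP ≈ 3) |
| weights | w_init = 0.2, w_potentiated = 0.8 | potentiation protects a synapse from removal |
| homeostasis | τ_H = 10 days (sum time-constant 2 days) | slow relative to encoding, fast enough to re-normalize over the 13-day protocols |
| turnover | Θ_removal = 0.3 | high-turnover subunits replace ~30% of eligible synapses per day, low-turnover ~3%, bracketing imaging-scale turnover |
| scale | 40 excitatory neurons, 100 synapses each, dt = 0.1 ms | see below |

**Problem sizes.** The default sweep (5 levels × 5 trials, 13 encoding
days + 10 recalls each) runs in ~20 s. 40 neurons is the smallest
population at which the Treves–Rolls trend — whose sign is stable already
at 20 neurons — is also statistically resolvable from 5 trials per level;
the pair-clustering trends are robust at either size.

## Engram readouts

Positions are only comparable within a subunit, so "all synapse pairs"
means all same-subunit pairs, aggregated over neurons (documented
interpretation). Clustered potentiated pairs: both weights > 0.8 and
`|Δpos| < 0.2` (strict <, immaterial at float resolution); new pairs: both
synapses inserted after encoding day 1. Treves–Rolls sparsity
a = (mean r)²/mean(r²) is scale-invariant, 1 for uniform rates, 1/N for
one-hot. The sweep summary uses one-way ANOVA plus the single-df
linear-trend contrast with centered level coefficients, tested against the
within-group mean square; slope and r² come from the pooled least-squares
regression. Perfectly separated noiseless levels return F = ∞, p = 0; a
globally constant response returns slope 0, p = 1.

## Synthetic-data generator

What it emulates: Poisson baseline spines (0.4/µm) on ~34 gamma-length
segments per animal (~40 µm); per-animal baseline turnover probability
ρᵢ ~ N(0.09, 0.03²) clipped to [0.02, 0.25], realized as per-spine loss
plus Poisson formation (so the realized turnover ratio concentrates on
ρᵢ); learning additions at 0.025/µm placed uniformly with probability
1 − κ or within ±h of a random pre-learning turnover site with
probability κ (default κ = 1, h = 2.5 µm); follow-up survival Bernoulli
at 0.676/0.49 for clustered/non-clustered new spines; saturating freezing
curves whose asymptote is 20% + 250%·ρᵢ + N(0, 8²). The defaults were
calibrated once, by simulation, so that κ = 0 yields chance clustering of
~20–22% under the 5 µm rule and κ = 1 yields ~36–41% observed — the
chance/enriched regime the analyses are designed to detect.

What it does **not** emulate: imaging noise and scoring ambiguity (every
presence is certain), spine identity errors, z-projection foreshortening,
segment-level covariates (depth, branch order), within-animal segment
correlations beyond hotspot placement, and any genotype biology (a
"mutant" group is simply a configuration with higher mean ρᵢ). Passing
calibration therefore shows the *statistics* behave correctly under the
generative assumptions, not that real imaging data meet those assumptions.

## Degenerate inputs and tie-breaks

Undefined ratios raise (`ZeroDivisionError`) rather than returning NaN:
empty spine sets for turnover, zero new stable spines for clustering,
empty survival cohorts (callers skip the animal), zero same-subunit pairs
for pair fractions, all-zero rate vectors for sparsity. NND sources
without an on-segment target are skipped silently (a count, not an
error). Coincident positions cluster at any d ≥ 0. Non-finite simulator
state aborts with a diagnostic rather than propagating NaNs.

## Known limitations

* The null models treat segments as independent within animal; dendritic
  branch relationships are not represented.
* The simulator's inhibition is a mean-field surrogate; engram-overlap
  statistics that depend on structured inhibition are out of scope.
* Homeostasis distributes drift additively, so very long simulations
  compress the weight distribution toward the clip boundaries.
* The generator's survival step assigns clustered status from the realized
  new-spine configuration before follow-up, so cluster dissolution between
  learning end and follow-up does not feed back on survival probability.
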