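"""Network readouts as structural turnover increases.

Sweeps the number of high-turnover dendritic subunits per neuron over
{0, 10, 20} (3 trials each, reduced from the default 5-level sweep for a
quick run), encoding one memory for 4 days plus 9 serial memories, and
prints the three readouts with their linear trend.  All three should rise
with turnover: more potentiated clustered pairs, more clustered new
synapses, and a higher Treves-Rolls value for the recall rates.
"""

import spinedyn as sd

df = sd.run_turnover_sweep(levels=(0, 10, 20), n_trials=3, seed=0)
print(df.groupby("n_high")[["clustered_pair_pct", "new_pair_pct",
                            "sparsity"]].mean().round(3))

trends = sd.sweep_trends(df)
print("\nlinear trend vs number of high-turnover subunits:")
for name, tr in trends.items():
    print(f"  {name:<22} slope {tr.slope:+.4f} per subunit, "
          f"r2 {tr.r2:.2f}, trend p {tr.p_trend:.2g}")
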