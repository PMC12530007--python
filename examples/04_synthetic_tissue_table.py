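"""Synthetic two-system tissue dataset and its Spearman analysis.

Generates an empirical-style table of per-female muscle and gonad total
thiamine for a thiamine-limited and a replete system sampled at four
migration stages, then runs the rank-correlation analysis per system and
stage (noise-free here so the mechanistic signal is visible; the default
adds 10% lognormal measurement noise).
"""

import thialloc as th

limited = th.presets.desk_scale(th.presets.reabsorption_scenario(3, 10, 2.0))
replete = th.presets.desk_scale(th.presets.reabsorption_scenario(3, 10, 6.0))

print("optimizing both systems' policies and simulating...")
table = th.generate_tissue_dataset(limited, replete, n_per_stage=25, noise_cv=0.0, seed=1)
print(table.head(3).to_string(index=False))
print(f"... {len(table)} rows, systems {sorted(set(table['system']))}")
print()

res = th.spearman_correlation(table, group_by=("system", "stage"))
print(res.to_string(index=False))
print()
print("Late-stage (upstream/spawning) rho is strongly positive only in the")
print("thiamine-limited system; the replete system shows no consistent rank")
print("correlation. Feeding-stage groups are flagged: gonads are empty there.")
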