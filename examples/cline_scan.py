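"""Kendall correlation scan on a latitude-stratified synthetic panel.

Simulates 52 populations (0-70 degrees latitude) with Balding-Nichols drift
growing away from the equatorial origin, plants Δphotoperiod-tracking
frequency clines in 1% of 10,000 SNPs, and calls selection with the dual
gate: Bonferroni-corrected Kendall p < 0.05 AND a MAF-binned |tau|
percentile rank > 0.95.
"""

import numpy as np

from photoclines import (
    SimulationConfig,
    call_significant,
    maf_binned_rank,
    make_populations,
    scan,
    simulate_frequencies,
)

cfg = SimulationConfig(n_pops=52, n_snps=10_000, frac_selected=0.01, seed=42)
pops, env = make_populations(cfg)
table, truth = simulate_frequencies(cfg, pops, env)

results = scan(table, env, "delta_photoperiod")
maf_binned_rank(results)
call_significant(results, n_tests=200)

sig = np.array([bool(r.significant) for r in results])
taus = np.array([r.tau for r in results])
print(f"{truth.sum()} planted clines among {len(results)} SNPs")
print(f"median |tau| at planted clines: {np.median(np.abs(taus[truth])):.2f}")
print(f"recall at the dual gate:        {100 * sig[truth].mean():.0f}%")
print(f"false positives among neutral:  {100 * sig[~truth].mean():.2f}%")
print()
print("The MAF-binned empirical rank absorbs the genome-wide drift gradient;")
print("only locus-specific cline signals clear the 0.95 rank gate.")
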