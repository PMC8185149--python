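"""Differential expression per genotype-vs-matched-WT contrast.

Median-of-ratios size factors, a per-transcript NB Wald test, BH-adjusted
q-values, significance at |log2FC| >= 1 and q < 0.05.  Run at 5 replicates
per condition code, where the desk-scale test has power for the planted
effects (the 2-replicate default has almost none — by design the t(2)
reference is very conservative).
"""

from droughtlnc import SyntheticConfig, simulate_study
from droughtlnc.diffexpr import (
    call_de,
    contrasts_from_sample_table,
    run_contrast,
    shared_de,
    size_factors,
)
from droughtlnc.simulate import evaluate_de_calls

study = simulate_study(SyntheticConfig(seed=42, n_samples_per_code=5))
factors = size_factors(study.counts)
print(f"size factors: min {factors.min():.2f}, max {factors.max():.2f} "
      "(true sequencing-depth range is 0.7-1.4)")

calls = {}
for contrast in contrasts_from_sample_table(study.sample_table):
    results = run_contrast(study.counts, contrast, factors)
    lnc_hits = call_de(results) & set(study.truth.all_lncrna_ids)
    calls[contrast.name] = call_de(results)
    if lnc_hits:
        print(f"{contrast.name:24s} {len(lnc_hits):3d} DE lncRNAs")

ev = evaluate_de_calls(study.truth, calls)
print(f"\nplanted-effect recall: {ev['recall']:.2f}   "
      f"false-discovery proportion: {ev['fdp']:.2f}")

a, b = "AtLEALS_vs_WTLS", "AtLEALL_vs_WTLL"
both = shared_de(calls[a], calls[b])
print(f"lncRNAs DE under both short- and long-term drought (leaves, "
      f"LEA-OE): {len(both)}")
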