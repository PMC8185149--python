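"""Generate the synthetic drought-stress study and look at what was planted.

Builds the full input set in memory — transcript models with StringTie-style
class codes, spliced sequences, a 20-condition x 2-replicate count matrix,
known-RNA IDs and a term annotation — and prints the planted ground truth
that the downstream stages are expected to recover.
"""

from droughtlnc import SyntheticConfig, simulate_study, write_fixture

study = simulate_study(SyntheticConfig(seed=42))

print(f"transcripts:     {len(study.transcripts)}")
print(f"samples:         {len(study.sample_table)} "
      f"({len(study.sample_table.codes())} condition codes)")
by_class = {k: len(v) for k, v in study.truth.lncrna_ids.items()}
print(f"planted lncRNAs: {by_class} "
      "(u = intergenic, i = intronic, x = antisense)")
print(f"filter decoys:   { {k: len(v) for k, v in study.truth.decoy_ids.items()} }")
print(f"planted DE:      {len(study.truth.de)} transcript/contrast effects, "
      f"|log2FC| in [1.5, 3.0]")
print(f"cis pairs:       {[p['distance'] for p in study.truth.cis_pairs]} bp gaps "
      f"(+ one decoy at {study.truth.cis_decoy_pairs[0]['distance']} bp)")
print(f"trans pairs:     {len(study.truth.trans_pairs)} "
      f"({len(set(p['gene'] for p in study.truth.trans_pairs))} target genes, "
      "one regulated by 8 lncRNAs)")
print(f"enriched terms:  {study.truth.enriched_term_ids}")

# write_fixture(study, "fixture/") would emit the six standard input files
# (GTF, FASTA, counts TSV, sample table, known IDs, term annotation) plus
# the truth JSON, byte-identical for a given seed.
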