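"""Identify lncRNAs: filter candidates, classify by class code, call the
coding-potential consensus.

A transcript survives when it is longer than 200 bp with at least two
exons, carries at least five reads across all samples, is not a known
mRNA/ncRNA, and has positional class code "u", "i" or "x".  Survivors are
called lncRNA only when every coding-potential predictor labels them
noncoding.
"""

from droughtlnc import SyntheticConfig, simulate_study
from droughtlnc.identify import (
    classify_by_class_code,
    consensus_noncoding,
    filter_candidates,
    predictor_tally,
    score_coding_potential,
)

study = simulate_study(SyntheticConfig(seed=42))

flt = filter_candidates(study.transcripts, study.counts, study.known_ids)
survivors = [f.transcript for f in flt if f.passed]
print(f"{len(flt)} transcripts -> {len(survivors)} candidates after filtering")

rejected = [f for f in flt if not f.passed]
by_rule = {}
for f in rejected:
    for rule, ok in f.flags.items():
        if not ok:
            by_rule[rule] = by_rule.get(rule, 0) + 1
print(f"rejections per rule (a transcript may fail several): {by_rule}")

lnc = classify_by_class_code(survivors)
print(f"positional classes: {lnc.class_counts()}")

# the built-in stand-in scorer combines max-ORF, Fickett TESTCODE and a
# hexamer log-likelihood ratio; real CNCI/CPC/CPAT/pfam label TSVs can be
# supplied instead (identify.read_label_tsv)
seqs = {t.transcript_id: study.sequences[t.transcript_id] for t in survivors}
components = score_coding_potential(seqs, per_component=True)
lnc = consensus_noncoding(lnc, components)
print(f"per-predictor noncoding tallies: {predictor_tally(lnc)}")
print(f"consensus lncRNAs (noncoding by every predictor): "
      f"{len(lnc.consensus_ids())}")
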