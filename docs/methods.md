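# Methods

This note documents the models and numerical choices behind `droughtlnc`,
what the synthetic study generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Study design

All analyses are organised around 20 condition codes combining five
*Arabidopsis* genotypes (LEA-OE, VOC-OE, mLEA, VOC-RNAi, WT), two drought
durations (long-term, short-term) and two tissues (leaves, silique). Each
non-WT code is contrasted against the wild-type code with the same
duration and tissue (e.g. `AtLEALS_vs_WTLS`), giving 16 contrasts. The
default design has 2 replicates per code (40 samples); replication is a
generator parameter.

## lncRNA identification

Four filters, each recorded as its own boolean flag so a rejection names
its rule:

* length strictly greater than 200 bp — a 200-bp transcript is rejected;
* at least 2 exons — "above 2" is read as ≥ 2, since the 2-exon transcript
  is the canonical minimal spliced lncRNA that the field keeps;
* read support of at least 5 reads. Whether support was meant per sample
  or cumulatively is ambiguous; the default sums over all samples
  (`read_mode="total"`), with `"every_sample"` as the stricter option;
* identifier not present in the known mRNA/ncRNA list, and positional
  class code in {u, i, x}. Known-RNA exclusion is by ID list rather than
  sequence alignment: once assembly and alignment are upstream concerns,
  ID matching is the testable proxy.

Class codes map to positional classes: u → lincRNA, i → intronic,
x → antisense. A non-{u,i,x} code reaching classification is an internal
contract error, not a data error.

### Coding-potential consensus

The consensus rule is an AND over predictors: a transcript is called
lncRNA only if every supplied predictor labels it noncoding; a transcript
missing from a predictor's output is conservatively treated as coding.
External predictors enter as two-column label TSVs.

The built-in stand-in scorer computes per transcript: the maximum
ATG-initiated open reading frame over the three forward frames (an ORF
running off the 3′ end counts its readable codons); the Fickett TESTCODE
statistic with the canonical position/content lookup tables; and a mean
in-frame hexamer log-likelihood ratio over the max-ORF region. Hexamer
tables are trained at call time from the input itself — coding usage from
in-frame hexamers of sequences whose ORF reaches the threshold, background
from the remaining sequences, add-one smoothing — so no external training
data is required. The combined label is: coding iff max ORF ≥ 100 codons,
**or** both composition scores agree (Fickett ≥ 0.95 and hexamer LLR > 0).
Requiring agreement of the two composition scores keeps the stand-in's
false-coding rate low, which is what an intersection-style consensus
needs. With `per_component=True` the three components act as separate
predictors, reproducing the realistic situation where tools disagree.

## Expression statistics

FPKM = count · 10⁹ / (library size · transcript length), with the library
size the per-sample column sum. Zero lengths and zero library sizes are
errors.

The Jensen–Shannon specificity of transcript profile p against condition
i is 1 − √JSD(p, e_i), JSD in bits (log base 2, 0·log 0 ≡ 0), e_i the
indicator distribution. Replicates are aggregated per condition code by
the arithmetic mean before scoring (median available). No pseudocount is
added: zeros are handled by the 0·log 0 convention, keeping the score of a
single-condition transcript exactly 1. Scoring is over the 20 condition
codes by default, with an option to collapse to the two tissues; all-zero
transcripts are unscored. JSD is bounded in [0, 1] in bits, so the score
is bounded in [0, 1].

The lncRNA/mRNA comparison reports per-group exon counts, lengths, mean
FPKM and maximum JS, and a two-sided Wilcoxon rank-sum p-value for the
expression difference (exact enumeration for groups of ≤ 20 without ties,
tie-corrected normal approximation otherwise).

## Differential expression

A deliberately self-contained, desk-scale re-implementation of the
count-based DE recipe; planted-truth recovery, not bit-compatibility with
any external engine, is its contract.

* **Size factors**: median over all-positive transcripts of the ratio to
  the per-transcript geometric mean. On the default study the estimates
  track the true simulated depth factors to ~2–3%.
* **Dispersion**: per-transcript method of moments,
  α_g = (var_g − μ_g)/μ_g² computed within each group and pooled with
  degrees-of-freedom weights, floored at 10⁻⁸. Pooling the per-group
  dispersions (rather than the raw variances over a pooled mean) keeps α
  unbiased when the group means differ by a large fold change.
* **Test**: log₂FC = log₂((m_T + ε)/(m_C + ε)) with ε = 0.5 normalised
  counts so the estimate is always finite; delta-method standard error
  from the NB variance μ + αμ²; the Wald statistic is referred to a t
  distribution with n_T + n_C − 2 degrees of freedom. The t reference is
  a small-sample calibration choice: without dispersion shrinkage toward a
  fitted trend (which this engine intentionally omits), a normal reference
  is anti-conservative at 2–5 replicates. Under a 2,000-transcript no-DE
  null at 5 vs 5 the raw p < 0.05 fraction is ≈ 0.050; at 2 vs 2 the test
  is conservative (≈ 0.015), which is why DE-dependent demonstrations run
  at 5 replicates per code.
* **Multiplicity**: Benjamini–Hochberg (the standard choice behind
  "q-values" in count-based DE); q ≥ p and q is monotone in p.
* **Calling**: significant iff |log₂FC| ≥ 1 and q < 0.05. All-zero
  transcripts are flagged with p = 1 and log₂FC = 0.

Scale invariance holds in the practical sense: multiplying one sample's
counts by a constant is absorbed by its size factor up to a global
renormalisation constant, which leaks into the Poisson term of the
dispersion at O(1/mean) — negligible for expressed transcripts and never
enough to change a call, but not an exact 10⁻⁸-level identity.

## Target prediction

* **cis**: a protein-coding gene is a target if its genomic span lies
  within 50,000 bp of the lncRNA span on the same chromosome. Distance is
  the gap between spans (bases strictly between them), overlap counts as
  0, and the boundary is inclusive — "within 50 kb" admits a gap of
  exactly 50,000 bp and excludes 50,001. Strand-agnostic. Widening the
  window is monotone.
* **trans**: |Pearson r| ≥ 0.9 between lncRNA and gene expression over all
  samples. `trans_targets` computes raw Pearson on whatever matrix it is
  given; the pipeline feeds it log₂(FPKM+1), the standard co-expression
  transform, under which multiplicative co-regulation is linear and
  anti-regulation (a reciprocal response) is exactly anti-linear. On the
  raw FPKM scale, anti-correlated positive-valued pairs face a hard
  ceiling (|r| ≲ 0.91 at NB dispersion 0.05, since CV_x·CV_y ≤ 1 for
  anti-affine positive pairs), which would make the −0.9 threshold
  unattainable; the log scale removes this artefact. Constant-expression
  partners are excluded with a warning (r undefined); fewer than 3 samples
  is an error. The search space is protein-coding genes; whether the mRNA
  partner must itself be DE is left open by the method description, and
  the default does not require it.
* The multi-regulator summary ranks genes by the number of lncRNAs
  targeting them, one row per (gene, mode).

## Enrichment

Upper-tail hypergeometric probability P[X ≥ k] (observed k included, the
standard over-representation convention) for k query genes of a term with
K annotated genes, query size n, universe N; exact via the survival
function, verified against integer-arithmetic enumeration for every
configuration with N ≤ 60. The universe is the study's gene set
intersected with the annotation's gene universe; BH adjustment across
tested terms; enriched iff adjusted p < 0.05. Zero-overlap terms are
reported but can never be enriched. No GO-DAG propagation is applied (the
annotation is taken as given).

The null calibration study (random queries) uses a fine-grained
configuration — universe 1,000, term sizes 100–200, query 100 — because
with small terms the discrete hypergeometric is conservative and the
p < 0.05 fraction falls below its nominal level no matter the
implementation; at this granularity the measured fraction is ≈ 0.04.

## The synthetic study generator

The generator emulates the complete input set with planted, exactly
recorded truth. What it plants, and why the defaults are what they are:

* **Genome**: 2 chromosomes × 3 Mb, 120 coding genes (2–6 exons,
  600–2,400 bp spliced) with class code "=", placed sequentially with
  3–9 kb gaps. 60 base lncRNAs in mix u:i:x = 0.5:0.25:0.25; intergenic
  lncRNAs are placed between gene bodies, intronic ones inside a host
  gene's guaranteed-long intron, antisense ones overlapping a host on the
  opposite strand — the emitted class code is honest by construction.
  All planted lncRNAs have ≥ 2 exons and length in 300–1,200 bp.
* **Decoys** (all must be rejected): 5 short (≤ 200 bp), 5 single-exon,
  5 known-ID, 5 class-code "j", 3 low-read (support forced below 5 by
  construction so rejection is deterministic at every seed).
* **Sequences**: coding models embed an ATG-initiated ORF of > 100
  codons; all noncoding sequences are rejection-sampled until their
  maximum forward ORF is < 100 codons.
* **Counts**: NB with variance μ + αμ², one global dispersion α = 0.05
  (matching the DE model so parameter recovery is well-posed);
  per-transcript base means log₂-uniform on [4, 9]; noncoding transcripts
  shifted 3.5 log₂ units down so the planted lncRNA-below-mRNA expression
  asymmetry survives FPKM's division by length (lncRNAs are ~2.4× shorter);
  per-sample depth factors uniform on [0.7, 1.4] so size-factor estimation
  is non-trivial.
* **DE**: 30% of unplanted base lncRNAs plus all cis-pair lncRNAs get one
  signed effect |log₂FC| ~ U(1.5, 3.0) in one random non-WT code. The
  lower bound is 1.5, not 1.0: the caller requires the *estimated*
  |log₂FC| ≥ 1, and an unbiased estimator misses an effect planted exactly
  at the boundary ~50% of the time, so planting at the boundary would
  measure estimator attenuation, not pipeline correctness. Planted-effect
  transcripts draw base means from the upper-middle range (2^4.5–2^6.5) —
  detectable by construction without sitting atop the expression
  distribution.
* **Condition specificity**: 20% of unplanted lncRNAs are near-silent
  (mean 0.05) outside one condition code. Their maximum JS score is close
  to, but not exactly, 1 — a few stray counts over 19 silent conditions
  pull it to ~0.9, which is the realistic behaviour of the metric.
* **cis pairs**: dedicated isolated [gene]–gap–[lncRNA] blocks with gaps
  {0, 1 k, 10 k, 25 k, 40 k, 50,000} plus one decoy at 50,001; distances
  are exact by construction. The overlapping (gap 0) partner is antisense
  on the opposite strand, since an overlapping "u" would be dishonest.
* **trans modules**: 5 one-to-one pairs plus one hub gene with 8
  regulators = 6 modules. Each module has a latent expression profile over
  the four (treatment × tissue) strata; profiles are drawn from a bank of
  six icosahedral directions expressed in an orthonormal stratum-contrast
  basis, so distinct modules are pairwise decorrelated (|cos| = 1/√5) and
  chance cross-module edges are geometrically excluded. Stratum-level
  latents cancel exactly in every genotype-vs-matched-WT contrast (both
  sides share the stratum), so they never masquerade as DE. Positive
  regulators share the gene's latent; negative regulators get its
  reciprocal (exactly anti-linear on the log scale). Each module carries
  one shared DE effect — applied to the gene and its positive regulators
  in a code of the module's maximal-latent stratum, i.e. where the module
  is expressed — so the bump is common-mode and the planted correlation
  survives it. Latent strength σ = 1.1 and trans-member base means
  2^7–2^9 were calibrated once, by simulation across seeds before the
  test suite was written, to put planted |r| ≥ 0.9 at a ≥ 99% per-pair
  rate; larger σ is counterproductive because low-latent strata fall into
  count-discretization noise.
* **Terms**: the planted enriched terms cover ~80% of the *expected*
  end-to-end target set — every coding gene within the cis window of a DE
  or condition-specific lncRNA plus the trans-module genes — which the
  generator computes exactly from its own truth; 30 background terms are
  random gene sets.

Everything is deterministic under the seed: two runs emit byte-identical
files.

### What the generator does not emulate

Read-level artefacts (no FASTQ, no mapping ambiguity), splice-isoform
complexity, batch effects beyond a scalar depth factor, gene-specific
dispersion trends, correlated background co-expression, and annotation
errors. Passing tests therefore demonstrate that the implementations
recover what their models define on data generated *from those models* —
they do not certify performance on real libraries, where dispersion
varies per gene, class codes err, and co-expression is pervasive.

## Problem sizes

The default study is 230 transcripts × 40 samples; DE recovery and the
end-to-end demonstrations use 5 replicates per code (100 samples); the
null calibrations use 2,000 transcripts (DE) and 200 random queries
(enrichment); the trans brute-force cross-check uses 500 × 500 pairs.
These sizes keep the full test suite and the acceptance script in the
seconds-to-a-minute range while leaving every estimate's Monte-Carlo
error well inside the asserted bounds.

## Known limitations

The DE engine has no dispersion shrinkage, so at 2 replicates it is very
conservative — real studies at n = 2 need an engine with information
sharing across genes (DESeq2, edgeR). The Fickett/hexamer stand-in is a
structural stand-in for the four external coding-potential tools, not a
re-implementation of them. Cis distance is span-gap based; TSS-anchored
definitions would shift distances for long genes. Enrichment treats terms
as flat sets (no ontology structure).
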