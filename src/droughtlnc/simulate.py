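"""Synthetic study generator with planted ground truth.

Emulates the full input set of the drought-stress lncRNA study design —
five Arabidopsis genotypes (LEA-OE, VOC-OE, mLEA, VOC-RNAi, WT) x two
drought durations x two tissues, 20 condition codes with replicates — and
plants a known answer for every downstream stage:

* lncRNAs of the three positional classes (intergenic "u", intronic "i",
  antisense "x"), all >200 bp with >=2 exons by construction;
* deliberate filter decoys (short, single-exon, known-ID, wrong class code,
  low read support) that the identification filters must reject;
* differential expression with |log2 fold change| >= 1 in a chosen
  genotype-vs-matched-WT contrast;
* cis lncRNA-gene pairs at controlled genomic gaps, including one at
  exactly 50,000 bp and one just beyond at 50,001 bp;
* trans lncRNA-gene pairs whose expression shares a log-normal latent
  factor, yielding |Pearson r| >= 0.9 on FPKM, plus one hub gene regulated
  by several lncRNAs at once;
* condition-specific transcripts (maximum Jensen-Shannon score 1);
* functional terms enriched in the planted target-gene set.

Counts are negative binomial with variance mu + alpha*mu^2 (one global
dispersion alpha), matching the differential-expression module's model so
parameter recovery is well-posed.  Everything is deterministic under the
seed: two runs emit byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .identify import max_orf_codons
from .model import (
    CONDITION_CODES,
    WT_CONTROL,
    ExpressionMatrix,
    Sample,
    SampleTable,
    TermAnnotation,
    Transcript,
    ValidationError,
)

_PHI = (1 + 5**0.5) / 2
#: six icosahedral axes in R^3, pairwise |cos| = 1/sqrt(5): the latent
#: profile bank keeping distinct trans modules decorrelated by design
_ICOSA = (
    np.array(
        [
            [0.0, 1.0, _PHI],
            [0.0, 1.0, -_PHI],
            [1.0, _PHI, 0.0],
            [1.0, -_PHI, 0.0],
            [_PHI, 0.0, 1.0],
            [-_PHI, 0.0, 1.0],
        ]
    )
    / np.sqrt(1 + _PHI**2)
)
#: orthonormal mean-zero contrast basis over the four (treatment, tissue)
#: strata; latent profiles live in this subspace so every stratum keeps
#: overall mean expression
_STRATUM_CONTRASTS = np.array(
    [[1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1]], dtype=float
) / 2.0

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SyntheticConfig:
    """Generator knobs.  Defaults are the study conditions the pipeline
    is validated against; see docs/methods.md for the rationale of each."""

    seed: int = 42
    n_chromosomes: int = 2
    chrom_length: int = 3_000_000
    n_coding_genes: int = 120
    n_lncrna: int = 60
    class_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # u, i, x
    n_samples_per_code: int = 2
    nb_dispersion: float = 0.05
    base_mean_log2_range: tuple[float, float] = (4.0, 9.0)
    planted_mean_log2_range: tuple[float, float] = (4.5, 6.5)
    trans_mean_log2_range: tuple[float, float] = (7.0, 9.0)
    lnc_mean_log2_offset: float = -3.5  # lncRNAs are lower expressed than mRNA
    de_fraction: float = 0.3
    de_log2fc_min: float = 1.5
    de_log2fc_span: float = 1.5  # |lfc| ~ U(min, min + span)
    cis_pair_count: int = 6
    trans_pair_count: int = 5  # one-to-one pairs; with the hub, six modules
    multi_regulator_count: int = 8
    trans_target_r: float = 0.9
    trans_latent_sigma: float = 1.1  # calibrated by simulation over seeds
    specific_fraction: float = 0.2
    enriched_terms: int = 2
    n_background_terms: int = 30
    n_decoy_short: int = 5
    n_decoy_single_exon: int = 5
    n_decoy_known: int = 5
    n_decoy_class: int = 5
    n_decoy_low_reads: int = 3
    depth_range: tuple[float, float] = (0.7, 1.4)

    def validate(self) -> None:
        if self.de_log2fc_min < 1.0:
            raise ValidationError("de_log2fc_min must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.specific_fraction <= 1.0:
            raise ValidationError("specific_fraction must be in [0, 1]")
        if self.trans_target_r < 0.9:
            raise ValidationError("trans_target_r must be >= 0.9")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValidationError("class_mix must sum to 1")
        for name in (
            "n_chromosomes",
            "n_coding_genes",
            "n_lncrna",
            "n_samples_per_code",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth the generator plants; every ID exists in the emitted
    annotation and every planted quantity is exact by construction."""

    lncrna_ids: dict[str, list[str]] = field(default_factory=dict)  # class -> ids
    coding_ids: list[str] = field(default_factory=list)
    decoy_ids: dict[str, list[str]] = field(default_factory=dict)  # reason -> ids
    known_ids: list[str] = field(default_factory=list)
    de: list[dict] = field(default_factory=list)  # {id, contrast, log2fc}
    cis_pairs: list[dict] = field(default_factory=list)  # {lncrna, gene, distance}
    cis_decoy_pairs: list[dict] = field(default_factory=list)  # beyond window
    trans_pairs: list[dict] = field(default_factory=list)  # {lncrna, gene, sign}
    trans_latent: dict[str, dict[str, float]] = field(default_factory=dict)
    specific: list[dict] = field(default_factory=list)  # {id, code}
    enriched_term_ids: list[str] = field(default_factory=list)
    target_gene_ids: list[str] = field(default_factory=list)

    @property
    def all_lncrna_ids(self) -> list[str]:
        out: list[str] = []
        for ids in self.lncrna_ids.values():
            out.extend(ids)
        return out

    @property
    def de_ids(self) -> list[str]:
        return [d["id"] for d in self.de]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# annotation


def _make_exons(
    rng: np.random.Generator, start: int, total_len: int, n_exons: int
) -> tuple[tuple[int, int], ...]:
    """Exon chain beginning at `start` with given spliced length and count."""
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [total_len]])).astype(int)
    exons = []
    pos = start
    for i, sz in enumerate(sizes):
        exons.append((pos, pos + sz - 1))
        pos += sz + (int(rng.integers(100, 800)) if i < len(sizes) - 1 else 0)
    return tuple(exons)


def _lnc_exons(rng: np.random.Generator, start: int, min_len: int = 300,
               max_len: int = 1200) -> tuple[tuple[int, int], ...]:
    total = int(rng.integers(min_len, max_len + 1))
    return _make_exons(rng, start, total, int(rng.integers(2, 5)))


class _Layout:
    """Sequential placement cursor for one chromosome."""

    def __init__(self, chrom: str, limit: int):
        self.chrom = chrom
        self.cursor = 1000
        self.limit = limit

    def advance(self, span: int, gap: int) -> int:
        start = self.cursor
        self.cursor = start + span + gap
        if self.cursor > self.limit:
            raise ValidationError(
                f"chromosome {self.chrom} too short ({self.limit} bp) for the "
                "requested gene count; increase chrom_length or n_chromosomes"
            )
        return start


def simulate_annotation(
    config: SyntheticConfig,
) -> tuple[list[Transcript], set[str], PlantedTruth]:
    """Emit the transcript models, the known-RNA ID list and the truth.

    Coding genes carry class code "="; lncRNAs are placed so their class
    code is honest: "u" outside every gene body, "i" inside a host intron,
    "x" overlapping a host on the opposite strand.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth(lncrna_ids={"u": [], "i": [], "x": []})
    transcripts: list[Transcript] = []
    known: set[str] = set()

    layouts = [
        _Layout(f"chr{i + 1}", config.chrom_length)
        for i in range(config.n_chromosomes)
    ]

    n_u = int(round(config.n_lncrna * config.class_mix[0]))
    n_i = int(round(config.n_lncrna * config.class_mix[1]))
    n_x = config.n_lncrna - n_u - n_i

    def next_layout(k: int) -> _Layout:
        return layouts[k % len(layouts)]

    gene_counter = 0
    lnc_counter = 0

    def new_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GENE{gene_counter:04d}"

    def new_lnc_id() -> str:
        nonlocal lnc_counter
        lnc_counter += 1
        return f"LNC{lnc_counter:04d}"

    def add_coding(lay: _Layout, intron_bp: int = 0) -> Transcript:
        gid = new_gene_id()
        total = int(rng.integers(600, 2400))
        n_ex = int(rng.integers(2, 7))
        start = lay.cursor
        if intron_bp:
            # two exons flanking one guaranteed-long intron
            half = max(total // 2, 200)
            exons = (
                (start, start + half - 1),
                (start + half + intron_bp, start + half + intron_bp + half - 1),
            )
        else:
            exons = _make_exons(rng, start, total, n_ex)
        t = Transcript(
            transcript_id=f"{gid}.1",
            gene_id=gid,
            chrom=lay.chrom,
            start=exons[0][0],
            end=exons[-1][1],
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons,
            class_code="=",
        )
        lay.advance(t.end - t.start + 1, int(rng.integers(3000, 9000)))
        transcripts.append(t)
        truth.coding_ids.append(t.transcript_id)
        known.add(t.transcript_id)
        return t

    def add_u_lnc(lay: _Layout, lnc_id: str | None = None) -> Transcript:
        lid = lnc_id or new_lnc_id()
        exons = _lnc_exons(rng, lay.cursor)
        t = Transcript(
            transcript_id=lid,
            gene_id=lid,
            chrom=lay.chrom,
            start=exons[0][0],
            end=exons[-1][1],
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons,
            class_code="u",
        )
        lay.advance(t.end - t.start + 1, int(rng.integers(3000, 9000)))
        transcripts.append(t)
        return t

    # ordinary coding genes, spread over chromosomes; reserve hosts for i/x
    n_hosts_i = n_i
    n_hosts_x = n_x
    n_plain = config.n_coding_genes - n_hosts_i - n_hosts_x
    if n_plain < config.cis_pair_count + 1:
        raise ValidationError(
            "n_coding_genes too small for the requested lncRNA and cis-pair counts"
        )

    for k in range(n_plain):
        add_coding(next_layout(k))

    # intronic lncRNAs inside dedicated hosts with a long intron
    for k in range(n_hosts_i):
        lay = next_layout(k)
        lid = new_lnc_id()
        intron_bp = int(rng.integers(1800, 3200))
        host = add_coding(lay, intron_bp=intron_bp)
        intron_lo = host.exons[0][1] + 1
        exons = _lnc_exons(
            rng, intron_lo + 50, min_len=300, max_len=min(900, intron_bp - 200)
        )
        if exons[-1][1] >= host.exons[1][0]:
            # compress: fall back to two tight exons inside the intron
            a = intron_lo + 50
            exons = ((a, a + 180), (a + 260, a + 260 + 180))
        t = Transcript(
            transcript_id=lid,
            gene_id=lid,
            chrom=host.chrom,
            start=exons[0][0],
            end=exons[-1][1],
            strand=host.strand,
            exons=exons,
            class_code="i",
        )
        transcripts.append(t)
        truth.lncrna_ids["i"].append(lid)

    # antisense lncRNAs overlapping dedicated hosts on the opposite strand
    for k in range(n_hosts_x):
        lay = next_layout(k + 1)
        host = add_coding(lay)
        lid = new_lnc_id()
        exons = _lnc_exons(rng, host.start + 20)
        t = Transcript(
            transcript_id=lid,
            gene_id=lid,
            chrom=host.chrom,
            start=exons[0][0],
            end=exons[-1][1],
            strand="-" if host.strand == "+" else "+",
            exons=exons,
            class_code="x",
        )
        transcripts.append(t)
        truth.lncrna_ids["x"].append(lid)

    # intergenic lncRNAs in the placement stream (outside all gene bodies)
    for k in range(n_u):
        t = add_u_lnc(next_layout(k))
        truth.lncrna_ids["u"].append(t.transcript_id)

    # cis pairs: [gene]--gap--[lncRNA], isolated by wide margins.
    # Gaps cover the window including its exact boundary, plus one decoy
    # 1 bp beyond it.
    within = [0, 1_000, 10_000, 25_000, 40_000, 50_000]
    gaps = (within * ((config.cis_pair_count // len(within)) + 1))[
        : config.cis_pair_count
    ]
    gaps = sorted(gaps)
    for k, gap in enumerate(gaps + [50_001]):
        lay = next_layout(k)
        lay.advance(0, 60_000)  # isolation margin before the block
        gene = add_coding(lay)
        lid = new_lnc_id()
        if gap == 0:
            # overlapping placement: honest class code is antisense
            a = gene.start + 10
            strand = "-" if gene.strand == "+" else "+"
            code = "x"
        else:
            a = gene.end + gap + 1  # gap bp strictly between the two spans
            strand, code = "+", "u"
        exons = _lnc_exons(rng, a)
        t = Transcript(
            transcript_id=lid,
            gene_id=lid,
            chrom=gene.chrom,
            start=exons[0][0],
            end=exons[-1][1],
            strand=strand,
            exons=exons,
            class_code=code,
        )
        transcripts.append(t)
        truth.lncrna_ids[code].append(lid)
        lay.cursor = max(lay.cursor, t.end + 1) + 60_000
        rec = {"lncrna": lid, "gene": gene.gene_id, "distance": gap}
        if gap <= 50_000:
            truth.cis_pairs.append(rec)
        else:
            truth.cis_decoy_pairs.append(rec)

    # trans-pair lncRNAs (and the multi-regulator hub) are intergenic
    trans_lnc: list[str] = []
    for k in range(config.trans_pair_count + config.multi_regulator_count):
        t = add_u_lnc(next_layout(k))
        truth.lncrna_ids["u"].append(t.transcript_id)
        trans_lnc.append(t.transcript_id)

    plain_genes = [t.rsplit(".", 1)[0] for t in truth.coding_ids[:n_plain]]
    cis_genes = {p["gene"] for p in truth.cis_pairs + truth.cis_decoy_pairs}
    pool = [g for g in plain_genes if g not in cis_genes]
    trans_genes = list(rng.choice(pool, size=config.trans_pair_count + 1, replace=False))
    hub_gene = trans_genes[-1]
    for k in range(config.trans_pair_count):
        sign = 1 if k % 2 == 0 else -1
        truth.trans_pairs.append(
            {"lncrna": trans_lnc[k], "gene": trans_genes[k], "sign": sign}
        )
    for k in range(config.multi_regulator_count):
        truth.trans_pairs.append(
            {
                "lncrna": trans_lnc[config.trans_pair_count + k],
                "gene": hub_gene,
                "sign": 1,
            }
        )

    # decoys ------------------------------------------------------------
    truth.decoy_ids = {k: [] for k in ("short", "single_exon", "known", "class", "low_reads")}
    for k in range(config.n_decoy_short):
        lay = next_layout(k)
        did = f"DECOY_SHORT{k + 1:02d}"
        total = int(rng.integers(120, 201))  # length <= 200, still 2 exons
        exons = _make_exons(rng, lay.cursor, total, 2)
        t = Transcript(did, did, lay.chrom, exons[0][0], exons[-1][1], "+", exons, "u")
        lay.advance(t.end - t.start + 1, 4000)
        transcripts.append(t)
        truth.decoy_ids["short"].append(did)
    for k in range(config.n_decoy_single_exon):
        lay = next_layout(k)
        did = f"DECOY_MONO{k + 1:02d}"
        total = int(rng.integers(400, 1000))
        start = lay.cursor
        t = Transcript(did, did, lay.chrom, start, start + total - 1, "+",
                       ((start, start + total - 1),), "u")
        lay.advance(total, 4000)
        transcripts.append(t)
        truth.decoy_ids["single_exon"].append(did)
    for k in range(config.n_decoy_known):
        lay = next_layout(k)
        did = f"KNOWN_NC{k + 1:02d}"  # e.g. an annotated snoRNA/rRNA locus
        t = add_u_lnc(lay, lnc_id=did)
        transcripts.remove(t)  # re-append with the decoy id kept, class u
        transcripts.append(t)
        known.add(did)
        truth.decoy_ids["known"].append(did)
    for k in range(config.n_decoy_class):
        lay = next_layout(k)
        did = f"DECOY_J{k + 1:02d}"  # novel isoform of a known gene: class "j"
        exons = _lnc_exons(rng, lay.cursor)
        t = Transcript(did, did, lay.chrom, exons[0][0], exons[-1][1], "+", exons, "j")
        lay.advance(t.end - t.start + 1, 4000)
        transcripts.append(t)
        truth.decoy_ids["class"].append(did)
    for k in range(config.n_decoy_low_reads):
        lay = next_layout(k)
        did = f"DECOY_LOW{k + 1:02d}"
        exons = _lnc_exons(rng, lay.cursor)
        t = Transcript(did, did, lay.chrom, exons[0][0], exons[-1][1], "+", exons, "u")
        lay.advance(t.end - t.start + 1, 4000)
        transcripts.append(t)
        truth.decoy_ids["low_reads"].append(did)

    truth.known_ids = sorted(known)
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return transcripts, known, truth


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _orf_poor_seq(rng: np.random.Generator, n: int, max_codons: int) -> str:
    """Random sequence rejected until no forward-frame ORF reaches max_codons."""
    for _ in range(200):
        s = _random_seq(rng, n)
        if max_orf_codons(s) < max_codons:
            return s
    raise RuntimeError("rejection sampling failed to find an ORF-poor sequence")


def _coding_seq(rng: np.random.Generator, n: int, min_codons: int) -> str:
    """Sequence of length n containing an in-frame ORF of >= min_codons codons."""
    n_codons = max(min_codons, (n - 60) // 3 - 1)
    orf = "ATG" + "".join(
        np.array(_NONSTOP_CODONS)[rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 1)]
    ) + "TAA"
    pad = n - len(orf)
    if pad < 0:
        return orf[: n] if n >= len(orf) else orf  # ORF dominates short models
    lead = int(rng.integers(0, pad + 1))
    return _random_seq(rng, lead) + orf + _random_seq(rng, pad - lead)


def simulate_sequences(
    transcripts: list[Transcript],
    truth: PlantedTruth,
    config: SyntheticConfig,
    orf_min_codons: int = 100,
) -> dict[str, str]:
    """Spliced sequences: coding models carry a long ORF, everything else is
    ORF-poor by rejection sampling.  Deterministic under the config seed."""
    rng = np.random.default_rng(config.seed + 1)
    coding = set(truth.coding_ids)
    out: dict[str, str] = {}
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        if t.transcript_id in coding:
            out[t.transcript_id] = _coding_seq(rng, max(t.length, 3 * (orf_min_codons + 2)), orf_min_codons + 1)
        else:
            out[t.transcript_id] = _orf_poor_seq(rng, t.length, orf_min_codons)
    return {t.transcript_id: out[t.transcript_id] for t in transcripts}


# ---------------------------------------------------------------------------
# counts


def make_sample_table(config: SyntheticConfig) -> SampleTable:
    samples = [
        Sample(f"{code}_r{rep}", code, rep)
        for code in CONDITION_CODES
        for rep in range(1, config.n_samples_per_code + 1)
    ]
    return SampleTable(samples)


def plant_de_and_specific(
    truth: PlantedTruth, config: SyntheticConfig, rng: np.random.Generator
) -> None:
    """Assign DE contrasts/effects and condition-specific status in truth."""
    non_wt = [c for c in CONDITION_CODES if CONDITION_CODES[c][0] != "WT"]
    cis_lnc = [p["lncrna"] for p in truth.cis_pairs + truth.cis_decoy_pairs]
    trans_lnc = [p["lncrna"] for p in truth.trans_pairs]
    planted = set(cis_lnc) | set(trans_lnc)
    base_pool = [l for l in truth.all_lncrna_ids if l not in planted]

    n_spec = int(round(config.specific_fraction * len(base_pool)))
    spec_ids = list(rng.choice(base_pool, size=n_spec, replace=False))
    for lid in spec_ids:
        code = str(rng.choice(list(CONDITION_CODES)))
        truth.specific.append({"id": lid, "code": code})

    def plant(tid: str, code: str, lfc: float) -> None:
        truth.de.append(
            {"id": tid, "contrast": f"{code}_vs_{WT_CONTROL[code]}",
             "code": code, "log2fc": round(float(lfc), 4)}
        )

    de_pool = [l for l in base_pool if l not in set(spec_ids)]
    n_de = int(round(config.de_fraction * len(de_pool)))
    de_ids = list(rng.choice(de_pool, size=n_de, replace=False))
    for lid in de_ids + cis_lnc:
        code = str(rng.choice(non_wt))
        mag = config.de_log2fc_min + config.de_log2fc_span * rng.random()
        sign = 1.0 if rng.random() < 0.5 else -1.0
        plant(lid, code, sign * mag)

    # Trans pairs are co-regulated modules: each target gene gets a latent
    # expression profile over the four (treatment, tissue) strata, and one
    # DE effect shared by the gene and its positively correlated
    # regulators (common-mode, so the planted correlation survives the
    # bump).  The DE effect is planted in the module's maximal-latent
    # stratum — the regulatory effect shows where the module is expressed.
    # Anti-correlated regulators carry no DE plant of their own: their
    # profile is the reciprocal of the gene's latent.
    def stratum_of(code: str) -> str:
        return CONDITION_CODES[code][1] + "/" + CONDITION_CODES[code][2]

    strata = sorted({stratum_of(c) for c in CONDITION_CODES})
    # per-stratum latent profiles: icosahedral directions in the contrast
    # basis, scaled to per-stratum variance 1.25; distinct modules are
    # pairwise decorrelated (|cos| = 1/sqrt(5)) by construction
    profiles = _ICOSA @ _STRATUM_CONTRASTS * np.sqrt(5.0)
    by_gene: dict[str, list[dict]] = {}
    for p in truth.trans_pairs:
        by_gene.setdefault(p["gene"], []).append(p)
    order = rng.permutation(len(profiles))
    for g_i, (gene, pairs) in enumerate(by_gene.items()):
        if g_i < len(profiles):
            z_vec = profiles[order[g_i]] * (1.0 if rng.random() < 0.5 else -1.0)
        else:  # more modules than bank entries: fall back to random draws
            z_vec = rng.standard_normal(len(strata)) * 1.118
        z_by = dict(zip(strata, z_vec))
        truth.trans_latent[gene] = {k: float(v) for k, v in z_by.items()}
        positives = [p for p in pairs if p["sign"] > 0]
        if not positives:
            continue
        top = max(z_by, key=z_by.get)
        code = str(rng.choice([c for c in non_wt if stratum_of(c) == top]))
        mag = config.de_log2fc_min + config.de_log2fc_span * rng.random()
        sign = 1.0 if rng.random() < 0.5 else -1.0
        plant(gene + ".1", code, sign * mag)
        for p in positives:
            plant(p["lncrna"], code, sign * mag)


def simulate_counts(
    transcripts: list[Transcript],
    truth: PlantedTruth,
    config: SyntheticConfig,
    sample_table: SampleTable | None = None,
) -> ExpressionMatrix:
    """Negative-binomial counts honouring every planted effect.

    Per-transcript base means are log2-uniform; planted DE multiplies the
    mean by 2^log2fc in the treated code's samples; trans pairs share a
    log-normal latent factor across samples (inverted for negative pairs);
    condition-specific transcripts are near-silent outside their code; a
    per-sample depth factor makes size-factor estimation non-trivial.
    """
    if sample_table is None:
        sample_table = make_sample_table(config)
    rng = np.random.default_rng(config.seed + 2)

    ids = [t.transcript_id for t in transcripts]
    idx = {tid: i for i, tid in enumerate(ids)}
    n_t, n_s = len(ids), len(sample_table)
    codes = np.array([s.code for s in sample_table])

    lo, hi = config.base_mean_log2_range
    base = 2.0 ** rng.uniform(lo, hi, size=n_t)

    # noncoding transcripts sit lower than mRNA, the expression asymmetry
    # the lncRNA/mRNA comparison measures
    noncoding_rows = [i for i, t in enumerate(transcripts) if t.class_code != "="]
    base[noncoding_rows] *= 2.0 ** config.lnc_mean_log2_offset

    # Planted-effect transcripts draw means making their signal detectable
    # by construction, not by luck of the draw.  Trans-module members need
    # the upper range (the latent sweeps their counts over ~e^±2, and the
    # low strata must stay clear of count-discretization noise); ordinary
    # DE plants keep lncRNA-realistic moderate means.
    trans_rows = sorted(
        {idx[p["lncrna"]] for p in truth.trans_pairs}
        | {
            idx[p["gene"] + ".1" if p["gene"] + ".1" in idx else p["gene"]]
            for p in truth.trans_pairs
        }
    )
    p_lo, p_hi = config.planted_mean_log2_range
    de_rows = sorted({idx[r["id"]] for r in truth.de} - set(trans_rows))
    base[de_rows] = 2.0 ** rng.uniform(p_lo, p_hi, size=len(de_rows))
    t_lo, t_hi = config.trans_mean_log2_range
    base[trans_rows] = 2.0 ** rng.uniform(t_lo, t_hi, size=len(trans_rows))
    mean = np.tile(base[:, None], (1, n_s)).astype(float)

    for rec in truth.specific:
        i = idx[rec["id"]]
        high = max(base[i], 2.0 ** ((lo + hi) / 2))
        mean[i, :] = 0.05
        mean[i, codes == rec["code"]] = high

    for rec in truth.de:
        i = idx[rec["id"]]
        mean[i, codes == rec["code"]] *= 2.0 ** rec["log2fc"]

    # Shared latent factors drive trans correlation; one latent per target
    # gene so a hub gene's regulators all ride the same factor.  The latent
    # varies over the four (treatment, tissue) strata, not per sample, so
    # it cancels exactly in every genotype-vs-matched-WT contrast and the
    # planted fold changes stay recoverable.
    sigma = config.trans_latent_sigma
    stratum = np.array(
        [CONDITION_CODES[c][1] + "/" + CONDITION_CODES[c][2] for c in codes]
    )
    gene_factor: dict[str, np.ndarray] = {}
    for rec in truth.trans_pairs:
        g = rec["gene"]
        if g not in gene_factor:
            z_by = truth.trans_latent.get(g)
            if z_by is None:  # truth without planted latents: no correlation
                gene_factor[g] = np.ones(n_s)
                continue
            z = np.array([z_by[s] for s in stratum])
            f = np.exp(sigma * z)
            gene_factor[g] = f / f.mean()
            mean[idx[g + ".1" if g + ".1" in idx else g], :] *= gene_factor[g]
        f = gene_factor[g]
        if rec["sign"] > 0:
            h = f
        else:
            # reciprocal latent: exactly anti-linear on the log scale
            h = 1.0 / f
            h = h / h.mean()
        mean[idx[rec["lncrna"]], :] *= h

    for did in truth.decoy_ids.get("low_reads", []):
        mean[idx[did], :] = 0.0  # counts set explicitly below

    depth = rng.uniform(*config.depth_range, size=n_s)
    mean *= depth[None, :]

    r = 1.0 / config.nb_dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    counts = rng.negative_binomial(r, p)
    counts[mean == 0] = 0

    # low-read decoys: total support strictly below the 5-read filter
    for did in truth.decoy_ids.get("low_reads", []):
        row = np.zeros(n_s, dtype=np.int64)
        row[:4] = 1
        counts[idx[did], :] = row

    df = pd.DataFrame(counts, index=ids, columns=sample_table.sample_ids)
    return ExpressionMatrix(df, unit="counts")


# ---------------------------------------------------------------------------
# term annotation


def simulate_terms(
    truth: PlantedTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
    transcripts: list[Transcript],
) -> list[TermAnnotation]:
    """Background terms of random genes plus planted terms concentrated in
    the expected target-gene set of the differentially expressed lncRNAs
    (every coding gene within the cis window of a DE or condition-specific
    lncRNA, plus the trans-module genes), which the generator can compute
    exactly from its own truth."""
    from .targets import cis_targets

    universe = sorted({t.rsplit(".", 1)[0] for t in truth.coding_ids})
    tmap = {t.transcript_id: t for t in transcripts}
    coding = [t for t in transcripts if t.class_code == "="]
    lnc_ids = set(truth.all_lncrna_ids)
    expected_de = sorted(
        (set(truth.de_ids) & lnc_ids) | {r["id"] for r in truth.specific}
    )
    cis_edges = cis_targets([tmap[l] for l in expected_de], coding)
    targets = sorted(
        {e.gene_id for e in cis_edges} | {p["gene"] for p in truth.trans_pairs}
    )
    truth.target_gene_ids = targets
    terms: list[TermAnnotation] = []
    for k in range(config.enriched_terms):
        tid = f"TERM_ENR{k + 1:02d}"
        n_tgt = max(2, int(round(0.8 * len(targets))))
        chosen = list(rng.choice(targets, size=min(n_tgt, len(targets)), replace=False))
        n_bg = int(rng.integers(1, 4))
        bg = [g for g in universe if g not in set(chosen)]
        chosen += list(rng.choice(bg, size=n_bg, replace=False))
        terms.append(TermAnnotation(tid, f"planted enriched term {k + 1}", frozenset(chosen)))
        truth.enriched_term_ids.append(tid)
    for k in range(config.n_background_terms):
        tid = f"TERM_BG{k + 1:03d}"
        size = int(rng.integers(8, 30))
        genes = list(rng.choice(universe, size=size, replace=False))
        terms.append(TermAnnotation(tid, f"background term {k + 1}", frozenset(genes)))
    return terms


# ---------------------------------------------------------------------------
# one-call fixture


@dataclass
class Fixture:
    config: SyntheticConfig
    transcripts: list[Transcript]
    known_ids: set[str]
    truth: PlantedTruth
    sequences: dict[str, str]
    sample_table: SampleTable
    counts: ExpressionMatrix
    terms: list[TermAnnotation]


def simulate_study(config: SyntheticConfig | None = None) -> Fixture:
    """Generate the complete input set in memory."""
    config = config or SyntheticConfig()
    transcripts, known, truth = simulate_annotation(config)
    rng = np.random.default_rng(config.seed + 3)
    plant_de_and_specific(truth, config, rng)
    sequences = simulate_sequences(transcripts, truth, config)
    sample_table = make_sample_table(config)
    counts = simulate_counts(transcripts, truth, config, sample_table)
    terms = simulate_terms(truth, config, rng, transcripts)
    return Fixture(config, transcripts, known, truth, sequences, sample_table, counts, terms)


def evaluate_de_calls(
    truth: PlantedTruth, calls_by_contrast: Mapping[str, set[str]]
) -> dict[str, float]:
    """Recall of the planted DE lncRNAs and false-discovery proportion of
    the lncRNA calls.

    A call (transcript, contrast) counts as true when the transcript was
    planted DE in that contrast, or is condition-specific to one of the
    contrast's two codes: a transcript silent everywhere except code X is
    genuinely differentially expressed in every contrast touching X.
    """
    planted = {(r["id"], r["contrast"]) for r in truth.de}
    spec_code = {r["id"]: r["code"] for r in truth.specific}
    lnc = set(truth.all_lncrna_ids)

    def is_true(tid: str, contrast: str) -> bool:
        if (tid, contrast) in planted:
            return True
        code_t, code_c = contrast.split("_vs_")
        return spec_code.get(tid) in {code_t, code_c}

    tp_recall = sum(
        1 for tid, cn in planted if tid in calls_by_contrast.get(cn, set())
    )
    lnc_calls = [
        (tid, cn)
        for cn, ids in calls_by_contrast.items()
        for tid in ids
        if tid in lnc
    ]
    fp = sum(1 for tid, cn in lnc_calls if not is_true(tid, cn))
    return {
        "recall": tp_recall / len(planted) if planted else float("nan"),
        "fdp": fp / len(lnc_calls) if lnc_calls else 0.0,
        "n_planted": len(planted),
        "n_calls": len(lnc_calls),
    }


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the six pipeline inputs plus the truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "transcripts.gtf",
        "fasta": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "known": outdir / "known_ids.txt",
        "terms": outdir / "terms.tsv",
        "truth": outdir / "truth.json",
    }
    dio.write_gtf(fixture.transcripts, paths["gtf"])
    dio.write_fasta(fixture.sequences, paths["fasta"])
    dio.write_matrix(fixture.counts, paths["counts"])
    dio.write_sample_table(fixture.sample_table, paths["samples"])
    dio.write_id_list(fixture.known_ids, paths["known"])
    dio.write_term_annotation(fixture.terms, paths["terms"])
    fixture.truth.to_json(paths["truth"])
    return paths
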