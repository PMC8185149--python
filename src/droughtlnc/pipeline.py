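"""End-to-end orchestration of the pipeline stages over files on disk.

Each ``run_*`` function reads its inputs, executes one stage and writes
TSV results whose header lines record the package version, seed and every
threshold, so any output is traceable to its parameters.  ``run_all``
chains the stages and emits a run summary mirroring the per-stage counts
a study report would give (lncRNAs per class, DE per contrast, target
edges, enriched terms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffexpr, enrichment, expression, identify, io as dio, targets
from .model import ExpressionMatrix, ValidationError, transcripts_by_id
from .simulate import SyntheticConfig, simulate_study, write_fixture


class InputError(FileNotFoundError):
    """A required input file is missing; message names the producing stage."""


@dataclass
class PipelineConfig:
    """All paths and thresholds; defaults are the study's stated values."""

    gtf: str = "transcripts.gtf"
    fasta: str = "transcripts.fa"
    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    known_ids: str = "known_ids.txt"
    terms: str = "terms.tsv"
    out_dir: str = "results"
    min_length: int = 200
    min_exons: int = 2
    min_reads: int = 5
    read_mode: str = "total"
    lfc_min: float = 1.0
    q_max: float = 0.05
    cis_window: int = 50_000
    trans_r: float = 0.9
    enrich_p: float = 0.05
    orf_min_codons: int = 100
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def header_lines(self) -> list[str]:
        thresholds = (
            f"min_length={self.min_length} min_exons={self.min_exons} "
            f"min_reads={self.min_reads} read_mode={self.read_mode} "
            f"lfc_min={self.lfc_min} q_max={self.q_max} "
            f"cis_window={self.cis_window} trans_r={self.trans_r} "
            f"enrich_p={self.enrich_p} orf_min_codons={self.orf_min_codons}"
        )
        return [
            f"# droughtlnc v{__version__} seed={self.seed}",
            f"# {thresholds}",
        ]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_result_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _require(path: str | Path, producer: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing input {path}; run `{producer}` first")
    return path


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: PipelineConfig, fixture_dir: str | Path,
                 synthetic: SyntheticConfig | None = None) -> dict[str, Path]:
    synth = synthetic or SyntheticConfig(seed=config.seed)
    fixture = simulate_study(synth)
    return write_fixture(fixture, fixture_dir)


def load_inputs(config: PipelineConfig):
    transcripts = dio.read_gtf(_require(config.gtf, "simulate"))
    sample_table = dio.read_sample_table(_require(config.samples, "simulate"))
    counts = dio.read_counts(_require(config.counts, "simulate"), sample_table)
    known = dio.read_id_list(_require(config.known_ids, "simulate"))
    return transcripts, sample_table, counts, known


def run_identify(config: PipelineConfig) -> identify.LncRNASet:
    """Filter, classify and consensus-call lncRNA candidates; writes
    lncrna_calls.tsv and filter_flags.tsv."""
    transcripts, sample_table, counts, known = load_inputs(config)
    sequences = dio.read_fasta(_require(config.fasta, "simulate"))

    flt = identify.filter_candidates(
        transcripts, counts, known,
        min_length=config.min_length, min_exons=config.min_exons,
        min_reads=config.min_reads, read_mode=config.read_mode,
    )
    survivors = [f.transcript for f in flt if f.passed]
    lnc_set = identify.classify_by_class_code(survivors)
    cand_seqs = {t.transcript_id: sequences[t.transcript_id] for t in survivors}
    labels = identify.score_coding_potential(
        cand_seqs, orf_min_codons=config.orf_min_codons
    )
    lnc_set = identify.consensus_noncoding(lnc_set, [labels])

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flags = pd.DataFrame(
        [
            {"transcript_id": f.transcript.transcript_id, **f.flags, "passed": f.passed}
            for f in flt
        ]
    ).set_index("transcript_id")
    _write_tsv(flags, out / "filter_flags.tsv", config)
    _write_tsv(lnc_set.to_frame(), out / "lncrna_calls.tsv", config)
    return lnc_set


def run_specificity(config: PipelineConfig) -> pd.DataFrame:
    """FPKM, per-transcript JS specificity and the lncRNA/mRNA comparison."""
    transcripts, sample_table, counts, known = load_inputs(config)
    tmap = transcripts_by_id(transcripts)
    lengths = {t.transcript_id: t.length for t in transcripts}
    fpkm = expression.compute_fpkm(counts, lengths)
    scores = expression.js_specificity(fpkm, sample_table)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(expression.specificity_frame(scores), out / "specificity.tsv", config)

    calls_path = out / "lncrna_calls.tsv"
    if calls_path.exists():
        calls = read_result_tsv(calls_path)
        lnc_ids = list(calls.loc[calls["consensus_noncoding"] == True, "transcript_id"])
        mrna_ids = [t.transcript_id for t in transcripts if t.class_code == "="]
        if len(lnc_ids) >= 2 and len(mrna_ids) >= 2:
            report = expression.compare_lnc_mrna(lnc_ids, mrna_ids, tmap, fpkm, scores)
            _write_tsv(report, out / "lnc_mrna_comparison.tsv", config)
    return expression.specificity_frame(scores)


def run_de(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """One DE table per genotype-vs-matched-WT contrast."""
    transcripts, sample_table, counts, known = load_inputs(config)
    factors = diffexpr.size_factors(counts)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    for contrast in diffexpr.contrasts_from_sample_table(sample_table):
        results = diffexpr.run_contrast(counts, contrast, factors)
        df = diffexpr.de_frame(results, config.lfc_min, config.q_max)
        _write_tsv(df, out / f"de_{contrast.name}.tsv", config)
        tables[contrast.name] = df
    summary = pd.DataFrame(
        {
            "contrast": list(tables),
            "n_significant": [int(t["significant"].sum()) for t in tables.values()],
        }
    ).set_index("contrast")
    _write_tsv(summary, out / "de_summary.tsv", config)
    return tables


def _significant_lncrnas(config: PipelineConfig, out: Path) -> set[str]:
    calls_path = _require(out / "lncrna_calls.tsv", "identify")
    calls = read_result_tsv(calls_path)
    lnc_ids = set(calls.loc[calls["consensus_noncoding"] == True, "transcript_id"])
    de_paths = sorted(out.glob("de_*_vs_*.tsv"))
    if not de_paths:
        raise InputError(f"no DE tables under {out}; run `de` first")
    sig: set[str] = set()
    for p in de_paths:
        df = read_result_tsv(p)
        sig |= set(df.loc[df["significant"] == True, "transcript_id"])
    return sig & lnc_ids


def run_targets(config: PipelineConfig) -> pd.DataFrame:
    """Cis and trans edges for the DE lncRNAs; writes targets.tsv and the
    multi-regulator summary."""
    transcripts, sample_table, counts, known = load_inputs(config)
    tmap = transcripts_by_id(transcripts)
    out = Path(config.out_dir)
    de_lnc = _significant_lncrnas(config, out)

    coding = [t for t in transcripts if t.class_code == "="]
    lnc_transcripts = [tmap[i] for i in sorted(de_lnc)]
    cis = targets.cis_targets(lnc_transcripts, coding, window_bp=config.cis_window)

    lengths = {t.transcript_id: t.length for t in transcripts}
    fpkm = expression.compute_fpkm(counts, lengths)
    gene_map = {t.transcript_id: t.gene_id for t in coding}
    # correlation on log2(FPKM+1): co-expression is multiplicative
    trans = targets.trans_targets(
        sorted(de_lnc), gene_map, expression.log2_expression(fpkm),
        r_threshold=config.trans_r,
    )

    edges = cis + trans
    df = targets.edges_frame(edges)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, out / "targets.tsv", config, index=False)
    _write_tsv(
        targets.multi_regulator_summary(edges), out / "multi_regulators.tsv",
        config, index=False,
    )
    return df


def run_enrich(config: PipelineConfig) -> pd.DataFrame:
    """Hypergeometric enrichment of the predicted target-gene set."""
    out = Path(config.out_dir)
    edges = read_result_tsv(_require(out / "targets.tsv", "targets"))
    annotation = dio.read_term_annotation(_require(config.terms, "simulate"))
    transcripts = dio.read_gtf(_require(config.gtf, "simulate"))
    study_genes = {t.gene_id for t in transcripts if t.class_code == "="}
    universe = sorted(
        study_genes & {g for term in annotation for g in term.gene_ids}
    )
    query = sorted(set(edges["gene_id"]) & set(universe))
    if not query:
        raise ValidationError("no target genes fall inside the annotation universe")
    results = enrichment.enrich_terms(query, annotation, universe, config.enrich_p)
    df = enrichment.enrichment_frame(results, config.enrich_p)
    _write_tsv(df, out / "enrichment.tsv", config)
    return df


def run_all(config: PipelineConfig) -> dict:
    """Full pipeline; returns and writes the per-stage summary."""
    lnc_set = run_identify(config)
    run_specificity(config)
    de_tables = run_de(config)
    edges = run_targets(config)
    enr = run_enrich(config)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_candidates": len(lnc_set),
        "lncrna_class_counts": lnc_set.class_counts(),
        "predictor_tally": identify.predictor_tally(lnc_set),
        "n_consensus_lncrna": len(lnc_set.consensus_ids()),
        "de_per_contrast": {
            name: int(t["significant"].sum()) for name, t in de_tables.items()
        },
        "n_cis_edges": int((edges["mode"] == "cis").sum()),
        "n_trans_edges": int((edges["mode"] == "trans").sum()),
        "n_enriched_terms": int(enr["enriched"].sum()),
    }
    out = Path(config.out_dir)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
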