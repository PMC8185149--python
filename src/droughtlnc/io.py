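"""Readers and writers for the formats the pipeline touches.

GTF (StringTie dialect, 1-based inclusive), FASTA, TSV count matrix, TSV
sample table, plain-text known-RNA ID lists, and TSV/GMT term annotations.
All tabular outputs use a fixed column order so downstream diffs are stable.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    ExpressionMatrix,
    Sample,
    SampleTable,
    TermAnnotation,
    Transcript,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path) -> list[Transcript]:
    """Parse a StringTie-style GTF into Transcript records.

    The ``class_code`` attribute is taken from the ``transcript`` feature
    line when present, else "." .  Exon lines are grouped by transcript_id;
    a transcript with no exon lines is a validation error.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(
                    f"{path}:{lineno}: malformed GTF line (expected 9 fields)"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted errors
                raise ParseError(f"{path}:{lineno}: malformed GTF line ({exc})")
            if feat.featuretype not in {"transcript", "exon"}:
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError):
                raise ParseError(
                    f"{path}:{lineno}: {feat.featuretype} line lacks transcript_id"
                )
            gid = feat.attributes.get("gene_id", [tid])[0]
            if tid not in meta:
                order.append(tid)
                meta[tid] = {
                    "gene_id": gid,
                    "chrom": feat.seqid,
                    "strand": feat.strand or ".",
                    "class_code": ".",
                }
            if feat.featuretype == "transcript":
                code = feat.attributes.get("class_code", ["."])[0]
                meta[tid]["class_code"] = code or "."
            else:
                exons.setdefault(tid, []).append((feat.start, feat.end))

    out: list[Transcript] = []
    for tid in order:
        m = meta[tid]
        if tid not in exons:
            raise ValidationError(f"{path}: transcript {tid} has zero exons")
        ex = tuple(sorted(exons[tid]))
        out.append(
            Transcript(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                start=ex[0][0],
                end=ex[-1][1],
                strand=m["strand"],
                exons=ex,
                class_code=m["class_code"],
            )
        )
    return out


def write_gtf(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts as StringTie-style GTF (transcript + exon lines)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'class_code "{t.class_code}";'
            )
            fh.write(
                f"{t.chrom}\tdroughtlnc\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tdroughtlnc\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Count matrix and sample table

def read_counts(path: str | Path, sample_table: SampleTable) -> ExpressionMatrix:
    """Read a transcripts x samples integer count TSV.

    Header samples must all appear in the sample table; columns are
    reordered to the sample-table order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in sample_table]
    if unknown:
        raise ValidationError(
            f"{path}: samples not in sample table: {', '.join(unknown)}"
        )
    missing = [s for s in sample_table.sample_ids if s not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: sample table samples absent from counts: {', '.join(missing)}"
        )
    df = df[sample_table.sample_ids]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValidationError(f"{path}: non-numeric count values")
    if (numeric < 0).any().any():
        raise ValidationError(f"{path}: negative count values")
    if not (numeric == numeric.round()).all().all():
        raise ValidationError(f"{path}: non-integer count values")
    return ExpressionMatrix(numeric, unit="counts")


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="transcript_id")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a sample table TSV with columns sample_id, code, replicate.

    Genotype/treatment/tissue are derived from the condition code, so extra
    columns carrying them are accepted but ignored.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "code", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: sample table needs columns {sorted(required)}"
        )
    return SampleTable(
        Sample(str(r.sample_id), str(r.code), int(r.replicate))
        for r in df.itertuples()
    )


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ID lists and term annotation

def read_id_list(path: str | Path) -> set[str]:
    """Plain text file, one transcript/gene ID per line; '#' comments allowed."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


def read_term_annotation(path: str | Path) -> list[TermAnnotation]:
    """Read a gene -> term annotation from two-column TSV or GMT.

    TSV rows are (gene_id, term_id[, term_name]); GMT lines are
    term_id <tab> description <tab> gene1 <tab> gene2 ...  The format is
    sniffed from the extension (.gmt) or the column count.  Duplicate
    (gene, term) pairs are de-duplicated; zero-gene terms are skipped with
    a warning.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            n_lines += 1
            if path.suffix.lower() == ".gmt" or len(fields) > 3:
                term, desc, genes = fields[0], fields[1], fields[2:]
                genes = [g for g in genes if g]
                if not genes:
                    warnings.warn(f"{path}:{lineno}: zero-gene term {term}, skipped")
                    continue
                terms.setdefault(term, set()).update(genes)
                names.setdefault(term, desc)
            else:
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected gene<TAB>term, got {line!r}"
                    )
                gene, term = fields[0], fields[1]
                name = fields[2] if len(fields) > 2 else term
                terms.setdefault(term, set()).add(gene)
                names.setdefault(term, name)
    if n_lines == 0:
        raise ValidationError(f"{path}: empty term annotation")
    return [
        TermAnnotation(term_id=t, term_name=names[t], gene_ids=frozenset(g))
        for t, g in terms.items()
    ]


def write_term_annotation(terms: Iterable[TermAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            for g in sorted(t.gene_ids):
                fh.write(f"{g}\t{t.term_id}\t{t.term_name}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
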