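"""Shared domain types for the drought-stress lncRNA pipeline.

Coordinates are 1-based and inclusive throughout the package, the GTF
convention; any half-open representation is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 20 condition codes of the study design: five Arabidopsis genotypes
#: (AtLEA over-expression, AtVOC over-expression, AtLEA mutant, AtVOC RNAi,
#: wild type) under long-term or short-term drought, sampled in leaves or
#: siliques.  Code -> (genotype, treatment, tissue).
CONDITION_CODES: dict[str, tuple[str, str, str]] = {
    "AtLEALL": ("LEA-OE", "long-term", "leaves"),
    "AtVOCLL": ("VOC-OE", "long-term", "leaves"),
    "mLEALL": ("mLEA", "long-term", "leaves"),
    "AtVOCRNAiLL": ("VOC-RNAi", "long-term", "leaves"),
    "WTLL": ("WT", "long-term", "leaves"),
    "AtLEALS": ("LEA-OE", "short-term", "leaves"),
    "AtVOCLS": ("VOC-OE", "short-term", "leaves"),
    "mLEALS": ("mLEA", "short-term", "leaves"),
    "AtVOCRNAiLS": ("VOC-RNAi", "short-term", "leaves"),
    "WTLS": ("WT", "short-term", "leaves"),
    "AtLEASL": ("LEA-OE", "long-term", "silique"),
    "AtVOCSL": ("VOC-OE", "long-term", "silique"),
    "mLEASL": ("mLEA", "long-term", "silique"),
    "AtVOCRNAiSL": ("VOC-RNAi", "long-term", "silique"),
    "WTSL": ("WT", "long-term", "silique"),
    "AtLEASS": ("LEA-OE", "short-term", "silique"),
    "AtVOCSS": ("VOC-OE", "short-term", "silique"),
    "mLEASS": ("mLEA", "short-term", "silique"),
    "AtVOCRNAiSS": ("VOC-RNAi", "short-term", "silique"),
    "WTSS": ("WT", "short-term", "silique"),
}

#: The matched wild-type control code for each non-WT condition code
#: (same treatment duration and tissue).
WT_CONTROL: dict[str, str] = {
    code: next(
        wt
        for wt, (g, t, s) in CONDITION_CODES.items()
        if g == "WT" and (t, s) == (trt, tis)
    )
    for code, (geno, trt, tis) in CONDITION_CODES.items()
    if geno != "WT"
}


class ValidationError(ValueError):
    """Input violates a documented contract."""


@dataclass(frozen=True)
class Transcript:
    """One assembled transcript model.

    ``class_code`` follows the StringTie/gffcompare dialect: "=" matches a
    reference transcript, "u" is intergenic, "i" fully intronic, "x" exonic
    overlap on the opposite strand, "j" a novel isoform, "." unknown.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    class_code: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has zero exons")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(
                f"{self.transcript_id}: bad strand {self.strand!r}"
            )
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s},{e}) has start > end"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def length(self) -> int:
        """Spliced length in bp (1-based inclusive exon spans)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class Sample:
    """One RNA-seq sample: a condition code plus a replicate index."""

    sample_id: str
    code: str
    replicate: int

    def __post_init__(self) -> None:
        if self.code not in CONDITION_CODES:
            raise ValidationError(
                f"{self.sample_id}: unknown condition code {self.code!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")

    @property
    def genotype(self) -> str:
        return CONDITION_CODES[self.code][0]

    @property
    def treatment(self) -> str:
        return CONDITION_CODES[self.code][1]

    @property
    def tissue(self) -> str:
        return CONDITION_CODES[self.code][2]


class SampleTable:
    """Ordered collection of samples with code -> samples lookup."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples: list[Sample] = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample IDs in sample table")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_for_code(self, code: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.code == code]

    def codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.code, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "code": [s.code for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


class ExpressionMatrix:
    """Dense transcripts x samples expression grid.

    ``unit`` is "counts" (non-negative integers) or "FPKM" (non-negative
    reals).  Backed by a pandas DataFrame with transcript IDs as the index
    and sample IDs as columns.
    """

    def __init__(self, data: pd.DataFrame, unit: str):
        if unit not in {"counts", "FPKM"}:
            raise ValidationError(f"unknown unit {unit!r}")
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValidationError("duplicate row or column labels")
        values = data.to_numpy()
        if np.any(values < 0):
            raise ValidationError(f"negative values in {unit} matrix")
        if unit == "counts" and not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers")
        self.data = data.astype(np.int64 if unit == "counts" else np.float64)
        self.unit = unit

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise ValidationError(
                f"features absent from matrix: {', '.join(missing[:10])}"
            )
        return ExpressionMatrix(self.data.loc[list(ids)], self.unit)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.columns]
        if missing:
            raise ValidationError(
                f"samples absent from matrix: {', '.join(missing[:10])}"
            )
        return ExpressionMatrix(self.data[list(ids)], self.unit)


@dataclass
class TermAnnotation:
    """One functional term (GO/KEGG-style) and its annotated gene set."""

    term_id: str
    term_name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"{self.term_id}: empty gene set")


def transcripts_by_id(transcripts: Iterable[Transcript]) -> dict[str, Transcript]:
    out: dict[str, Transcript] = {}
    for t in transcripts:
        if t.transcript_id in out:
            raise ValidationError(f"duplicate transcript ID {t.transcript_id}")
        out[t.transcript_id] = t
    return out
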