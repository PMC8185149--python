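"""Cis and trans target-gene prediction for differentially expressed lncRNAs.

Cis: a protein-coding gene whose genomic span lies within 50 kb (gap
between spans, overlap counts as 0, boundary inclusive) of the lncRNA on
the same chromosome, strand-agnostic.  Trans: a gene whose expression
across all samples correlates with the lncRNA at |Pearson r| >= 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, Transcript, ValidationError


@dataclass(frozen=True)
class TargetEdge:
    lncrna_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    evidence: float  # distance bp (cis) or Pearson r (trans)


def span_gap(a: Transcript, b: Transcript) -> int | None:
    """Gap in bp between two transcript spans on the same chromosome;
    0 for overlap, None for different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def cis_targets(
    de_lncrnas: Sequence[Transcript],
    coding_genes: Sequence[Transcript],
    window_bp: int = 50_000,
) -> list[TargetEdge]:
    """All (lncRNA, gene) pairs with span gap <= window_bp, reporting the
    gap as evidence.  Warns when a lncRNA's chromosome carries no genes."""
    by_chrom: dict[str, list[Transcript]] = {}
    for g in coding_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    edges: list[TargetEdge] = []
    for lnc in de_lncrnas:
        genes = by_chrom.get(lnc.chrom)
        if genes is None:
            warnings.warn(
                f"{lnc.transcript_id}: chromosome {lnc.chrom} has no coding genes"
            )
            continue
        for g in genes:
            gap = span_gap(lnc, g)
            if gap is not None and gap <= window_bp:
                edges.append(TargetEdge(lnc.transcript_id, g.gene_id, "cis", float(gap)))
    return edges


def trans_targets(
    de_lncrna_ids: Sequence[str],
    gene_map: Mapping[str, str],
    fpkm: ExpressionMatrix,
    r_threshold: float = 0.9,
    samples: Sequence[str] | None = None,
) -> list[TargetEdge]:
    """Pairs with |Pearson r| >= r_threshold over all samples (or the
    given subset).  ``gene_map`` maps candidate transcript IDs to their
    gene IDs (the protein-coding search space).  Constant-expression
    partners are excluded with a warning: their correlation is undefined.
    """
    data = fpkm.data if samples is None else fpkm.data[list(samples)]
    if data.shape[1] < 3:
        raise ValidationError("need >= 3 samples for correlation")
    lnc_ids = [l for l in de_lncrna_ids]
    missing = [l for l in lnc_ids if l not in data.index]
    missing += [t for t in gene_map if t not in data.index]
    if missing:
        raise ValidationError(
            "transcripts absent from expression matrix: " + ", ".join(missing[:10])
        )
    gene_tids = list(gene_map)
    lnc = data.loc[lnc_ids].to_numpy(dtype=float)
    gen = data.loc[gene_tids].to_numpy(dtype=float)

    lnc_sd = lnc.std(axis=1)
    gen_sd = gen.std(axis=1)
    for ids, sd in ((lnc_ids, lnc_sd), (gene_tids, gen_sd)):
        for i, s in zip(ids, sd):
            if s == 0:
                warnings.warn(f"{i}: constant expression, correlation undefined")

    lz = (lnc - lnc.mean(axis=1, keepdims=True))
    gz = (gen - gen.mean(axis=1, keepdims=True))
    n = data.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (lz @ gz.T) / (n * np.outer(lnc_sd, gen_sd))
    r[~np.isfinite(r)] = 0.0

    edges: list[TargetEdge] = []
    for i, lid in enumerate(lnc_ids):
        for j, tid in enumerate(gene_tids):
            if tid == lid:
                continue
            if abs(r[i, j]) >= r_threshold:
                edges.append(TargetEdge(lid, gene_map[tid], "trans", float(r[i, j])))
    return edges


def multi_regulator_summary(edges: Sequence[TargetEdge]) -> pd.DataFrame:
    """Genes ranked by how many lncRNAs target them; one row per
    (gene, mode) with the regulator IDs listed."""
    rows: dict[tuple[str, str], list[str]] = {}
    for e in edges:
        rows.setdefault((e.gene_id, e.mode), []).append(e.lncrna_id)
    df = pd.DataFrame(
        {
            "gene_id": [k[0] for k in rows],
            "mode": [k[1] for k in rows],
            "n_regulators": [len(v) for v in rows.values()],
            "lncrna_ids": [",".join(sorted(v)) for v in rows.values()],
        }
    )
    return df.sort_values(
        ["n_regulators", "gene_id", "mode"], ascending=[False, True, True]
    ).reset_index(drop=True)


def edges_frame(edges: Sequence[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [e.lncrna_id for e in edges],
            "gene_id": [e.gene_id for e in edges],
            "mode": [e.mode for e in edges],
            "evidence": [e.evidence for e in edges],
        }
    )
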