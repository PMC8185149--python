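"""Expression-level statistics: FPKM, Jensen-Shannon condition
specificity, and the lncRNA-vs-mRNA feature comparison.

The specificity score for transcript expression profile p against
condition i is ``1 - sqrt(JSD(p, e_i))`` where e_i is the indicator
distribution of condition i and JSD is the Jensen-Shannon divergence in
bits (log base 2, 0*log0 = 0).  A transcript expressed in exactly one
condition scores 1 there; the maximum over conditions is reported as the
transcript's tissue/condition specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, SampleTable, Transcript, ValidationError


def compute_fpkm(
    counts: ExpressionMatrix, lengths: Mapping[str, int]
) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (library_size * length); library size is the
    per-sample column sum of the count matrix."""
    if counts.unit != "counts":
        raise ValidationError("compute_fpkm expects a counts matrix")
    missing = [t for t in counts.feature_ids if t not in lengths]
    if missing:
        raise ValidationError(
            "transcripts without a length: " + ", ".join(missing[:10])
        )
    length = np.array([lengths[t] for t in counts.feature_ids], dtype=float)
    if np.any(length <= 0):
        raise ValidationError("zero or negative transcript length")
    lib = counts.data.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValidationError("zero library size in at least one sample")
    fpkm = counts.values * 1e9 / (lib[None, :] * length[:, None])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.feature_ids, columns=counts.sample_ids),
        unit="FPKM",
    )


def log2_expression(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount), the standard transform for co-expression
    correlation: multiplicative regulation becomes linear and zeros stay
    finite."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(expr.data + pseudocount), unit=expr.unit)


# ---------------------------------------------------------------------------
# Jensen-Shannon specificity


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits between two distributions,
    bounded in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("distributions must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("negative probabilities")
    p = p / p.sum()
    q = q / q.sum()
    m = (p + q) / 2.0
    return _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(q)) / 2.0


def js_specificity_score(profile: np.ndarray, condition_index: int) -> float:
    """1 - sqrt(JSD(profile, indicator of condition_index))."""
    e = np.zeros_like(np.asarray(profile, dtype=float))
    e[condition_index] = 1.0
    jsd = js_divergence(profile, e)
    return 1.0 - float(np.sqrt(max(jsd, 0.0)))


@dataclass
class SpecificityScore:
    transcript_id: str
    scores: dict[str, float]  # condition code -> score
    max_js: float
    argmax_condition: str


def condition_means(
    expr: ExpressionMatrix, sample_table: SampleTable, aggregate: str = "mean"
) -> pd.DataFrame:
    """Average replicates per condition code (mean by default, median as
    the alternative aggregate)."""
    if aggregate not in {"mean", "median"}:
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    cols = {}
    for code in sample_table.codes():
        sub = expr.data[sample_table.samples_for_code(code)]
        cols[code] = sub.mean(axis=1) if aggregate == "mean" else sub.median(axis=1)
    return pd.DataFrame(cols)


def js_specificity(
    expr: ExpressionMatrix,
    sample_table: SampleTable,
    aggregate: str = "mean",
    collapse_to_tissue: bool = False,
) -> list[SpecificityScore]:
    """Per-transcript JS specificity over condition codes (or over the two
    tissues with ``collapse_to_tissue``).  All-zero transcripts get no
    score and are omitted."""
    means = condition_means(expr, sample_table, aggregate)
    if collapse_to_tissue:
        tissue_of = {
            code: sample_table[sample_table.samples_for_code(code)[0]].tissue
            for code in means.columns
        }
        means = means.T.groupby(tissue_of.get).mean().T
    conditions = list(means.columns)
    out: list[SpecificityScore] = []
    values = means.to_numpy(dtype=float)
    for row_idx, tid in enumerate(means.index):
        profile = values[row_idx]
        total = profile.sum()
        if total <= 0:
            continue
        p = profile / total
        scores = {
            cond: js_specificity_score(p, i) for i, cond in enumerate(conditions)
        }
        best = max(scores, key=scores.get)
        out.append(SpecificityScore(tid, scores, scores[best], best))
    return out


def specificity_frame(scores: Sequence[SpecificityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in scores],
            "max_js": [s.max_js for s in scores],
            "argmax_condition": [s.argmax_condition for s in scores],
        }
    ).set_index("transcript_id")


# ---------------------------------------------------------------------------
# lncRNA vs mRNA comparison


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value: exact when both groups have
    <= 20 observations and no ties, tie-corrected normal approximation
    otherwise."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 observations")
    exact = (
        len(x) <= 20
        and len(y) <= 20
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_lnc_mrna(
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
    transcripts: Mapping[str, Transcript],
    fpkm: ExpressionMatrix,
    specificity: Sequence[SpecificityScore] | None = None,
) -> pd.DataFrame:
    """Group summaries (exon count, length, mean FPKM, max JS) plus the
    Wilcoxon rank-sum p-value for the FPKM difference.  Returns a tidy
    two-row frame indexed by group."""
    if len(lnc_ids) < 2 or len(mrna_ids) < 2:
        raise ValidationError("each group needs >= 2 transcripts")
    spec_map = {s.transcript_id: s.max_js for s in specificity or []}

    def summarise(ids: Sequence[str]) -> dict:
        exp = fpkm.data.loc[list(ids)].mean(axis=1)
        return {
            "n": len(ids),
            "median_exons": float(np.median([transcripts[i].n_exons for i in ids])),
            "median_length": float(np.median([transcripts[i].length for i in ids])),
            "median_fpkm": float(exp.median()),
            "mean_fpkm": float(exp.mean()),
            "median_max_js": (
                float(np.median([spec_map[i] for i in ids if i in spec_map]))
                if spec_map
                else np.nan
            ),
        }

    lnc_expr = fpkm.data.loc[list(lnc_ids)].mean(axis=1)
    mrna_expr = fpkm.data.loc[list(mrna_ids)].mean(axis=1)
    p = wilcoxon_rank_sum(lnc_expr, mrna_expr)
    df = pd.DataFrame(
        [summarise(lnc_ids), summarise(mrna_ids)], index=["lncRNA", "mRNA"]
    )
    df["wilcoxon_p_fpkm"] = p
    return df
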