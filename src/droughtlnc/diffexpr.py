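"""Desk-scale negative-binomial differential expression.

The model follows the classic count-based DE recipe: median-of-ratios
size factors, a per-transcript NB mean-dispersion model (variance
mu + alpha*mu^2, method-of-moments dispersion, no trend shrinkage) and a
Wald test on the log2 fold change with a delta-method standard error,
referred to a t distribution with nT + nC - 2 degrees of freedom for
small-sample calibration.  Significance uses the study thresholds
|log2fc| >= 1 and q < 0.05 (Benjamini-Hochberg).

This is deliberately a self-contained re-implementation: planted-truth
recovery, not bit-compatibility with any external engine, is its contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    CONDITION_CODES,
    WT_CONTROL,
    ExpressionMatrix,
    SampleTable,
    ValidationError,
)

DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5  # normalised-count pseudovalue keeping log2fc finite


@dataclass(frozen=True)
class Contrast:
    """One genotype-vs-matched-WT comparison."""

    name: str
    treatment_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.treatment_samples) & set(self.control_samples):
            raise ValidationError(f"{self.name}: groups overlap")
        if len(self.treatment_samples) < 2 or len(self.control_samples) < 2:
            raise ValidationError(f"{self.name}: each group needs >= 2 samples")


def contrasts_from_sample_table(sample_table: SampleTable) -> list[Contrast]:
    """Each non-WT condition code against its matched wild-type code
    (same drought duration and tissue)."""
    out = []
    for code in sample_table.codes():
        if CONDITION_CODES[code][0] == "WT":
            continue
        wt = WT_CONTROL[code]
        t = sample_table.samples_for_code(code)
        c = sample_table.samples_for_code(wt)
        if len(t) >= 2 and len(c) >= 2:
            out.append(Contrast(f"{code}_vs_{wt}", tuple(t), tuple(c)))
    return out


# ---------------------------------------------------------------------------


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios normalisation: factor_j = median over genes of
    count_gj / geometric-mean_g, over genes with all-positive counts."""
    mat = counts.values.astype(float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.sample_ids)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no transcript has positive counts in every sample; filter first"
        )
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids)


@dataclass
class DEResult:
    transcript_id: str
    base_mean: float
    log2fc: float
    p: float
    q: float = np.nan
    all_zero: bool = False

    def significant(self, lfc_min: float = 1.0, q_max: float = 0.05) -> bool:
        return abs(self.log2fc) >= lfc_min and self.q < q_max


def nb_test(
    counts: ExpressionMatrix,
    contrast: Contrast,
    factors: pd.Series | None = None,
) -> list[DEResult]:
    """Per-transcript Wald test of the treatment/control log2 ratio.

    Normalised counts are counts / size factor.  The delta-method variance
    of log2(mean + pseudocount) uses the NB variance mu + alpha*mu^2 with
    a pooled method-of-moments alpha per transcript, floored at 1e-8.
    """
    if factors is None:
        factors = size_factors(counts)
    for s in contrast.treatment_samples + contrast.control_samples:
        if s not in counts.data.columns:
            raise ValidationError(f"{contrast.name}: sample {s} absent from counts")
    norm = counts.data / factors
    t_mat = norm[list(contrast.treatment_samples)].to_numpy(dtype=float)
    c_mat = norm[list(contrast.control_samples)].to_numpy(dtype=float)
    n_t, n_c = t_mat.shape[1], c_mat.shape[1]
    df = n_t + n_c - 2

    m_t = t_mat.mean(axis=1)
    m_c = c_mat.mean(axis=1)
    base_mean = (n_t * m_t + n_c * m_c) / (n_t + n_c)

    # method-of-moments dispersion pooled across groups: per-group
    # alpha_g = (var_g - mu_g) / mu_g^2, combined with df weights.
    # Pooling the dispersions (not the raw variances) keeps alpha
    # unbiased when the two group means differ by a large fold change.
    var_t = ((t_mat - m_t[:, None]) ** 2).sum(axis=1) / (n_t - 1)
    var_c = ((c_mat - m_c[:, None]) ** 2).sum(axis=1) / (n_c - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_t = np.where(m_t > 0, (var_t - m_t) / np.maximum(m_t, 1e-300) ** 2, 0.0)
        a_c = np.where(m_c > 0, (var_c - m_c) / np.maximum(m_c, 1e-300) ** 2, 0.0)
    w_t = np.where(m_t > 0, n_t - 1, 0)
    w_c = np.where(m_c > 0, n_c - 1, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            w_t + w_c > 0, (w_t * a_t + w_c * a_c) / np.maximum(w_t + w_c, 1), 0.0
        )
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    eps = LFC_PSEUDOCOUNT
    log2fc = np.log2((m_t + eps) / (m_c + eps))

    ln2 = np.log(2.0)
    var_mt = (m_t + alpha * m_t**2) / n_t
    var_mc = (m_c + alpha * m_c**2) / n_c
    se = np.sqrt(
        var_mt / ((m_t + eps) * ln2) ** 2 + var_mc / ((m_c + eps) * ln2) ** 2
    )

    all_zero = (m_t == 0) & (m_c == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    p = np.clip(p, 0.0, 1.0)
    p[all_zero] = 1.0
    log2fc[all_zero] = 0.0

    return [
        DEResult(
            transcript_id=tid,
            base_mean=float(base_mean[i]),
            log2fc=float(log2fc[i]),
            p=float(p[i]),
            all_zero=bool(all_zero[i]),
        )
        for i, tid in enumerate(counts.feature_ids)
    ]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, clipped at 1."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_results(results: list[DEResult]) -> list[DEResult]:
    q = bh_adjust([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def run_contrast(
    counts: ExpressionMatrix, contrast: Contrast, factors: pd.Series | None = None
) -> list[DEResult]:
    return adjust_results(nb_test(counts, contrast, factors))


def call_de(
    results: Sequence[DEResult], lfc_min: float = 1.0, q_max: float = 0.05
) -> set[str]:
    """Significant set at the study cut-off |log2fc| >= 1 and q < 0.05."""
    return {r.transcript_id for r in results if r.significant(lfc_min, q_max)}


def shared_de(set_a: set[str], set_b: set[str]) -> set[str]:
    """lncRNAs differentially expressed in both contrasts."""
    return set_a & set_b


def de_frame(results: Sequence[DEResult], lfc_min: float = 1.0, q_max: float = 0.05) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant(lfc_min, q_max) for r in results],
        }
    ).set_index("transcript_id")
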