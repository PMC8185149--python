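"""Hypergeometric over-representation of functional terms in a gene set.

For a query of n genes drawn from a universe of N genes of which K carry
the term and k are observed in the query, the enrichment p-value is the
upper tail P[X >= k] of the hypergeometric distribution (the observed k
included, the standard over-representation convention).  Adjustment
across tested terms is Benjamini-Hochberg; a term is enriched when
adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .model import TermAnnotation, ValidationError


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValidationError(
            f"impossible configuration k={k}, n={n}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p: float
    adjusted_p: float = float("nan")
    overlap_genes: tuple[str, ...] = ()

    def enriched(self, adjusted_p_max: float = 0.05) -> bool:
        return self.adjusted_p < adjusted_p_max


def enrich_terms(
    query_genes: Sequence[str],
    annotation: Sequence[TermAnnotation],
    universe: Sequence[str],
    adjusted_p_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term with BH adjustment.

    Term gene sets are intersected with the universe; the query must be a
    subset of the universe.  Terms with zero overlap are reported (p = 1
    region) but can never be enriched.
    """
    universe_set = set(universe)
    query_set = set(query_genes)
    if not query_set:
        raise ValidationError("empty query gene set")
    if not universe_set:
        raise ValidationError("empty universe")
    stray = query_set - universe_set
    if stray:
        raise ValidationError(
            "query genes outside the universe: " + ", ".join(sorted(stray)[:10])
        )
    N = len(universe_set)
    n = len(query_set)
    results: list[EnrichmentResult] = []
    for term in annotation:
        term_genes = term.gene_ids & universe_set
        if not term_genes:
            continue
        overlap = sorted(term_genes & query_set)
        k, K = len(overlap), len(term_genes)
        p = hypergeom_upper_tail(k, n, K, N)
        results.append(
            EnrichmentResult(
                term.term_id, term.term_name, k, n, K, N, p,
                overlap_genes=tuple(overlap),
            )
        )
    if results:
        q = bh_adjust([r.p for r in results])
        for r, qi in zip(results, q):
            r.adjusted_p = float(qi)
    return sorted(results, key=lambda r: (r.p, r.term_id))


def enrichment_frame(
    results: Sequence[EnrichmentResult], adjusted_p_max: float = 0.05
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "enriched": [r.enriched(adjusted_p_max) for r in results],
            "genes": [",".join(r.overlap_genes) for r in results],
        }
    ).set_index("term_id")
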