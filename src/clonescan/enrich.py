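"""Fisher exact pathway enrichment of a selected gene set against a background."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "pathway_enrichment", "benjamini_hochberg"]


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway: str
    k: int  # selected genes in the pathway
    K: int  # selected genes total
    n: int  # background genes in the pathway
    N: int  # background genes total
    p: float
    enriched: bool


def pathway_enrichment(
    selected: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
    alternative: str = "greater",
    correct: bool = False,
) -> list[EnrichmentRecord]:
    """Per-pathway Fisher exact test of over-representation.

    The 2x2 table is [[k, K-k], [n-k, (N-K)-(n-k)]] with k the selected
    genes in the pathway, K the selected total, n the background genes in
    the pathway and N the background total. One-sided (greater) by
    default; ``correct=True`` applies Benjamini–Hochberg before the alpha
    call. Annotated genes outside the background are dropped with a
    warning.
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    N, K = len(background), len(selected)
    records = []
    for pathway in sorted(annotations):
        members = annotations[pathway]
        outside = members - background
        if outside:
            logger.warning(
                "pathway %s: %d annotated genes outside the background dropped",
                pathway, len(outside),
            )
        members = members & background
        if not members:
            continue
        n = len(members)
        k = len(members & selected)
        table = [[k, K - k], [n - k, (N - K) - (n - k)]]
        p = float(fisher_exact(table, alternative=alternative)[1])
        records.append(EnrichmentRecord(pathway, k, K, n, N, p, False))
    if correct:
        adj = benjamini_hochberg([r.p for r in records])
    else:
        adj = [r.p for r in records]
    return [
        EnrichmentRecord(r.pathway, r.k, r.K, r.n, r.N, r.p, q < alpha)
        for r, q in zip(records, adj)
    ]


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (monotone step-up)."""
    m = len(pvalues)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adj[i] = running
    return adj
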