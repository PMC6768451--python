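"""Reciprocal-best-hit orthology between two transcript sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filter import KmerIndex, Scoring, local_align, search_best_hit

logger = logging.getLogger(__name__)

__all__ = ["OrthologPair", "best_hits", "reciprocal_best_hits", "position_map"]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    bitscore_ab: float
    bitscore_ba: float
    evalue_ab: float
    evalue_ba: float


def best_hits(
    set_a: dict[str, str],
    set_b: dict[str, str],
    evalue_cutoff: float = 1e-50,
    scoring: Scoring = Scoring(),
) -> dict[str, "AlignmentHit"]:
    """Best-subject hit per query at the e-value cutoff.

    The best hit maximises bitscore among hits with evalue <= cutoff;
    equal-bitscore ties go to the lexicographically smallest subject id.
    Queries with no qualifying hit are absent from the map.
    """
    index = KmerIndex(set_b, scoring.seed_k)
    hits = {}
    for name, seq in set_a.items():
        hit = search_best_hit(seq, index, scoring, query_id=name)
        if hit is not None and hit.evalue <= evalue_cutoff:
            hits[name] = hit
    return hits


def reciprocal_best_hits(map_ab: dict, map_ba: dict) -> list[OrthologPair]:
    """Pairs (a, b) with map_ab[a] = b and map_ba[b] = a."""
    pairs = []
    for a, hit_ab in map_ab.items():
        b = hit_ab.subject
        hit_ba = map_ba.get(b)
        if hit_ba is not None and hit_ba.subject == a:
            pairs.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=b,
                    bitscore_ab=hit_ab.bitscore,
                    bitscore_ba=hit_ba.bitscore,
                    evalue_ab=hit_ab.evalue,
                    evalue_ba=hit_ba.evalue,
                )
            )
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def position_map(seq_a: str, seq_b: str, scoring: Scoring = Scoring()) -> dict[int, int]:
    """Map 0-based positions of seq_b onto seq_a via the local alignment.

    Gap columns are unmappable and absent from the map; an unalignable pair
    yields an empty map.
    """
    hit = local_align(seq_a, seq_b, scoring, with_coordinates=True)
    if hit is None:
        return {}
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    mapping: dict[int, int] = {}
    for (a0, a1), (b0, b1) in zip(np.asarray(blocks_a), np.asarray(blocks_b)):
        for off in range(a1 - a0):
            mapping[b0 + off] = a0 + off
    return mapping
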