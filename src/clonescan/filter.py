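"""Contaminant and rRNA contig filtering with a seeded local aligner.

The aligner pairs an exact k-mer seeding prefilter with optimal local
(Smith–Waterman) dynamic programming, and converts raw scores to bits and
e-values through Karlin–Altschul surrogates:

    bitscore = (lambda * score - ln K) / ln 2
    evalue   = m * n * 2 ** (-bitscore)

Filtering applies the two-database best-hit rule: keep a contig only if
its best reference-database bitscore either has no contaminant competitor
or beats it by at least the configured margin (default 100 bits); rRNA
contigs are removed on any hit at or below the e-value cutoff.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

from Bio import Align

logger = logging.getLogger(__name__)

__all__ = [
    "Scoring",
    "AlignmentHit",
    "FilterDecision",
    "local_align",
    "search_best_hit",
    "contaminant_filter",
    "rrna_filter",
]


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring with Karlin–Altschul surrogates."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    k: float = 0.41
    seed_k: int = 11
    min_raw_score: int = 22
    max_candidates: int = 4
    min_shared_kmers: int = 8

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def bitscore(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2.0)

    def evalue(self, raw: float, query_len: int, db_len: int) -> float:
        return query_len * db_len * 2.0 ** (-self.bitscore(raw))


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    score: int
    bitscore: float
    evalue: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int


@dataclass(frozen=True)
class FilterDecision:
    contig: str
    kept: bool
    reason: str  # ref-only-hit | margin-pass | margin-fail | contaminant-only-hit | no-hit | rrna
    best_ref_bits: float = math.nan
    best_contam_bits: float = math.nan


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = -scoring.gap_open
    a.extend_gap_score = -scoring.gap_extend
    return a


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def local_align(
    query: str,
    subject: str,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    subject_id: str = "subject",
    db_len: int | None = None,
    with_coordinates: bool = True,
) -> AlignmentHit | None:
    """Best local alignment between two sequences, or None below threshold.

    Pairs sharing no exact ``seed_k``-mer are rejected without dynamic
    programming, as are alignments scoring below ``min_raw_score``.
    """
    query, subject = query.upper(), subject.upper()
    if not query or not subject:
        return None
    if not (_kmers(query, scoring.seed_k) & _kmers(subject, scoring.seed_k)):
        return None
    aligner = _aligner(scoring)
    score = int(aligner.score(query, subject))
    if score < scoring.min_raw_score:
        return None
    qs = qe = ss = se = 0
    if with_coordinates:
        aln = aligner.align(query, subject)[0]
        qblocks, sblocks = aln.aligned
        qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
        ss, se = int(sblocks[0][0]), int(sblocks[-1][1])
    n = db_len if db_len is not None else len(subject)
    return AlignmentHit(
        query=query_id,
        subject=subject_id,
        score=score,
        bitscore=scoring.bitscore(score),
        evalue=scoring.evalue(score, len(query), n),
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
    )


class KmerIndex:
    """Exact k-mer index over a sequence database for candidate screening."""

    def __init__(self, db: dict[str, str], k: int):
        self.k = k
        self.db = db
        self.total_len = sum(len(s) for s in db.values())
        self._index: dict[str, set[str]] = defaultdict(set)
        for name, seq in db.items():
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].add(name)

    def candidates(self, query: str) -> list[tuple[str, int]]:
        """Subjects sharing >= 1 k-mer, by descending shared-kmer count."""
        counts: dict[str, int] = defaultdict(int)
        for kmer in _kmers(query.upper(), self.k):
            for name in self._index.get(kmer, ()):
                counts[name] += 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def search_best_hit(
    query: str,
    db: dict[str, str] | KmerIndex,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    with_coordinates: bool = False,
) -> AlignmentHit | None:
    """Best hit of a query against a database; ties broken by subject id."""
    index = db if isinstance(db, KmerIndex) else KmerIndex(db, scoring.seed_k)
    best: AlignmentHit | None = None
    candidates = [
        (name, c) for name, c in index.candidates(query) if c >= scoring.min_shared_kmers
    ]
    for subject_id, _ in candidates[: scoring.max_candidates]:
        hit = local_align(
            query,
            index.db[subject_id],
            scoring,
            query_id=query_id,
            subject_id=subject_id,
            db_len=index.total_len,
            with_coordinates=with_coordinates,
        )
        if hit is None:
            continue
        if best is None or hit.score > best.score or (
            hit.score == best.score and hit.subject < best.subject
        ):
            best = hit
    return best


def contaminant_filter(
    contigs: dict[str, str],
    reference_db: dict[str, str],
    contaminant_db: dict[str, str],
    margin: float = 100.0,
    scoring: Scoring = Scoring(),
    search_fn=None,
) -> list[FilterDecision]:
    """Two-database best-hit filtering of contigs.

    Keep a contig iff it has a reference-database hit AND either no
    contaminant hit (reason ``ref-only-hit``) or a reference bitscore
    exceeding the contaminant bitscore by at least ``margin`` bits
    (``margin-pass``). Contigs hitting only the contaminant database or
    nothing are discarded.
    """
    if not reference_db or not contaminant_db:
        raise ValueError("both databases must be non-empty")
    if search_fn is None:
        ref_index = KmerIndex(reference_db, scoring.seed_k)
        contam_index = KmerIndex(contaminant_db, scoring.seed_k)

        def search_fn(name, seq, which):  # noqa: F811
            index = ref_index if which == "ref" else contam_index
            return search_best_hit(seq, index, scoring, query_id=name)

    decisions = []
    for name, seq in contigs.items():
        ref_hit = search_fn(name, seq, "ref")
        contam_hit = search_fn(name, seq, "contam")
        ref_bits = ref_hit.bitscore if ref_hit else math.nan
        contam_bits = contam_hit.bitscore if contam_hit else math.nan
        if ref_hit is None:
            reason = "contaminant-only-hit" if contam_hit else "no-hit"
            kept = False
        elif contam_hit is None:
            kept, reason = True, "ref-only-hit"
        elif ref_bits - contam_bits >= margin:
            kept, reason = True, "margin-pass"
        else:
            kept, reason = False, "margin-fail"
        decisions.append(FilterDecision(name, kept, reason, ref_bits, contam_bits))
    return decisions


def rrna_filter(
    contigs: dict[str, str],
    rrna_db: dict[str, str],
    evalue_cutoff: float = 1e-10,
    scoring: Scoring = Scoring(),
    search_fn=None,
) -> list[FilterDecision]:
    """Remove contigs with any rRNA-database hit at e-value <= cutoff."""
    if not rrna_db:
        raise ValueError("rRNA database must be non-empty")
    if search_fn is None:
        index = KmerIndex(rrna_db, scoring.seed_k)

        def search_fn(name, seq):  # noqa: F811
            return search_best_hit(seq, index, scoring, query_id=name)

    decisions = []
    for name, seq in contigs.items():
        hit = search_fn(name, seq)
        if hit is not None and hit.evalue <= evalue_cutoff:
            decisions.append(FilterDecision(name, False, "rrna"))
        else:
            decisions.append(FilterDecision(name, True, "no-hit"))
    return decisions
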