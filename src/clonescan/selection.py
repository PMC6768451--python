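"""ORF finding, NG86 Ka/Ks estimation, selection classification and dating.

The Ka/Ks machinery follows the Nei–Gojobori (1986) counting scheme:
fractional synonymous/nonsynonymous site counts per codon, pathway
averaging for multi-hit codons, Jukes–Cantor distance correction, and a
per-gene two-sided Fisher exact test on the rounded substitution table.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

from scipy.stats import fisher_exact

from ._genetics import BASES, CODON_TO_AA, is_stop, translate_codon

logger = logging.getLogger(__name__)

__all__ = [
    "OrfRecord",
    "SiteCounts",
    "DiffCounts",
    "KaKsRecord",
    "find_orfs",
    "apply_fixed_variants",
    "ng86_site_counts",
    "ng86_difference_counts",
    "classify_single_change",
    "kaks_estimate",
    "classify_selection",
    "jukes_cantor",
    "p_distance",
    "divergence_time",
]


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on a transcript (0-based, half-open).

    The span includes the terminal stop codon when one terminates the run.
    """

    gene: str
    frame: int
    strand: str
    start: int
    end: int
    partial5: bool

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


def _scan_frame(gene: str, seq: str, frame: int, strand: str, allow_partial: bool) -> list[OrfRecord]:
    orfs: list[OrfRecord] = []
    n_codons = (len(seq) - frame) // 3
    start: int | None = frame if allow_partial else None
    partial5 = allow_partial
    for i in range(n_codons):
        pos = frame + 3 * i
        codon = seq[pos:pos + 3]
        if codon == "ATG" and (start is None or start == pos):
            start, partial5 = (start if start == pos else pos), False
        if is_stop(codon) and start is not None:
            orfs.append(OrfRecord(gene, frame, strand, start, pos + 3, partial5))
            start, partial5 = None, False
    if start is not None:
        end = frame + 3 * n_codons
        if end > start:
            orfs.append(OrfRecord(gene, frame, strand, start, end, partial5))
    return orfs


def find_orfs(
    transcript: str,
    gene: str = "",
    min_len_codons: int = 100,
    allow_partial: bool = True,
    six_frame: bool = False,
) -> list[OrfRecord]:
    """ORFs (longest first) over the three forward frames (six behind a flag).

    An ORF runs from an ATG — or from the frame start when ``allow_partial``
    — to the next stop codon (included) or the end of the transcript. Only
    ORFs of at least ``min_len_codons`` codons are reported.
    """
    seq = transcript.upper()
    orfs: list[OrfRecord] = []
    for frame in range(3):
        orfs.extend(_scan_frame(gene, seq, frame, "+", allow_partial))
    if six_frame:
        from Bio.Seq import Seq

        rc = str(Seq(seq).reverse_complement())
        for frame in range(3):
            for orf in _scan_frame(gene, rc, frame, "-", allow_partial):
                # report reverse-strand coordinates on the forward transcript
                orfs.append(
                    OrfRecord(gene, frame, "-", len(seq) - orf.end, len(seq) - orf.start, orf.partial5)
                )
    orfs = [o for o in orfs if o.n_codons >= min_len_codons]
    orfs.sort(key=lambda o: (-(o.end - o.start), o.start, o.strand, o.frame))
    return orfs


def apply_fixed_variants(cds: str, variants, cds_start: int = 0) -> str:
    """Swap fixed-variant alleles into a CDS, producing the alternative CDS.

    ``variants`` is an iterable of ``(pos, ref_allele, alt_allele)`` with
    ``pos`` on the transcript; positions outside ``[cds_start, cds_start +
    len(cds))`` are ignored (the CDS-trimming step). A reference-allele
    mismatch indicates corrupt inputs and raises ``ValueError``.
    """
    out = list(cds)
    for pos, ref, alt in variants:
        k = pos - cds_start
        if k < 0 or k >= len(cds):
            continue
        if out[k] != ref:
            raise ValueError(
                f"variant at CDS position {k}: reference allele {ref!r} "
                f"does not match sequence base {out[k]!r}"
            )
        out[k] = alt
    return "".join(out)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    S: float
    N: float


@dataclass(frozen=True)
class DiffCounts:
    Ns: float
    Nn: float


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three single-nucleotide
    mutants that are synonymous; mutants creating stop codons count as
    nonsynonymous.
    """
    aa = translate_codon(codon)
    s = 0.0
    for i in range(3):
        syn = 0
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if not is_stop(mutant) and translate_codon(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def ng86_site_counts(cds: str) -> SiteCounts:
    """NG86 synonymous/nonsynonymous site counts of a CDS.

    Length must be a multiple of 3 and free of internal stop codons; codons
    with ambiguous bases are skipped (logged).
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    S = N = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(b not in BASES for b in codon):
            logger.warning("skipping ambiguous codon %r at position %d", codon, i)
            continue
        s, n = _codon_sites(codon)
        S += s
        N += n
    return SiteCounts(S, N)


def classify_single_change(codon: str, pos: int, new_base: str) -> str:
    """Classify a single-nucleotide change in codon context.

    Returns 'syn' or 'nonsyn'; changes to or from stop codons are
    nonsynonymous unless both codons are stops.
    """
    mutant = codon[:pos] + new_base + codon[pos + 1:]
    a1, a2 = CODON_TO_AA[codon], CODON_TO_AA[mutant]
    return "syn" if a1 == a2 else "nonsyn"


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) step counts between two codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are excluded from the average (falling
    back to all pathways if every one passes through a stop).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []
    valid: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                non += 1
            if nxt != c2 and is_stop(nxt):
                through_stop = True
            cur = nxt
        paths.append((syn, non))
        if not through_stop:
            valid.append((syn, non))
    use = valid or paths
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def ng86_difference_counts(cdsA: str, cdsB: str) -> DiffCounts:
    """NG86 pathway-averaged difference counts between two in-frame CDSs."""
    if len(cdsA) != len(cdsB):
        raise ValueError("CDS lengths differ")
    if len(cdsA) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    cdsA, cdsB = cdsA.upper(), cdsB.upper()
    Ns = Nn = 0.0
    for i in range(0, len(cdsA), 3):
        a, b = cdsA[i:i + 3], cdsB[i:i + 3]
        if a == b:
            continue
        if any(x not in BASES for x in a + b):
            logger.warning("skipping ambiguous codon pair %r/%r at %d", a, b, i)
            continue
        s, n = _pair_diffs(a, b)
        Ns += s
        Nn += n
    return DiffCounts(Ns, Nn)


# ---------------------------------------------------------------------------
# Ka/Ks estimation and classification
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsRecord:
    gene: str
    S: float
    N: float
    Ns: float
    Nn: float
    ps: float = math.nan
    pn: float = math.nan
    Ka: float = math.nan
    Ks: float = math.nan
    ratio: float = math.nan
    fisher_p: float = math.nan
    selection_class: str = "unclassified"
    flags: list[str] = field(default_factory=list)


def _fisher_table(rec: KaKsRecord) -> list[list[int]]:
    ns, nn = round(rec.Ns), round(rec.Nn)
    return [
        [ns, max(round(rec.S - rec.Ns), 0)],
        [nn, max(round(rec.N - rec.Nn), 0)],
    ]


def kaks_estimate(cdsA: str, cdsB: str, gene: str = "", alpha: float = 0.05) -> KaKsRecord:
    """NG86 Ka/Ks with Fisher exact significance and selection class.

    ``ps = Ns/S`` and ``pn = Nn/N`` are Jukes–Cantor corrected into Ks and
    Ka. The Fisher test is two-sided on ``[[round(Ns), round(S-Ns)],
    [round(Nn), round(N-Nn)]]``. Class is positive iff ratio > 1 and
    p < alpha; purifying iff ratio < 1 and p < alpha; otherwise
    unclassified. Undefined corrections or Ks = 0 leave the record
    unclassified (flagged), except Ks = 0 with Nn > 0 and a significant
    test, reported as positive with infinite ratio.
    """
    if len(cdsA) >= 3 and is_stop(cdsA[-3:]) and is_stop(cdsB[-3:]):
        cdsA, cdsB = cdsA[:-3], cdsB[:-3]
    sc = ng86_site_counts(cdsA)
    dc = ng86_difference_counts(cdsA, cdsB)
    rec = KaKsRecord(gene=gene, S=sc.S, N=sc.N, Ns=dc.Ns, Nn=dc.Nn)
    if sc.S == 0 or sc.N == 0:
        rec.flags.append("degenerate-sites")
        return rec
    rec.ps = dc.Ns / sc.S
    rec.pn = dc.Nn / sc.N
    rec.fisher_p = float(fisher_exact(_fisher_table(rec), alternative="two-sided")[1])
    try:
        rec.Ks = jukes_cantor(rec.ps)
        rec.Ka = jukes_cantor(rec.pn)
    except ValueError:
        rec.flags.append("jc-undefined")
        return rec
    if rec.Ks == 0.0:
        if rec.Ka > 0.0:
            rec.ratio = math.inf
            rec.flags.append("ks-zero")
            if rec.fisher_p < alpha:
                rec.selection_class = "positive"
        return rec
    rec.ratio = rec.Ka / rec.Ks
    if rec.ratio > 50:
        rec.flags.append("ratio-gt-50")
    if rec.fisher_p < alpha:
        if rec.ratio > 1:
            rec.selection_class = "positive"
        elif rec.ratio < 1:
            rec.selection_class = "purifying"
    return rec


def classify_selection(records, alpha: float = 0.05) -> dict[str, int]:
    """Partition counts {positive, purifying, unclassified} over records."""
    records = list(records)
    counts = {"positive": 0, "purifying": 0, "unclassified": 0}
    for rec in records:
        cls = rec.selection_class
        if not math.isnan(rec.fisher_p) and not math.isnan(rec.ratio):
            cls = "unclassified"
            if rec.fisher_p < alpha:
                if rec.ratio > 1:
                    cls = "positive"
                elif rec.ratio < 1:
                    cls = "purifying"
        counts[cls] += 1
    assert sum(counts.values()) == len(records)
    return counts


# ---------------------------------------------------------------------------
# Distance and dating
# ---------------------------------------------------------------------------

def p_distance(seqA: str, seqB: str, gap_chars: str = "-.") -> float:
    """Proportion of differing sites, excluding pairwise-gapped columns."""
    if len(seqA) != len(seqB):
        raise ValueError("aligned sequences must have equal length")
    compared = mismatch = 0
    for a, b in zip(seqA.upper(), seqB.upper()):
        if a in gap_chars or b in gap_chars:
            continue
        compared += 1
        if a != b:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable (non-gap) sites")
    return mismatch / compared


def divergence_time(distance: float, rate_per_myr: float = 0.02) -> float:
    """Split time in Myr: genetic distance divided by divergence rate."""
    if rate_per_myr <= 0:
        raise ValueError("rate must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance / rate_per_myr
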