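"""Genotype calling from pileups and fixed inter-clone difference extraction.

A pileup row carries per-site allele depths (A/C/G/T plus ins/del read
counts). Calls partition sites into hom_ref / hom_alt / het / indel /
no_call; fixed differences between the clones are the hom_alt calls,
consolidated bi-directionally over reciprocal-best-hit orthologs onto the
designated reference clone's coordinates. Heterozygosity is the fraction
of callable sites called het.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PileupSite",
    "GenotypeCall",
    "HeterozygosityEstimate",
    "CallerParams",
    "call_genotype",
    "call_genotypes",
    "fixed_differences",
    "consolidate_bidirectional",
    "heterozygosity",
]

_ALLELES = ("A", "C", "G", "T")
PILEUP_COLUMNS = ["gene", "pos", "ref", "A", "C", "G", "T", "ins", "del"]


@dataclass(frozen=True)
class PileupSite:
    gene: str
    pos: int  # 0-based
    ref: str
    A: int
    C: int
    G: int
    T: int
    ins: int = 0
    dels: int = 0


@dataclass(frozen=True)
class GenotypeCall:
    gene: str
    pos: int
    call_class: str  # hom_ref | hom_alt | het | indel | no_call
    alleles: tuple[str, ...]
    depths: tuple[int, ...]


@dataclass(frozen=True)
class HeterozygosityEstimate:
    clone: str
    het_sites: int
    total_sites: int

    @property
    def H(self) -> float:
        return self.het_sites / self.total_sites


@dataclass(frozen=True)
class CallerParams:
    min_depth: int = 10
    hom_fraction: float = 0.9
    het_min_fraction: float = 0.2
    het_min_reads: int = 2


def call_genotype(
    site: PileupSite,
    min_depth: int = 10,
    hom_fraction: float = 0.9,
    het_min_fraction: float = 0.2,
    het_min_reads: int = 2,
) -> GenotypeCall:
    """Classify one pileup site.

    Order of rules: no_call below ``min_depth`` total depth; indel when the
    ins+del read fraction reaches ``het_min_fraction``; hom_alt when the top
    non-reference allele fraction reaches ``hom_fraction``; het when the
    second allele holds >= ``het_min_fraction`` of base reads with >=
    ``het_min_reads`` reads and the reference allele has support; otherwise
    hom_ref.
    """
    if site.ref not in _ALLELES:
        raise ValueError(f"unknown reference base {site.ref!r}")
    depths = {"A": site.A, "C": site.C, "G": site.G, "T": site.T}
    base_total = sum(depths.values())
    total = base_total + site.ins + site.dels
    if total < min_depth:
        return GenotypeCall(site.gene, site.pos, "no_call", (), ())
    if (site.ins + site.dels) / total >= het_min_fraction:
        return GenotypeCall(site.gene, site.pos, "indel", (), ())
    ranked = sorted(_ALLELES, key=lambda b: (-depths[b], b))
    top_nonref = next(b for b in ranked if b != site.ref)
    if base_total > 0 and depths[top_nonref] / base_total >= hom_fraction:
        return GenotypeCall(
            site.gene, site.pos, "hom_alt", (top_nonref,), (depths[top_nonref],)
        )
    first, second = ranked[0], ranked[1]
    if (
        base_total > 0
        and depths[second] / base_total >= het_min_fraction
        and depths[second] >= het_min_reads
        and depths[site.ref] >= 1
    ):
        return GenotypeCall(
            site.gene, site.pos, "het", (first, second), (depths[first], depths[second])
        )
    return GenotypeCall(site.gene, site.pos, "hom_ref", (site.ref,), (depths[site.ref],))


def call_genotypes(pileup: pd.DataFrame, params: CallerParams = CallerParams()) -> pd.DataFrame:
    """Vectorised genotype calling over a pileup table.

    Returns the pileup with added columns ``call`` and ``alt`` (the top
    non-reference allele; '.' where irrelevant). Equivalent site-by-site to
    :func:`call_genotype`.
    """
    base = pileup[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    ins = pileup["ins"].to_numpy(dtype=np.int64)
    dels = pileup["del"].to_numpy(dtype=np.int64)
    base_total = base.sum(axis=1)
    total = base_total + ins + dels

    ref_idx = pd.Categorical(pileup["ref"], categories=list(_ALLELES)).codes
    if (ref_idx < 0).any():
        raise ValueError("unknown reference base in pileup")
    n = len(pileup)
    rows = np.arange(n)

    # rank alleles per row; ties by alphabetical order via stable sort on (-depth)
    order = np.argsort(-base, axis=1, kind="stable")
    first = order[:, 0]
    second = order[:, 1]
    ref_depth = base[rows, ref_idx]

    masked = base.copy()
    masked[rows, ref_idx] = -1
    nonref_order = np.argsort(-masked, axis=1, kind="stable")
    top_nonref = nonref_order[:, 0]
    top_nonref_depth = base[rows, top_nonref]

    with np.errstate(divide="ignore", invalid="ignore"):
        safe_base = np.maximum(base_total, 1)
        frac_nonref = top_nonref_depth / safe_base
        frac_second = base[rows, second] / safe_base
        frac_indel = (ins + dels) / np.maximum(total, 1)

    call = np.full(n, "hom_ref", dtype=object)
    is_nocall = total < params.min_depth
    is_indel = ~is_nocall & (frac_indel >= params.het_min_fraction)
    is_homalt = ~is_nocall & ~is_indel & (base_total > 0) & (frac_nonref >= params.hom_fraction)
    is_het = (
        ~is_nocall
        & ~is_indel
        & ~is_homalt
        & (base_total > 0)
        & (frac_second >= params.het_min_fraction)
        & (base[rows, second] >= params.het_min_reads)
        & (ref_depth >= 1)
    )
    call[is_nocall] = "no_call"
    call[is_indel] = "indel"
    call[is_homalt] = "hom_alt"
    call[is_het] = "het"

    allele_arr = np.array(list(_ALLELES))
    alt = np.full(n, ".", dtype=object)
    alt[is_homalt] = allele_arr[top_nonref[is_homalt]]
    het_alt = np.where(first == ref_idx, second, first)
    alt[is_het] = allele_arr[het_alt[is_het]]

    out = pileup.copy()
    out["call"] = call
    out["alt"] = alt
    return out


def fixed_differences(calls: pd.DataFrame) -> pd.DataFrame:
    """One-direction fixed-difference table: exactly the hom_alt calls."""
    rows = calls[calls["call"] == "hom_alt"]
    return rows[["gene", "pos", "ref", "alt"]].reset_index(drop=True)


def consolidate_bidirectional(
    table_ab: pd.DataFrame,
    table_ba: pd.DataFrame,
    pairs,
    position_maps: dict[str, dict[int, int]] | None = None,
) -> pd.DataFrame:
    """Consolidate directional fixed-difference tables onto reference clone A.

    ``table_ab`` holds clone-A reads called against clone-B references
    (coordinates on B); ``table_ba`` the converse (coordinates on A, the
    designated reference). Rows in genes without a reciprocal-best-hit pair
    are dropped; B-side rows are mapped onto A coordinates through
    ``position_maps`` (gene_b -> {posB: posA}); unmappable rows are dropped
    with a warning. The output reports, per consolidated row, whether it
    was observed in one or both directions.
    """
    a_by_b = {p.gene_b: p.gene_a for p in pairs}
    rbh_a = {p.gene_a for p in pairs}
    position_maps = position_maps or {}

    rows: dict[tuple[str, int], dict] = {}
    for _, r in table_ba.iterrows():
        if r["gene"] not in rbh_a:
            continue
        rows[(r["gene"], int(r["pos"]))] = {
            "gene": r["gene"],
            "pos": int(r["pos"]),
            "allele_a": r["ref"],
            "allele_b": r["alt"],
            "directions": "BA",
        }
    n_dropped = 0
    for _, r in table_ab.iterrows():
        gene_b = r["gene"]
        gene_a = a_by_b.get(gene_b)
        if gene_a is None:
            continue
        pmap = position_maps.get(gene_b)
        if pmap is None:
            pos_a = int(r["pos"])  # identity fallback when no map supplied
        else:
            pos_a = pmap.get(int(r["pos"]), -1)
            if pos_a < 0:
                n_dropped += 1
                continue
        key = (gene_a, pos_a)
        if key in rows:
            rows[key]["directions"] = "both"
        else:
            # observed only A-on-B: the alt allele is clone A's, B's is its ref
            rows[key] = {
                "gene": gene_a,
                "pos": pos_a,
                "allele_a": r["alt"],
                "allele_b": r["ref"],
                "directions": "AB",
            }
    if n_dropped:
        logger.warning("dropped %d rows mapping outside the partner sequence", n_dropped)
    out = pd.DataFrame(
        sorted(rows.values(), key=lambda d: (d["gene"], d["pos"])),
        columns=["gene", "pos", "allele_a", "allele_b", "directions"],
    )
    return out


def heterozygosity(
    calls: pd.DataFrame, clone: str = "", denominator: str = "callable"
) -> HeterozygosityEstimate:
    """Fraction of sites carrying heterozygous polymorphisms.

    ``denominator='callable'`` excludes no_call sites from the total;
    ``'all'`` divides by every pileup site.
    """
    if len(calls) == 0:
        raise ValueError("no sites to estimate heterozygosity from")
    het = int((calls["call"] == "het").sum())
    if denominator == "callable":
        total = int((calls["call"] != "no_call").sum())
    elif denominator == "all":
        total = len(calls)
    else:
        raise ValueError("denominator must be 'callable' or 'all'")
    if total == 0:
        raise ValueError("zero callable sites")
    return HeterozygosityEstimate(clone, het, total)
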