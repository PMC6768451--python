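"""Synthetic clone-pair transcriptome generator.

Produces everything the analysis consumes: an ancestral transcript set and
two clone derivatives carrying planted fixed differences of known
synonymous/nonsynonymous class, within-clone heterozygous sites,
contaminant and rRNA contigs, Poisson-depth/binomial-allele pileups, and
negative-binomial count matrices with planted differential expression.
All randomness flows from one seed through named sub-streams, so identical
configurations reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import filter as filt
from ._genetics import BASES, SENSE_CODONS, STOP_CODONS
from .selection import classify_single_change, is_stop, ng86_site_counts
from .variants import PILEUP_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "FixedDiffTruth",
    "simulate_transcriptomes",
    "inject_contaminants",
    "simulate_pileups",
    "simulate_counts",
    "simulate_pathways",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 60
    cds_len_codons: tuple[int, int] = (120, 300)
    utr_len: tuple[int, int] = (30, 90)
    omega: float = 0.2
    omega_mixture: tuple[tuple[float, float], ...] | None = None  # ((fraction, omega), ...)
    ks_target: float = 0.05
    het_rate: float = 0.001
    coverage: float = 30.0
    error_rate: float = 0.005
    n_contaminants: int = 10
    n_rrna: int = 5
    n_replicates_per_condition: int = 2
    de_fraction: float = 0.1
    fold_change: float = 4.0
    nb_dispersion: float = 0.1
    gene_gc: float = 0.30
    contaminant_gc: float = 0.55
    allow_multi_hit: bool = False
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.ks_target <= 0:
            raise ValueError("ks_target must be positive")
        for name in ("het_rate", "error_rate", "de_fraction", "gene_gc", "contaminant_gc", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.omega_mixture is not None:
            fracs = [f for f, _ in self.omega_mixture]
            if abs(sum(fracs) - 1.0) > 1e-9 or any(w < 0 for _, w in self.omega_mixture):
                raise ValueError("omega_mixture fractions must sum to 1 with omegas >= 0")
        if self.cds_len_codons[0] < 10 or self.cds_len_codons[0] > self.cds_len_codons[1]:
            raise ValueError("invalid cds_len_codons range")
        if self.n_replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")


@dataclass(frozen=True)
class FixedDiffTruth:
    gene: str
    pos: int  # 0-based on the transcript
    base_a: str
    base_b: str
    cls: str  # 'syn' | 'nonsyn'
    branch: str  # clone that carries the derived allele


@dataclass
class SimulationTruth:
    omega_true: dict[str, float] = field(default_factory=dict)
    cds_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)  # incl. stop codon
    fixed_diffs: list[FixedDiffTruth] = field(default_factory=list)
    het_sites: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    contaminant_ids: list[str] = field(default_factory=list)
    rrna_ids: list[str] = field(default_factory=list)
    de_flags: dict[str, bool] = field(default_factory=dict)
    fold: dict[str, float] = field(default_factory=dict)
    library_factors: dict[str, float] = field(default_factory=dict)
    indel_sites: set[tuple[str, int]] = field(default_factory=set)

    def fixed_diffs_by_gene(self) -> dict[str, list[FixedDiffTruth]]:
        out: dict[str, list[FixedDiffTruth]] = {}
        for d in self.fixed_diffs:
            out.setdefault(d.gene, []).append(d)
        return out


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode())])


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    idx = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join(BASES[i] for i in idx)


def _codon_weights(gc: float) -> np.ndarray:
    p = _base_probs(gc)
    w = np.array([p[_BASE_INDEX[c[0]]] * p[_BASE_INDEX[c[1]]] * p[_BASE_INDEX[c[2]]] for c in SENSE_CODONS])
    return w / w.sum()


def _gene_omegas(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.omega_mixture is None:
        return np.full(config.n_genes, float(config.omega))
    fracs = np.array([f for f, _ in config.omega_mixture])
    omegas = np.array([w for _, w in config.omega_mixture])
    idx = rng.choice(len(omegas), size=config.n_genes, p=fracs)
    return omegas[idx]


def _plant_gene(
    rng: np.random.Generator,
    config: SimulationConfig,
    gene: str,
    omega: float,
    weights: np.ndarray,
) -> tuple[str, str, str, list[FixedDiffTruth], tuple[int, int]] | None:
    """Build one gene's ancestral/cloneA/cloneB transcripts, or None on failure."""
    n_codons = int(rng.integers(config.cds_len_codons[0], config.cds_len_codons[1] + 1))
    body_idx = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=weights)
    stop = sorted(STOP_CODONS)[int(rng.integers(3))]
    codons = ["ATG"] + [SENSE_CODONS[i] for i in body_idx] + [stop]
    utr5 = _random_seq(rng, int(rng.integers(config.utr_len[0], config.utr_len[1] + 1)), config.gene_gc)
    utr3 = _random_seq(rng, int(rng.integers(config.utr_len[0], config.utr_len[1] + 1)), config.gene_gc)

    counting_cds = "".join(codons[:-1])  # terminal stop excluded from site counts
    sc = ng86_site_counts(counting_cds)
    n_syn = int(rng.poisson(config.ks_target * sc.S))
    n_non = int(rng.poisson(omega * config.ks_target * sc.N))

    codons_a = list(codons)
    codons_b = list(codons)
    hit: set[int] = set()
    diffs: list[FixedDiffTruth] = []
    budget = 200 * (n_syn + n_non + 1)
    for cls, quota in (("syn", n_syn), ("nonsyn", n_non)):
        placed = 0
        while placed < quota:
            budget -= 1
            if budget <= 0:
                return None
            c = int(rng.integers(1, n_codons - 1))  # skip ATG and the stop codon
            j = int(rng.integers(3))
            branch = "A" if rng.random() < 0.5 else "B"
            mutated = codons_a if branch == "A" else codons_b
            cur = mutated[c]
            ref_base = cur[j]
            alt = BASES[int(rng.integers(4))]
            if alt == ref_base:
                continue
            if c in hit and not config.allow_multi_hit:
                continue
            new_codon = cur[:j] + alt + cur[j + 1:]
            if is_stop(new_codon):
                continue
            if classify_single_change(cur, j, alt) != cls:
                continue
            mutated[c] = new_codon
            hit.add(c)
            pos = len(utr5) + 3 * c + j
            base_a, base_b = codons_a[c][j], codons_b[c][j]
            assert base_a != base_b
            diffs.append(FixedDiffTruth(gene, pos, base_a, base_b, cls, branch))
            placed += 1
    anc = utr5 + "".join(codons) + utr3
    seq_a = utr5 + "".join(codons_a) + utr3
    seq_b = utr5 + "".join(codons_b) + utr3
    cds_range = (len(utr5), len(utr5) + 3 * n_codons)
    return anc, seq_a, seq_b, diffs, cds_range


def simulate_transcriptomes(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], SimulationTruth]:
    """Generate ancestral and clone transcript sets plus ground truth.

    Each gene is one transcript (5' UTR + ATG...stop CDS + 3' UTR) of
    identical length across the three sets; fixed differences are single
    substitutions planted inside the CDS at Poisson counts with expectation
    ``ks_target * S`` (synonymous) and ``omega * ks_target * N``
    (nonsynonymous), classified against the codon context, at most one per
    codon unless ``allow_multi_hit``. Heterozygous sites are planted per
    clone at ``het_rate`` per transcript site, never on a fixed-difference
    position of the same clone.
    """
    rng = _rng(config, "transcriptomes")
    weights = _codon_weights(config.gene_gc)
    omegas = _gene_omegas(config, _rng(config, "omega"))
    truth = SimulationTruth()
    ancestral: dict[str, str] = {}
    clone_a: dict[str, str] = {}
    clone_b: dict[str, str] = {}
    for g in range(config.n_genes):
        gene = f"gene{g + 1:04d}"
        for attempt in range(10):
            built = _plant_gene(rng, config, gene, float(omegas[g]), weights)
            if built is not None:
                break
            logger.warning("rejection sampling failed for %s (attempt %d); resampling gene", gene, attempt + 1)
        else:
            raise RuntimeError(f"could not place required differences in {gene}")
        anc, seq_a, seq_b, diffs, cds_range = built
        ancestral[gene] = anc
        clone_a[gene] = seq_a
        clone_b[gene] = seq_b
        truth.fixed_diffs.extend(diffs)
        truth.omega_true[gene] = float(omegas[g])
        truth.cds_ranges[gene] = cds_range

    het_rng = _rng(config, "heterozygosity")
    fixed_pos = {(d.gene, d.pos) for d in truth.fixed_diffs}
    for clone_name, seqs in (("A", clone_a), ("B", clone_b)):
        sites: list[tuple[str, int, str]] = []
        for gene, seq in seqs.items():
            mask = het_rng.random(len(seq)) < config.het_rate
            for pos in np.flatnonzero(mask):
                pos = int(pos)
                if (gene, pos) in fixed_pos:
                    continue
                ref = seq[pos]
                alt = BASES[(_BASE_INDEX[ref] + 1 + int(het_rng.integers(3))) % 4]
                sites.append((gene, pos, alt))
        truth.het_sites[clone_name] = sites
    return ancestral, clone_a, clone_b, truth


def inject_contaminants(
    clone_sets: dict[str, dict[str, str]],
    config: SimulationConfig,
    truth: SimulationTruth,
) -> tuple[dict[str, dict[str, str]], dict[str, str], dict[str, str]]:
    """Add contaminant and rRNA contigs to each clone's transcript set.

    Contaminants are drawn from a composition model distinct from the gene
    GC content; each generated contig is verified with the filter module's
    aligner to have no gene hit competitive with its own database entry.
    Returns (mixed sets, contaminant db, rRNA db); ids are recorded in the
    truth object.
    """
    if config.n_contaminants == 0 and config.n_rrna == 0:
        return clone_sets, {}, {}
    rng = _rng(config, "contaminants")
    any_clone = next(iter(clone_sets.values()))
    gene_index = filt.KmerIndex(any_clone, filt.Scoring().seed_k)
    contaminant_db: dict[str, str] = {}
    for i in range(config.n_contaminants):
        name = f"contam{i + 1:04d}"
        for _ in range(20):
            seq = _random_seq(rng, int(rng.integers(500, 1500)), config.contaminant_gc)
            hit = filt.search_best_hit(seq, gene_index)
            self_bits = filt.Scoring().bitscore(2 * len(seq))
            if hit is None or hit.bitscore < self_bits - 100.0:
                break
        contaminant_db[name] = seq
    rrna_db: dict[str, str] = {}
    for i in range(config.n_rrna):
        name = f"rrna{i + 1:04d}"
        for _ in range(20):
            seq = _random_seq(rng, int(rng.integers(1000, 2000)), 0.45)
            hit = filt.search_best_hit(seq, gene_index)
            if hit is None or hit.evalue > 1e-10:
                break
        rrna_db[name] = seq
    mixed = {}
    for clone, seqs in clone_sets.items():
        merged = dict(seqs)
        for name, seq in contaminant_db.items():
            merged[name] = seq
        for name, seq in rrna_db.items():
            merged[name] = seq
        mixed[clone] = merged
    truth.contaminant_ids = sorted(contaminant_db)
    truth.rrna_ids = sorted(rrna_db)
    return mixed, contaminant_db, rrna_db


def _pileup_one_direction(
    rng: np.random.Generator,
    ref_seqs: dict[str, str],
    read_seqs: dict[str, str],
    het_sites: list[tuple[str, int, str]],
    config: SimulationConfig,
    truth: SimulationTruth,
    record_indels: bool,
) -> pd.DataFrame:
    het_by_gene: dict[str, dict[int, str]] = {}
    for gene, pos, alt in het_sites:
        het_by_gene.setdefault(gene, {})[pos] = alt
    frames = []
    e = config.error_rate
    for gene in ref_seqs:
        ref = ref_seqs[gene]
        reads_src = read_seqs[gene]
        L = len(ref)
        ref_idx = np.array([_BASE_INDEX[b] for b in ref], dtype=np.int64)
        true_idx = np.array([_BASE_INDEX[b] for b in reads_src], dtype=np.int64)
        depth = rng.poisson(config.coverage, size=L)
        pvals = np.full((L, 4), e / 3.0)
        pvals[np.arange(L), true_idx] += 1.0 - e - e / 3.0
        het = het_by_gene.get(gene, {})
        if het:
            hpos = np.array(sorted(het), dtype=np.int64)
            halt = np.array([_BASE_INDEX[het[int(p)]] for p in hpos], dtype=np.int64)
            pvals[hpos] = e / 3.0
            pvals[hpos, true_idx[hpos]] += 0.5 * (1.0 - e - e / 3.0)
            pvals[hpos, halt] += 0.5 * (1.0 - e - e / 3.0)
        counts = rng.multinomial(depth, pvals)
        ins = np.zeros(L, dtype=np.int64)
        dels = np.zeros(L, dtype=np.int64)
        if config.indel_rate > 0:
            imask = rng.random(L) < config.indel_rate
            for p in np.flatnonzero(imask):
                take = rng.binomial(counts[p].sum(), 0.5)
                # move reads from the modal base into a deletion signal
                top = int(np.argmax(counts[p]))
                moved = min(take, counts[p, top])
                counts[p, top] -= moved
                dels[p] += moved
                if record_indels:
                    truth.indel_sites.add((gene, int(p)))
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "pos": np.arange(L),
                    "ref": list(ref),
                    "A": counts[:, 0],
                    "C": counts[:, 1],
                    "G": counts[:, 2],
                    "T": counts[:, 3],
                    "ins": ins,
                    "del": dels,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]


def simulate_pileups(
    clone_a: dict[str, str],
    clone_b: dict[str, str],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Per-site pileups for both directional and both self alignments.

    Keys: ``A_on_B`` (clone-A reads against clone-B references), ``B_on_A``,
    and self tables ``A_on_A`` / ``B_on_B``. Depth is Poisson(coverage);
    heterozygous sites split reads 50/50 between the two alleles; every
    read mismatches to a uniform other base with probability error_rate.
    """
    out = {}
    for key, (ref, reads, het_clone) in {
        "A_on_B": (clone_b, clone_a, "A"),
        "B_on_A": (clone_a, clone_b, "B"),
        "A_on_A": (clone_a, clone_a, "A"),
        "B_on_B": (clone_b, clone_b, "B"),
    }.items():
        rng = _rng(config, f"pileup:{key}")
        out[key] = _pileup_one_direction(
            rng, ref, reads, truth.het_sites.get(het_clone, []), config, truth,
            record_indels=(key == "B_on_A"),
        )
    return out


def simulate_counts(
    config: SimulationConfig, truth: SimulationTruth | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Negative-binomial count matrix with planted differential expression.

    Gene means are log-normal; DE genes (fraction ``de_fraction``, none
    when ``fold_change == 1``) have their condition-2 mean multiplied by
    ``fold_change``. Dispersion follows Var = mu + nb_dispersion * mu^2.
    Returns (counts, condition labels); DE truth is written into ``truth``
    when given.
    """
    rng = _rng(config, "counts")
    n = config.n_genes
    genes = [f"gene{g + 1:04d}" for g in range(n)]
    reps = config.n_replicates_per_condition
    samples = [f"cond1_rep{i + 1}" for i in range(reps)] + [f"cond2_rep{i + 1}" for i in range(reps)]
    conditions = ["cond1"] * reps + ["cond2"] * reps

    means = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n)
    if config.fold_change == 1.0:
        de = np.zeros(n, dtype=bool)
    else:
        de = rng.random(n) < config.de_fraction
    fold = np.where(de, config.fold_change, 1.0)
    lib = rng.uniform(0.7, 1.3, size=len(samples))

    mu = means[:, None] * lib[None, :]
    cond2 = np.array([c == "cond2" for c in conditions])
    mu[:, cond2] *= fold[:, None]
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=genes, columns=samples)
    df.index.name = "gene"
    if truth is not None:
        truth.de_flags = dict(zip(genes, de.tolist()))
        truth.fold = dict(zip(genes, fold.tolist()))
        truth.library_factors = dict(zip(samples, lib.tolist()))
    return df, conditions


def simulate_pathways(
    gene_ids,
    n_pathways: int = 20,
    size_range: tuple[int, int] = (5, 30),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random pathway annotation (GMT-style) over the simulated genes."""
    rng = np.random.default_rng([seed, zlib.crc32(b"pathways")])
    gene_ids = list(gene_ids)
    out = {}
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], min(size_range[1], len(gene_ids)) + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        out[f"pw{i + 1:03d}"] = {gene_ids[j] for j in members}
    return out
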