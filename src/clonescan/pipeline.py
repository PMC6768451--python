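"""End-to-end orchestration: simulate -> filter -> orthologs -> variants ->
selection -> enrichment -> differential expression, with a run report.

The report's accounting is checked on every run: the summed synonymous and
nonsynonymous difference counts must equal the number of coding fixed SNPs
fed to the Ka/Ks stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import de as de_mod
from . import enrich as enrich_mod
from . import io as cio
from . import orthologs as orth_mod
from . import selection as sel_mod
from . import simulate as sim_mod
from . import variants as var_mod
from .filter import Scoring, contaminant_filter, rrna_filter

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)  # margin, evalue
    variants: dict = field(default_factory=dict)  # caller thresholds, het_denominator
    orthologs: dict = field(default_factory=dict)  # evalue
    selection: dict = field(default_factory=dict)  # alpha, min_orf_codons
    enrich: dict = field(default_factory=dict)  # alpha, n_pathways
    de: dict = field(default_factory=dict)  # ppde_threshold, fdr_cap
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


@dataclass
class RunReport:
    seed: int
    contigs_total: int = 0
    contigs_kept: int = 0
    contigs_removed_contaminant: int = 0
    contigs_removed_rrna: int = 0
    fixed_snps_a_on_b: int = 0
    fixed_snps_b_on_a: int = 0
    fixed_snps_consolidated: int = 0
    rbh_pairs: int = 0
    genes_with_orf_and_coding_snps: int = 0
    coding_fixed_snps: int = 0
    synonymous_substitutions: float = 0.0
    nonsynonymous_substitutions: float = 0.0
    positive_genes: int = 0
    purifying_genes: int = 0
    unclassified_genes: int = 0
    enriched_pathways: int = 0
    de_genes: int = 0
    heterozygosity_a: float = 0.0
    heterozygosity_b: float = 0.0
    version: str = ""

    def check_accounting(self, atol: float = 1e-6) -> None:
        total = self.synonymous_substitutions + self.nonsynonymous_substitutions
        if abs(total - self.coding_fixed_snps) > atol:
            raise AssertionError(
                f"substitution accounting broken: {self.synonymous_substitutions} syn + "
                f"{self.nonsynonymous_substitutions} nonsyn != {self.coding_fixed_snps} coding SNPs"
            )


def run_all(config: PipelineConfig) -> RunReport:
    """Run every stage on a simulated clone pair and write all outputs.

    Re-running with the same config and seed reproduces every output file
    byte-identically (wall-clock timings go to a separate log).
    """
    from . import __version__

    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)

    sim_cfg = sim_mod.SimulationConfig(**{**config.simulate, "seed": config.seed})
    ancestral, clone_a, clone_b, truth = sim_mod.simulate_transcriptomes(sim_cfg)
    mixed, contam_db, rrna_db = sim_mod.inject_contaminants(
        {"A": clone_a, "B": clone_b}, sim_cfg, truth
    )
    pileups = sim_mod.simulate_pileups(clone_a, clone_b, truth, sim_cfg)
    counts, conditions = sim_mod.simulate_counts(sim_cfg, truth)
    annotations = sim_mod.simulate_pathways(
        sorted(ancestral), n_pathways=config.enrich.get("n_pathways", 20), seed=config.seed
    )

    cio.write_fasta(ancestral, outdir / "ancestral.fasta")
    cio.write_fasta(clone_a, outdir / "cloneA.fasta")
    cio.write_fasta(clone_b, outdir / "cloneB.fasta")
    for clone, seqs in mixed.items():
        cio.write_fasta(seqs, outdir / f"clone{clone}_mixed.fasta")
    if contam_db:
        cio.write_fasta(contam_db, outdir / "contaminant_db.fasta")
    if rrna_db:
        cio.write_fasta(rrna_db, outdir / "rrna_db.fasta")
    for key, table in pileups.items():
        cio.write_pileup(table, outdir / f"pileup_{key}.tsv")
    cio.write_counts(counts, outdir / "counts.tsv")
    cio.write_gmt(annotations, outdir / "pathways.gmt")

    # --- contaminant & rRNA filtering (per clone, against the reference set)
    scoring = Scoring()
    margin = float(config.filter.get("margin", 100.0))
    rrna_cut = float(config.filter.get("evalue", 1e-10))
    kept_sets: dict[str, dict[str, str]] = {}
    decision_rows = []
    for clone, contigs in mixed.items():
        if contam_db:
            decisions = contaminant_filter(contigs, ancestral, contam_db, margin=margin, scoring=scoring)
        else:
            decisions = []
        removed = {d.contig for d in decisions if not d.kept}
        survivors = {n: s for n, s in contigs.items() if n not in removed}
        if rrna_db:
            rdec = rrna_filter(survivors, rrna_db, evalue_cutoff=rrna_cut, scoring=scoring)
        else:
            rdec = []
        rrna_removed = {d.contig for d in rdec if not d.kept}
        kept_sets[clone] = {n: s for n, s in survivors.items() if n not in rrna_removed}
        report.contigs_total += len(contigs)
        report.contigs_kept += len(kept_sets[clone])
        report.contigs_removed_contaminant += len(removed)
        report.contigs_removed_rrna += len(rrna_removed)
        for d in list(decisions) + list(rdec):
            decision_rows.append(
                {"clone": clone, "contig": d.contig, "kept": d.kept, "reason": d.reason,
                 "best_ref_bits": d.best_ref_bits, "best_contam_bits": d.best_contam_bits}
            )
    if decision_rows:
        import pandas as pd

        pd.DataFrame(decision_rows).to_csv(outdir / "filter_decisions.tsv", sep="\t", index=False)

    # --- reciprocal best hits
    ortho_cut = float(config.orthologs.get("evalue", 1e-50))
    map_ab = orth_mod.best_hits(kept_sets["A"], kept_sets["B"], evalue_cutoff=ortho_cut, scoring=scoring)
    map_ba = orth_mod.best_hits(kept_sets["B"], kept_sets["A"], evalue_cutoff=ortho_cut, scoring=scoring)
    pairs = orth_mod.reciprocal_best_hits(map_ab, map_ba)
    report.rbh_pairs = len(pairs)
    with open(outdir / "orthologs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tbits_ab\tbits_ba\tevalue_ab\tevalue_ba\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.bitscore_ab:.2f}\t{p.bitscore_ba:.2f}"
                f"\t{p.evalue_ab:.3e}\t{p.evalue_ba:.3e}\n"
            )

    # --- genotype calling, fixed differences, heterozygosity
    params = var_mod.CallerParams(
        **{k: v for k, v in config.variants.items() if k in var_mod.CallerParams.__dataclass_fields__}
    )
    calls = {key: var_mod.call_genotypes(tbl, params) for key, tbl in pileups.items()}
    table_ab = var_mod.fixed_differences(calls["A_on_B"])  # coordinates on B
    table_ba = var_mod.fixed_differences(calls["B_on_A"])  # coordinates on A (reference)
    report.fixed_snps_a_on_b = len(table_ab)
    report.fixed_snps_b_on_a = len(table_ba)
    posmaps = {
        p.gene_b: orth_mod.position_map(kept_sets["A"][p.gene_a], kept_sets["B"][p.gene_b], scoring)
        for p in pairs
    }
    consolidated = var_mod.consolidate_bidirectional(table_ab, table_ba, pairs, posmaps)
    report.fixed_snps_consolidated = len(consolidated)
    cio.write_variants_tsv(consolidated, outdir / "fixed_variants.tsv")
    cio.write_variants_vcf(consolidated, outdir / "fixed_variants.vcf")

    denom = config.variants.get("het_denominator", "callable")
    het_a = var_mod.heterozygosity(calls["A_on_A"], clone="A", denominator=denom)
    het_b = var_mod.heterozygosity(calls["B_on_B"], clone="B", denominator=denom)
    report.heterozygosity_a = het_a.H
    report.heterozygosity_b = het_b.H
    with open(outdir / "heterozygosity.tsv", "w") as fh:
        fh.write("clone\thet_sites\ttotal_sites\tH\n")
        for h in (het_a, het_b):
            fh.write(f"{h.clone}\t{h.het_sites}\t{h.total_sites}\t{h.H:.6g}\n")

    # --- ORFs, alternative CDS, Ka/Ks
    alpha = float(config.selection.get("alpha", 0.05))
    min_orf = int(config.selection.get("min_orf_codons", 100))
    by_gene = {g: t for g, t in consolidated.groupby("gene")} if len(consolidated) else {}
    records = []
    coding_snps = 0
    for p in pairs:
        seq_a = kept_sets["A"][p.gene_a]
        orfs = sel_mod.find_orfs(seq_a, gene=p.gene_a, min_len_codons=min_orf)
        if not orfs:
            continue
        orf = orfs[0]
        end = orf.end
        if end - orf.start >= 3 and sel_mod.is_stop(seq_a[end - 3:end]):
            end -= 3  # drop the terminal stop codon from the analysed CDS
        rows = by_gene.get(p.gene_a)
        if rows is None:
            continue
        in_cds = rows[(rows["pos"] >= orf.start) & (rows["pos"] < end)]
        # guard against noise-called rows whose allele disagrees with the reference
        variant_rows = [
            (int(r["pos"]), r["allele_a"], r["allele_b"])
            for _, r in in_cds.iterrows()
            if seq_a[int(r["pos"])] == r["allele_a"]
        ]
        if len(variant_rows) < len(in_cds):
            logger.warning(
                "%s: dropped %d variant rows with mismatching reference allele",
                p.gene_a, len(in_cds) - len(variant_rows),
            )
        if not variant_rows:
            continue
        cds = seq_a[orf.start:end]
        alt_cds = sel_mod.apply_fixed_variants(cds, variant_rows, cds_start=orf.start)
        coding_snps += len(variant_rows)
        records.append(sel_mod.kaks_estimate(cds, alt_cds, gene=p.gene_a, alpha=alpha))
    cio.write_kaks_tsv(records, outdir / "kaks.tsv")
    summary = sel_mod.classify_selection(records, alpha=alpha)
    report.genes_with_orf_and_coding_snps = len(records)
    report.coding_fixed_snps = coding_snps
    report.synonymous_substitutions = round(sum(r.Ns for r in records), 6)
    report.nonsynonymous_substitutions = round(sum(r.Nn for r in records), 6)
    report.positive_genes = summary["positive"]
    report.purifying_genes = summary["purifying"]
    report.unclassified_genes = summary["unclassified"]
    report.check_accounting()

    # --- pathway enrichment of the positive set against SNP-carrying genes
    background = set(consolidated["gene"]) if len(consolidated) else set()
    selected = {r.gene for r in records if r.selection_class == "positive"} & background
    if background:
        enr = enrich_mod.pathway_enrichment(
            selected, background, annotations, alpha=float(config.enrich.get("alpha", 0.05))
        )
        report.enriched_pathways = sum(r.enriched for r in enr)
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("pathway\tk\tK\tn\tN\tp\tenriched\n")
            for r in enr:
                fh.write(f"{r.pathway}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t{r.enriched}\n")

    # --- differential expression
    result = de_mod.fit_ppde(
        counts,
        conditions,
        ppde_threshold=float(config.de.get("ppde_threshold", 1.0 - 1e-5)),
        fdr_cap=float(config.de.get("fdr_cap", 0.05)),
    )
    report.de_genes = len(result.selected)
    result.as_frame().to_csv(outdir / "de_results.tsv", sep="\t")

    (outdir / "report.json").write_text(json.dumps(asdict(report), indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report
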