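"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; pileups, counts, decisions and per-gene results as
TSV; fixed variants additionally as minimal VCF 4.2; pathway annotations
as GMT. Positions are 0-based half-open in memory and 1-based in pileup
TSV and VCF on disk.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import PILEUP_COLUMNS

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pileup",
    "write_pileup",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_variants_tsv",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df["pos"] = df["pos"].astype(int) - 1  # 1-based on disk
    return df[PILEUP_COLUMNS]


def write_pileup(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        out[fields[0]] = set(fields[2:])
    return out


def write_gmt(annotations: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for pathway in sorted(annotations):
            genes = "\t".join(sorted(annotations[pathway]))
            fh.write(f"{pathway}\t{description}\t{genes}\n")


def read_gene_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_variants_vcf(table: pd.DataFrame, path, reference_name: str = "cloneA") -> None:
    """Fixed-variant table (gene, pos, allele_a, allele_b[, directions]) as VCF 4.2.

    CHROM is the reference-clone gene id; REF the reference clone's allele.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=clonescan\n##reference={reference_name}\n")
        fh.write('##INFO=<ID=DIR,Number=1,Type=String,Description="Directions observed">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in table.iterrows():
            info = f"DIR={r['directions']}" if "directions" in table.columns else "."
            fh.write(
                f"{r['gene']}\t{int(r['pos']) + 1}\t.\t{r['allele_a']}\t{r['allele_b']}\t.\tPASS\t{info}\n"
            )


def read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _id, ref, alt, _q, _f, info = line.split("\t")[:8]
        directions = "."
        for kv in info.split(";"):
            if kv.startswith("DIR="):
                directions = kv[4:]
        rows.append(
            {"gene": chrom, "pos": int(pos) - 1, "allele_a": ref, "allele_b": alt, "directions": directions}
        )
    return pd.DataFrame(rows, columns=["gene", "pos", "allele_a", "allele_b", "directions"])


def write_variants_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def write_kaks_tsv(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene,
                "S": r.S,
                "N": r.N,
                "Ns": r.Ns,
                "Nn": r.Nn,
                "Ka": r.Ka,
                "Ks": r.Ks,
                "ratio": r.ratio if not math.isnan(r.ratio) else "NA",
                "fisher_p": r.fisher_p,
                "class": r.selection_class,
                "flags": ",".join(r.flags) if r.flags else ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
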