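"""Standard genetic code tables shared by the simulator and the Ka/Ks stage."""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    """Amino acid for a codon ('*' for stop); KeyError on ambiguous codons."""
    return CODON_TO_AA[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
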