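"""Genetic-code helpers built on Biopython's NCBI translation tables.

All coding-sequence analyses in this package default to the invertebrate
mitochondrial code (NCBI table 5), in which TGA encodes Trp, ATA encodes
Met, AGA/AGG encode Ser, and only TAA/TAG terminate translation.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

INVERTEBRATE_MITO = 5

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes accepted)."""
    return str(Seq(seq).reverse_complement())


@lru_cache(maxsize=None)
def codon_table(code: int = INVERTEBRATE_MITO) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code]


@lru_cache(maxsize=None)
def stop_codons(code: int = INVERTEBRATE_MITO) -> frozenset[str]:
    return frozenset(codon_table(code).stop_codons)


@lru_cache(maxsize=None)
def sense_codons(code: int = INVERTEBRATE_MITO) -> tuple[str, ...]:
    """All non-stop codons of the code, lexicographically ordered."""
    table = codon_table(code)
    return tuple(sorted(table.forward_table))


def translate_codon(codon: str, code: int = INVERTEBRATE_MITO) -> str:
    """One-letter amino acid for a codon, ``*`` for a stop codon."""
    codon = codon.upper()
    if codon in stop_codons(code):
        return "*"
    return codon_table(code).forward_table[codon]


@lru_cache(maxsize=None)
def synonymous_families(code: int = INVERTEBRATE_MITO) -> dict[str, tuple[str, ...]]:
    """Map amino acid -> sorted tuple of codons encoding it (stops excluded)."""
    fams: dict[str, list[str]] = {}
    for codon, aa in codon_table(code).forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


@lru_cache(maxsize=None)
def family_size(code: int = INVERTEBRATE_MITO) -> dict[str, int]:
    """Map codon -> size of its synonymous family."""
    out: dict[str, int] = {}
    for cods in synonymous_families(code).values():
        for c in cods:
            out[c] = len(cods)
    return out


@lru_cache(maxsize=None)
def fourfold_codons(code: int = INVERTEBRATE_MITO) -> frozenset[str]:
    """Codons whose third position is fully degenerate under the code."""
    table = codon_table(code).forward_table
    out = set()
    for c in table:
        stem = c[:2]
        aas = {table.get(stem + b) for b in BASES}
        if len(aas) == 1 and None not in aas:
            out.add(c)
    return frozenset(out)


def anticodon_for(aa: str, code: int = INVERTEBRATE_MITO) -> str:
    """A representative anticodon (DNA alphabet) for an amino acid."""
    cods = synonymous_families(code)[aa]
    return revcomp(cods[0])


def anticodon_decodes(anticodon: str, code: int = INVERTEBRATE_MITO) -> str:
    """Amino acid read by an anticodon (taken as the reverse complement codon)."""
    return translate_codon(revcomp(anticodon), code)
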