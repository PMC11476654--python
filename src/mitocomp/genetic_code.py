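"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

All codon-level analyses in this package (codon usage, RSCU, CDspT,
Nei-Gojobori site/difference counting) operate under this code, in which
AGA/AGG are stop codons, TGA encodes tryptophan and ATA encodes methionine.
The code structure is taken from Biopython's codon tables rather than being
hard-coded, so switching tables only requires a different table id.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

VERTEBRATE_MITO_TABLE_ID = 2

BASES = "ACGT"


@lru_cache(maxsize=None)
def _table(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def stop_codons(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> frozenset[str]:
    return frozenset(_table(table_id).stop_codons)


@lru_cache(maxsize=None)
def sense_codons(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> tuple[str, ...]:
    """The 60 sense codons of the vertebrate mito code, lexicographic order."""
    stops = stop_codons(table_id)
    return tuple(
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in stops
    )


def translate(codon: str, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    codon = codon.upper().replace("U", "T")
    if codon in stop_codons(table_id):
        return "*"
    return _table(table_id).forward_table[codon]


def is_stop(codon: str, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> bool:
    return codon.upper().replace("U", "T") in stop_codons(table_id)


@lru_cache(maxsize=None)
def synonymous_families(
    table_id: int = VERTEBRATE_MITO_TABLE_ID,
) -> dict[str, tuple[str, ...]]:
    """Map amino acid -> tuple of its sense codons (the synonymous family).

    Under table 2 the Leu and Ser families have 6 members while Met (ATA/ATG)
    and Trp (TGA/TGG) are two-codon families.
    """
    fams: dict[str, list[str]] = {}
    for codon in sense_codons(table_id):
        fams.setdefault(translate(codon, table_id), []).append(codon)
    return {aa: tuple(cods) for aa, cods in fams.items()}


@lru_cache(maxsize=None)
def family_of(codon: str, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> tuple[str, ...]:
    return synonymous_families(table_id)[translate(codon, table_id)]
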