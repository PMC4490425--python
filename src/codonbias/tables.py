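"""Genetic-code lookup tables shared across the package.

Everything here derives from the standard genetic code (NCBI table 1) as
shipped with Biopython; the module only reshapes it into the family
structures the codon-usage statistics need.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = ("A", "C", "G", "T")

#: codon -> one-letter amino acid, with '*' for the three stop codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if CODON_TO_AA[c] != "*"
)

#: amino acid (or '*') -> sorted tuple of codons encoding it.
FAMILY: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    FAMILY.setdefault(CODON_TO_AA[_codon], ())
FAMILY = {
    aa: tuple(sorted(c for c in ALL_CODONS if CODON_TO_AA[c] == aa))
    for aa in FAMILY
}

#: degeneracy S_i of each family (stop family included under '*').
DEGENERACY: dict[str, int] = {aa: len(codons) for aa, codons in FAMILY.items()}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(a for a in FAMILY if a != "*"))

#: amino acids with more than one synonymous codon (Met and Trp excluded).
DEGENERATE_AMINO_ACIDS: tuple[str, ...] = tuple(
    a for a in AMINO_ACIDS if DEGENERACY[a] > 1
)

#: the 59 sense codons belonging to degenerate families.
DEGENERATE_SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

#: index maps for vectorised counting.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

START_CODON = "ATG"


def to_rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet (T -> U) for reports."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")
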