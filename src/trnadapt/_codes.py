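"""Genetic-code tables shared across the package.

Canonical internal alphabet is DNA (T); U is accepted on input everywhere
and converted. All tables derive from the standard nuclear genetic code.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: 61 sense codons, lexicographically sorted (DNA alphabet).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

#: The three stop codons.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: codon -> 1-letter amino acid.
AA_OF_CODON: dict[str, str] = dict(_STANDARD.forward_table)

#: 1-letter -> 3-letter amino-acid code (gtRNAdb naming style).
AA1_TO_AA3: dict[str, str] = {aa: seq3(aa) for aa in set(AA_OF_CODON.values())}
AA3_TO_AA1: dict[str, str] = {v: k for k, v in AA1_TO_AA3.items()}

#: 3-letter amino acid -> sorted tuple of synonymous sense codons.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa3 = AA1_TO_AA3[AA_OF_CODON[_codon]]
    SYNONYMOUS_FAMILIES.setdefault(_aa3, ())
    SYNONYMOUS_FAMILIES[_aa3] += (_codon,)

#: codon -> 3-letter amino acid.
AA3_OF_CODON: dict[str, str] = {
    c: AA1_TO_AA3[AA_OF_CODON[c]] for c in SENSE_CODONS
}

#: Single-codon families (no within-family synonymous variance).
SINGLE_CODON_FAMILIES: frozenset[str] = frozenset(
    aa for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) == 1
)  # {'Met', 'Trp'} -> codons ATG, TGG

#: Codons dropped by amino-acid normalization (members of 1-codon families).
SINGLE_FAMILY_CODONS: frozenset[str] = frozenset(
    SYNONYMOUS_FAMILIES[aa][0] for aa in SINGLE_CODON_FAMILIES
)

#: 59 codons retained by amino-acid normalization.
AA_NORMALIZED_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in SINGLE_FAMILY_CODONS
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def to_dna(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def wc_anticodon(codon: str) -> str:
    """Watson-Crick anticodon of a codon (its reverse complement, DNA)."""
    return reverse_complement(codon)


def is_sense_codon(codon: str) -> bool:
    return to_dna(codon) in AA_OF_CODON
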