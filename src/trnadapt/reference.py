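"""Mature-tRNA reference construction and codon-anticodon pairing rules.

Builds the isodecoder reference used for tRNA-seq quantification: tRNA genes
with byte-identical mature sequences are collapsed into isodecoder groups
(CCA-appended), isodecoders sharing an anticodon form isoacceptor groups, and
a configurable wobble rule set maps each sense codon to its cognate decoding
anticodons with dos Reis-style binding penalties.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from ._codes import (
    AA3_OF_CODON,
    STOP_CODONS,
    is_sense_codon,
    to_dna,
    wc_anticodon,
)

__all__ = [
    "TRNAGene",
    "IsodecoderGroup",
    "IsoacceptorGroup",
    "WobbleRule",
    "WobbleRuleSet",
    "parse_trna_fasta",
    "build_isodecoder_reference",
    "build_isoacceptor_map",
    "cognate_trnas",
    "write_reference_fasta",
]

# gtRNAdb-style gene name, e.g. tRNA-Ser-TGA-1-1 (RNA letters accepted).
_NAME_RE = re.compile(
    r"tRNA-(?P<aa>[A-Za-z]{3}|iMet|SeC|Und)-(?P<ac>[ACGTUacgtu]{3})"
    r"(?:-(?P<i>\d+)-(?P<j>\d+))?"
)
_MITO_RE = re.compile(r"\bmito|\bMT-|chrM|mitochond", re.IGNORECASE)

#: Labels that are parsed but excluded from isoacceptor maps and metrics.
NON_STANDARD_AA = {"SeC", "Und"}


@dataclass(frozen=True)
class TRNAGene:
    """One tRNA gene: gtRNAdb-style id, decoded amino acid, anticodon and
    mature (CCA-less) sequence."""

    gene_id: str
    amino_acid: str
    anticodon: str  # DNA alphabet
    mature_sequence: str  # DNA alphabet, no CCA
    origin: str = "nuclear"  # nuclear | mitochondrial

    def __post_init__(self) -> None:
        if not self.mature_sequence:
            raise ValueError(f"{self.gene_id}: empty mature sequence")
        if set(self.mature_sequence) - set("ACGT"):
            raise ValueError(f"{self.gene_id}: non-ACGT characters in sequence")
        m = _NAME_RE.search(self.gene_id)
        if m and to_dna(m.group("ac")) != self.anticodon:
            raise ValueError(
                f"{self.gene_id}: anticodon field {self.anticodon} does not "
                f"match the gene name"
            )


@dataclass(frozen=True)
class IsodecoderGroup:
    """Distinguishable mature tRNA: one or more genes with identical mature
    sequence, collapsed; reference sequence carries the 3' CCA."""

    group_id: str
    member_gene_ids: tuple[str, ...]
    reference_sequence: str  # mature + CCA
    anticodon: str
    amino_acid: str
    origin: str = "nuclear"

    @property
    def copy_number(self) -> int:
        return len(self.member_gene_ids)

    def __post_init__(self) -> None:
        if not self.reference_sequence.endswith("CCA"):
            raise ValueError(f"{self.group_id}: reference must end in CCA")
        if not self.member_gene_ids:
            raise ValueError(f"{self.group_id}: no members")


@dataclass(frozen=True)
class IsoacceptorGroup:
    """All isodecoders sharing one (amino acid, anticodon)."""

    anticodon: str
    amino_acid: str
    isodecoder_group_ids: tuple[str, ...]

    @property
    def key(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"


@dataclass(frozen=True)
class WobbleRule:
    codon_third_base: str
    anticodon_first_base: str
    pairing_label: str
    s_penalty: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_penalty <= 1.0:
            raise ValueError(f"s penalty {self.s_penalty} outside [0,1]")


@dataclass(frozen=True)
class WobbleRuleSet:
    """Codon:anticodon pairing rules with binding penalties s in [0,1].

    The default is the dos Reis et al. eukaryotic table: Watson-Crick pairs
    have s = 0; wobble pairs are G34:U3 (s=0.41), I34:C3 (s=0.28, anticodon A
    read as inosine), I34:A3 (s=0.9999) and U34:G3 (s=0.68). The bacterial
    lysidine rule (C34 reading AUA, s=0.89) is carried but disabled by
    default. ATG is restricted to its Watson-Crick anticodon because
    elongator Met is decoded only by CAT; set ``met_wc_only=False`` to apply
    the mechanical U34:G3 rule there too.
    """

    rules: tuple[WobbleRule, ...] = (
        WobbleRule("T", "A", "WC", 0.0),
        WobbleRule("T", "G", "G:U", 0.41),
        WobbleRule("C", "G", "WC", 0.0),
        WobbleRule("C", "A", "I:C", 0.28),
        WobbleRule("A", "T", "WC", 0.0),
        WobbleRule("A", "A", "I:A", 0.9999),
        WobbleRule("G", "C", "WC", 0.0),
        WobbleRule("G", "T", "U:G", 0.68),
    )
    lysidine_enabled: bool = False
    lysidine_s: float = 0.89
    met_wc_only: bool = True

    def __post_init__(self) -> None:
        for r in self.rules:
            if r.pairing_label == "WC" and r.s_penalty != 0.0:
                raise ValueError("Watson-Crick pairings must have s = 0")

    def pairings(self, codon: str) -> list[tuple[str, str, float]]:
        """(anticodon, label, s) for every anticodon that can read `codon`."""
        codon = to_dna(codon)
        wc = wc_anticodon(codon)
        out: list[tuple[str, str, float]] = []
        for r in self.rules:
            if r.codon_third_base != codon[2]:
                continue
            if (
                self.met_wc_only
                and codon == "ATG"
                and r.pairing_label != "WC"
            ):
                continue
            anticodon = r.anticodon_first_base + wc[1:]
            out.append((anticodon, r.pairing_label, r.s_penalty))
        if self.lysidine_enabled and codon == "ATA":
            out.append(("CAT", "L:A", self.lysidine_s))
        return out


def parse_trna_fasta(
    fasta_path: str | Path,
) -> tuple[list[TRNAGene], list[str]]:
    """Parse a gtRNAdb-style tRNA gene FASTA.

    Returns (genes, failures) where failures lists the headers that carried
    no parsable amino-acid/anticodon name. Raises ``ValueError`` on an empty
    file. Records whose header carries a mitochondrial tag are flagged
    ``origin='mitochondrial'``; SeC and pseudogene (Und) records are kept
    with their labels and filtered downstream.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: empty FASTA, no tRNA records")
    genes: list[TRNAGene] = []
    failures: list[str] = []
    for rec in records:
        header = rec.description
        m = _NAME_RE.search(header)
        if m is None:
            failures.append(header)
            continue
        origin = "mitochondrial" if _MITO_RE.search(header) else "nuclear"
        name = m.group(0)
        genes.append(
            TRNAGene(
                gene_id=name,
                amino_acid=m.group("aa"),
                anticodon=to_dna(m.group("ac")),
                mature_sequence=to_dna(str(rec.seq)),
                origin=origin,
            )
        )
    return genes, failures


def _family_prefix(gene_id: str) -> str:
    """tRNA-Ser-TGA-1-1 -> tRNA-Ser-TGA."""
    m = _NAME_RE.search(gene_id)
    if m is None:  # pragma: no cover - genes always carry parsable ids
        return gene_id
    return f"tRNA-{m.group('aa')}-{m.group('ac')}"


def build_isodecoder_reference(
    genes: Sequence[TRNAGene],
) -> list[IsodecoderGroup]:
    """Collapse genes with identical mature sequences into isodecoder groups
    and append the 3' CCA to each collapsed reference sequence.

    Single-member groups keep the gene id; merged groups are named
    ``<family>-X`` (``-X1``, ``-X2``, ... ordered by sequence when one family
    yields several merged groups). Genes identical in sequence but annotated
    with different anticodons raise ``ValueError``.
    """
    if not genes:
        raise ValueError("no tRNA genes to collapse")
    by_seq: dict[str, list[TRNAGene]] = defaultdict(list)
    for g in genes:
        by_seq[g.mature_sequence].append(g)

    # name collisions: count merged groups per family first
    merged_by_family: dict[str, list[str]] = defaultdict(list)
    for seq in sorted(by_seq):
        members = by_seq[seq]
        anticodons = {g.anticodon for g in members}
        if len(anticodons) > 1:
            ids = ", ".join(g.gene_id for g in members)
            raise ValueError(
                f"inconsistent annotation: identical mature sequence with "
                f"differing anticodons ({ids})"
            )
        if len(members) > 1:
            merged_by_family[_family_prefix(members[0].gene_id)].append(seq)

    groups: list[IsodecoderGroup] = []
    for seq in sorted(by_seq):
        members = sorted(by_seq[seq], key=lambda g: g.gene_id)
        first = members[0]
        if len(members) == 1:
            group_id = first.gene_id
        else:
            fam = _family_prefix(first.gene_id)
            siblings = merged_by_family[fam]
            if len(siblings) == 1:
                group_id = f"{fam}-X"
            else:
                group_id = f"{fam}-X{siblings.index(seq) + 1}"
        origins = {g.origin for g in members}
        groups.append(
            IsodecoderGroup(
                group_id=group_id,
                member_gene_ids=tuple(g.gene_id for g in members),
                reference_sequence=seq + "CCA",
                anticodon=first.anticodon,
                amino_acid=first.amino_acid,
                origin="mitochondrial" if origins == {"mitochondrial"} else "nuclear",
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def build_isoacceptor_map(
    isodecoders: Sequence[IsodecoderGroup],
    include_mitochondrial: bool = False,
    include_non_standard: bool = False,
) -> list[IsoacceptorGroup]:
    """Partition isodecoder groups by (amino acid, anticodon).

    By default restricts to cytosolic tRNAs of the standard amino acids
    (plus iMet, which stays a separate group from elongator Met): SeC and
    pseudogene records, and mitochondrial tRNAs, are excluded unless asked
    for.
    """
    keyed: dict[tuple[str, str], list[str]] = defaultdict(list)
    for iso in isodecoders:
        if not include_mitochondrial and iso.origin == "mitochondrial":
            continue
        if not include_non_standard and iso.amino_acid in NON_STANDARD_AA:
            continue
        keyed[(iso.amino_acid, iso.anticodon)].append(iso.group_id)
    return [
        IsoacceptorGroup(
            anticodon=ac,
            amino_acid=aa,
            isodecoder_group_ids=tuple(sorted(ids)),
        )
        for (aa, ac), ids in sorted(keyed.items())
    ]


def cognate_trnas(
    codon: str,
    isoacceptor_abundances: Mapping[str, float],
    rules: WobbleRuleSet | None = None,
) -> list[tuple[str, float, float]]:
    """Cognate decoding anticodons of a sense codon.

    Returns ``[(anticodon, s_penalty, abundance), ...]`` covering the
    Watson-Crick anticodon and every wobble-readable anticodon under the
    rule set; abundance is 0 for anticodons absent from the supplied pool.
    Abundance keys are anticodons in the DNA alphabet (U accepted).
    """
    codon = to_dna(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon, not decodable")
    if not is_sense_codon(codon):
        raise ValueError(f"{codon} is not a valid sense codon")
    if rules is None:
        rules = WobbleRuleSet()
    pool = {to_dna(k): float(v) for k, v in isoacceptor_abundances.items()}
    for v in pool.values():
        if v < 0:
            raise ValueError("negative tRNA abundance")
    out = []
    for anticodon, _label, s in rules.pairings(codon):
        out.append((anticodon, s, pool.get(anticodon, 0.0)))
    return out


def write_reference_fasta(
    groups: Iterable[IsodecoderGroup], path: str | Path
) -> None:
    """Write the CCA-appended isodecoder reference sequences."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write(f">{g.group_id} copy_number={g.copy_number}\n")
            fh.write(g.reference_sequence + "\n")


def codon_of_anticodon(anticodon: str) -> str | None:
    """Sense codon Watson-Crick decoded by an anticodon, or None."""
    codon = wc_anticodon(anticodon)  # revcomp is an involution
    return codon if is_sense_codon(codon) else None


def expected_amino_acid(anticodon: str) -> str | None:
    """3-letter amino acid the anticodon's WC codon encodes, or None."""
    codon = codon_of_anticodon(anticodon)
    return AA3_OF_CODON[codon] if codon else None
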