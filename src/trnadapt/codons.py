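"""Codon counting and length- / amino-acid-normalized frequency matrices.

Every downstream metric (CSC, tAI_gene, CAI, SDR, codon-usage PCA) consumes
the per-gene codon counts produced here. Frequencies are over the 61 sense
codons; amino-acid-normalized frequencies re-express usage within each
synonymous family (59 dimensions after dropping the single-codon families
ATG and TGG), removing amino-acid composition and gene length as confounds.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codes import (
    AA_NORMALIZED_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    to_dna,
)

logger = logging.getLogger(__name__)

__all__ = [
    "count_codons",
    "read_cds_fasta",
    "codon_count_matrix",
    "normalized_frequencies",
    "aa_normalized_frequencies",
    "rank_by_content",
]


def count_codons(
    sequence: str, gene_id: str = "?", internal_stop: str = "strict"
) -> pd.Series:
    """Count sense codons in a CDS.

    A single terminal stop codon is stripped and not counted. The CDS length
    must be divisible by 3. Internal stops are an error under
    ``internal_stop='strict'`` (the default; half-life/CDS tables should be
    clean) or truncate the CDS there under ``'lenient'`` (logged). Codons
    containing an ambiguous base are skipped and logged. Returns a 61-long
    integer Series over the sense codons; its sum is L.
    """
    seq = to_dna(sequence)
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for pos, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if internal_stop == "strict":
                raise ValueError(
                    f"{gene_id}: internal stop codon {codon} at codon {pos}"
                )
            logger.warning("%s: truncated at internal stop (codon %d)", gene_id, pos)
            break
        if codon not in counts:
            logger.warning("%s: skipped ambiguous codon %r at %d", gene_id, codon, pos)
            continue
        counts[codon] += 1
    return pd.Series(counts, dtype=int)


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """One representative CDS per gene; record id is the gene id."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: empty CDS FASTA")
    return seqs


def codon_count_matrix(
    cds: Mapping[str, str], internal_stop: str = "strict"
) -> pd.DataFrame:
    """genes x 61 codon-count matrix from a gene -> CDS mapping."""
    rows = {
        gene: count_codons(seq, gene_id=gene, internal_stop=internal_stop)
        for gene, seq in cds.items()
    }
    return pd.DataFrame(rows).T[list(SENSE_CODONS)]


def normalized_frequencies(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """freq_i = count_i / L per gene; rows sum to 1."""
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total == 0:
            raise ValueError("CDS has no sense codons (L = 0)")
        return counts / total
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"genes with no sense codons: {empty}")
    return counts.div(totals, axis=0)


def aa_normalized_frequencies(
    counts: pd.DataFrame, unoccupied: str = "zero"
) -> pd.DataFrame:
    """Within-synonymous-family codon proportions (59 columns).

    For each gene and each multi-codon amino-acid family with at least one
    occurrence, value = codon count / family count, so occupied families sum
    to 1. Families absent from a gene yield 0 for all members under
    ``unoccupied='zero'`` (the default; PCA centering absorbs the offset) or
    the uniform 1/k under ``'uniform'``. Single-codon families (ATG, TGG)
    are dropped.
    """
    if unoccupied not in {"zero", "uniform"}:
        raise ValueError("unoccupied must be 'zero' or 'uniform'")
    out = pd.DataFrame(
        0.0, index=counts.index, columns=list(AA_NORMALIZED_CODONS)
    )
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if len(family) == 1:
            continue
        cols = list(family)
        block = counts[cols].astype(float)
        totals = block.sum(axis=1)
        occupied = totals > 0
        out.loc[occupied, cols] = block.loc[occupied].div(
            totals[occupied], axis=0
        )
        if unoccupied == "uniform":
            out.loc[~occupied, cols] = 1.0 / len(cols)
    return out


def rank_by_content(
    freqs: pd.DataFrame,
    codon_set: Iterable[str],
    top_fraction: float | None = None,
    min_percent: float | None = None,
) -> pd.Index:
    """Select genes by their summed frequency over a codon set.

    Exactly one of ``top_fraction`` (top fraction of genes by content, ties
    broken by gene id) or ``min_percent`` (all genes with content >=
    min_percent/100, boundary inclusive) must be given.
    """
    codon_set = [to_dna(c) for c in codon_set]
    if not codon_set:
        raise ValueError("empty codon set")
    unknown = sorted(set(codon_set) - set(SENSE_CODONS))
    if unknown:
        raise ValueError(f"not sense codons: {unknown}")
    if (top_fraction is None) == (min_percent is None):
        raise ValueError("give exactly one of top_fraction or min_percent")
    content = freqs[codon_set].sum(axis=1)
    if min_percent is not None:
        if min_percent < 0:
            raise ValueError("min_percent must be >= 0")
        return content.index[content >= min_percent / 100.0]
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    order = content.to_frame("content")
    order["gene"] = order.index
    order = order.sort_values(["content", "gene"], ascending=[False, True])
    n_top = max(1, int(np.floor(len(order) * top_fraction)))
    return pd.Index(order.index[:n_top])
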