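"""Synthetic data generators with planted ground truth.

The generators emit exactly the inputs the pipeline consumes — a
gtRNAdb-style tRNA gene FASTA, replicate tRNA-seq count tables, a CDS
FASTA, half-life and expression tables — with the statistical structure
the analysis assumes: negative-binomial replicate noise around planted
isodecoder fold changes, Dirichlet synonymous-codon preference profiles at
fixed amino-acid composition, and half-lives from a planted linear
codon-frequency model. Every generator is a pure function of its
parameters and seed, and records its ground truth for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import (
    AA3_OF_CODON,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    wc_anticodon,
)
from .codons import normalized_frequencies
from .reference import TRNAGene

__all__ = [
    "SyntheticTruth",
    "gen_trna_set",
    "gen_counts",
    "gen_transcriptome",
    "gen_halflives",
    "gen_expression",
    "gen_condition_pools",
    "scenario",
    "Scenario",
]

# amino-acid composition (3-letter -> weight), loosely typical of animal
# proteomes; held fixed across profiles so only synonymous usage varies
_AA_WEIGHTS = {
    "Ala": 7.0, "Arg": 5.5, "Asn": 4.0, "Asp": 5.0, "Cys": 2.0,
    "Gln": 4.5, "Glu": 6.5, "Gly": 6.5, "His": 2.5, "Ile": 5.0,
    "Leu": 9.5, "Lys": 6.0, "Met": 2.5, "Phe": 4.0, "Pro": 5.0,
    "Ser": 7.5, "Thr": 5.5, "Trp": 1.5, "Tyr": 3.0, "Val": 6.5,
}


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator run."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_lfc: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    gene_profiles: dict[str, int] = field(default_factory=dict)
    condition_pools: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.planted_lfc.items():
            rows.append(("planted_lfc", k, v))
        for k, v in self.beta.items():
            rows.append(("beta", k, v))
        for k, v in self.gene_profiles.items():
            rows.append(("gene_profile", k, v))
        return pd.DataFrame(rows, columns=["kind", "key", "value"])


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_trna_set(
    n_families: int,
    isodecoders_per_family: int = 2,
    n_duplicated: int = 1,
    seq_length: int = 72,
    seed: int = 0,
) -> tuple[list[TRNAGene], SyntheticTruth]:
    """Synthetic gtRNAdb-style tRNA gene set.

    Picks ``n_families`` anticodons (each decoding a distinct sense codon
    by Watson-Crick pairing) and gives each ``isodecoders_per_family``
    genes. In the first ``n_duplicated`` families the first two genes share
    one mature sequence (two indistinguishable gene copies, named
    ``-1-1``/``-1-2`` in the gtRNAdb style) to exercise isodecoder
    collapsing; total genes = n_families x isodecoders_per_family.
    """
    if n_families < 1 or n_families > len(SENSE_CODONS):
        raise ValueError(f"n_families must be in [1, {len(SENSE_CODONS)}]")
    if n_duplicated > n_families:
        raise ValueError("cannot duplicate more families than exist")
    if n_duplicated > 0 and isodecoders_per_family < 2:
        raise ValueError("duplication needs >= 2 isodecoders per family")
    rng = _rng(seed)
    # cover every amino-acid family first (so downstream tAI always has
    # decoding capacity), then draw extra anticodons at random
    chosen: list[str] = []
    for aa in sorted(SYNONYMOUS_FAMILIES):
        if len(chosen) >= n_families:
            break
        fam = SYNONYMOUS_FAMILIES[aa]
        chosen.append(fam[int(rng.integers(len(fam)))])
    leftover = sorted(set(SENSE_CODONS) - set(chosen))
    n_extra = n_families - len(chosen)
    if n_extra > 0:
        extra = rng.choice(len(leftover), n_extra, replace=False)
        chosen += [leftover[i] for i in sorted(extra)]
    chosen = chosen[:n_families]
    genes: list[TRNAGene] = []
    seen: set[str] = set()
    for fam_i, codon in enumerate(chosen):
        anticodon = wc_anticodon(codon)
        aa = AA3_OF_CODON[codon]
        duplicated = fam_i < n_duplicated
        n_distinct = (
            isodecoders_per_family - 1 if duplicated else isodecoders_per_family
        )
        sequences = []
        for _ in range(n_distinct):
            while True:
                seq = "".join(rng.choice(list("ACGT"), seq_length))
                if seq not in seen:
                    seen.add(seq)
                    break
            sequences.append(seq)
        if duplicated:
            sequences = [sequences[0]] + sequences
        iso_num, copy_num = 0, 0
        prev_seq = None
        for seq in sequences:
            if seq == prev_seq:
                copy_num += 1
            else:
                iso_num += 1
                copy_num = 1
            prev_seq = seq
            genes.append(
                TRNAGene(
                    gene_id=f"tRNA-{aa}-{anticodon}-{iso_num}-{copy_num}",
                    amino_acid=aa,
                    anticodon=anticodon,
                    mature_sequence=seq,
                )
            )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_families": n_families,
            "isodecoders_per_family": isodecoders_per_family,
            "n_duplicated": n_duplicated,
            "seq_length": seq_length,
        },
    )
    return genes, truth


def write_trna_fasta(genes: Sequence[TRNAGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.mature_sequence}\n")


def gen_counts(
    feature_ids: Sequence[str],
    planted_lfc: Mapping[str, float] | None = None,
    dispersion: float = 0.05,
    depth: float = 1e6,
    n_reps: int = 3,
    conditions: tuple[str, str] = ("neuroblast", "neuron"),
    lib_jitter: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Replicate tRNA-seq count tables with planted differential features.

    Baseline means are log-uniform over ~3 orders of magnitude and scaled
    to the target depth; condition-B means are baseline x 2**planted_lfc;
    counts are negative-binomial (variance m + dispersion * m**2; Poisson at
    dispersion 0) with per-sample library sizes jittered by ±lib_jitter.

    Returns (counts, sample_conditions, truth).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed)
    planted_lfc = dict(planted_lfc or {})
    unknown = sorted(set(planted_lfc) - set(feature_ids))
    if unknown:
        raise ValueError(f"planted lfc on unknown features: {unknown}")
    n = len(feature_ids)
    base = 10 ** rng.uniform(0, 3, n)
    base = base / base.sum() * depth
    means = {conditions[0]: base.copy(), conditions[1]: base.copy()}
    lfc_vec = np.array([planted_lfc.get(f, 0.0) for f in feature_ids])
    means[conditions[1]] = base * 2.0**lfc_vec

    cols = {}
    sample_conditions = {}
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            sid = f"{cond}_{rep}"
            sample_conditions[sid] = cond
            jitter = rng.uniform(1 - lib_jitter, 1 + lib_jitter)
            m = means[cond] * jitter
            if dispersion == 0:
                cols[sid] = rng.poisson(m)
            else:
                size = 1.0 / dispersion
                p = size / (size + m)
                cols[sid] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=list(feature_ids))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "dispersion": dispersion,
            "depth": depth,
            "n_reps": n_reps,
            "lib_jitter": lib_jitter,
        },
        planted_lfc=planted_lfc,
    )
    return counts, pd.Series(sample_conditions), truth


def _profile_preferences(
    n_profiles: int, divergence: float, rng: np.random.Generator
) -> list[dict[str, np.ndarray]]:
    """Per-profile synonymous-codon preference vectors per family.

    Each profile's family preference interpolates between a shared Dirichlet
    base draw and a profile-specific Dirichlet draw; ``divergence`` in [0,1]
    controls the separation between profiles.
    """
    base = {
        aa: rng.dirichlet(np.ones(len(fam)))
        for aa, fam in SYNONYMOUS_FAMILIES.items()
    }
    profiles = []
    for _ in range(n_profiles):
        own = {
            aa: rng.dirichlet(np.full(len(fam), 0.5))
            for aa, fam in SYNONYMOUS_FAMILIES.items()
        }
        pref = {
            aa: (1 - divergence) * base[aa] + divergence * own[aa]
            for aa in SYNONYMOUS_FAMILIES
        }
        profiles.append(pref)
    return profiles


def gen_transcriptome(
    n_genes: int,
    n_profiles: int = 2,
    profile_divergence: float = 0.9,
    length_range: tuple[int, int] = (150, 450),
    profile_fractions: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """CDS set drawn from distinct synonymous codon-usage profiles.

    Amino-acid composition is fixed across profiles; genes are sampled
    codon-by-codon from their profile's within-family preferences, with
    lengths (in codons) uniform over ``length_range`` and a terminal TAA.
    Returns (gene -> CDS, truth with profile labels and preferences).
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    if not 0 <= profile_divergence <= 1:
        raise ValueError("profile_divergence must be in [0, 1]")
    rng = _rng(seed)
    prefs = _profile_preferences(n_profiles, profile_divergence, rng)
    if profile_fractions is None:
        profile_fractions = [1.0 / n_profiles] * n_profiles
    fractions = np.asarray(profile_fractions, dtype=float)
    fractions = fractions / fractions.sum()
    aa_names = list(_AA_WEIGHTS)
    aa_p = np.array([_AA_WEIGHTS[a] for a in aa_names])
    aa_p = aa_p / aa_p.sum()

    cds: dict[str, str] = {}
    gene_profiles: dict[str, int] = {}
    for i in range(n_genes):
        profile = int(rng.choice(n_profiles, p=fractions))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        aas = rng.choice(aa_names, size=length, p=aa_p)
        codons = []
        for aa in aas:
            fam = SYNONYMOUS_FAMILIES[aa]
            codons.append(fam[int(rng.choice(len(fam), p=prefs[profile][aa]))])
        gene = f"gene{i:05d}"
        cds[gene] = "".join(codons) + "TAA"
        gene_profiles[gene] = profile
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_profiles": n_profiles,
            "profile_divergence": profile_divergence,
            "length_range": length_range,
            "profile_fractions": list(fractions),
            "preferences": prefs,
        },
        gene_profiles=gene_profiles,
    )
    return cds, truth


def gen_halflives(
    freqs: pd.DataFrame,
    planted_beta: Mapping[str, float] | None = None,
    noise_sd: float | str = "auto",
    baseline: float = 5.0,
    beta_scale: float = 50.0,
    floor: float = 0.1,
    seed: int = 0,
) -> tuple[pd.Series, SyntheticTruth]:
    """Half-lives from a planted linear codon-frequency model plus noise.

    half_life_g = baseline + sum_c beta_c * freq_{g,c} + N(0, noise_sd),
    floored at ``floor`` hours. When ``planted_beta`` is None, betas are
    drawn uniform(-beta_scale, +beta_scale) per sense codon (hours per unit
    frequency). ``noise_sd='auto'`` uses 25% of the noiseless half-life
    range.
    """
    rng = _rng(seed)
    if planted_beta is None:
        beta = pd.Series(
            rng.uniform(-beta_scale, beta_scale, len(SENSE_CODONS)),
            index=list(SENSE_CODONS),
        )
    else:
        beta = pd.Series(0.0, index=list(SENSE_CODONS))
        for c, b in planted_beta.items():
            beta[c] = b
    clean = baseline + freqs[list(SENSE_CODONS)].to_numpy() @ beta.to_numpy()
    if noise_sd == "auto":
        noise_sd = 0.25 * float(np.ptp(clean))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    hl = clean + rng.normal(0, noise_sd, len(clean))
    hl = np.maximum(hl, floor)
    if np.all(hl == floor):
        raise ValueError("all half-lives floored; parameters degenerate")
    truth = SyntheticTruth(
        seed=seed,
        params={
            "baseline": baseline,
            "noise_sd": float(noise_sd),
            "floor": floor,
        },
        beta=beta.to_dict(),
    )
    return pd.Series(hl, index=freqs.index, name="half_life"), truth


def gen_expression(
    gene_ids: Sequence[str],
    dynamic_range: float = 100.0,
    profile_bias: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Log-uniform expression over ``dynamic_range`` (1 = all equal).

    ``profile_bias`` maps gene ids to multiplicative up-weights, used to
    shift codon demand toward one profile's genes in one condition.
    """
    if dynamic_range < 1:
        raise ValueError("dynamic_range must be >= 1")
    rng = _rng(seed)
    expr = 10 ** rng.uniform(0, np.log10(dynamic_range), len(gene_ids))
    out = pd.Series(expr, index=list(gene_ids), name="expression")
    if profile_bias:
        for g, w in profile_bias.items():
            if g in out.index:
                out[g] *= w
    return out


def gen_condition_pools(
    preferences: Sequence[Mapping[str, np.ndarray]],
    favored_profile: Mapping[str, int],
    boost: float = 4.0,
    base_abundance: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Condition-specific isoacceptor abundance pools.

    Every sense codon's Watson-Crick anticodon is present at
    ``base_abundance`` (log-normal jitter); in each condition, the
    anticodons decoding the favored profile's preferred codon of each
    family are boosted ``boost``-fold. Returns anticodons x conditions.
    """
    rng = _rng(seed)
    anticodons = sorted({wc_anticodon(c) for c in SENSE_CODONS})
    base = pd.Series(
        base_abundance * rng.lognormal(0, 0.25, len(anticodons)),
        index=anticodons,
    )
    pools = {}
    for cond, profile in favored_profile.items():
        pool = base.copy()
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            pref = preferences[profile][aa]
            best_codon = fam[int(np.argmax(pref))]
            pool[wc_anticodon(best_codon)] *= boost
        pools[cond] = pool
    return pd.DataFrame(pools)


@dataclass
class Scenario:
    """A full synthetic study: all pipeline inputs plus ground truth."""

    trna_genes: list[TRNAGene]
    counts: pd.DataFrame
    sample_conditions: pd.Series
    cds: dict[str, str]
    freqs: pd.DataFrame
    half_lives: pd.DataFrame
    expression: pd.DataFrame
    isoacceptor_pools: pd.DataFrame
    reference_cds: dict[str, str]
    conditions: tuple[str, str]
    truth: SyntheticTruth


def scenario(
    seed: int = 0,
    n_genes: int = 1000,
    n_isodecoder_features: int = 80,
    n_differential: int = 10,
    conditions: tuple[str, str] = ("neuroblast", "neuron"),
    profile_fractions: tuple[float, float] = (0.8, 0.2),
    profile_divergence: float = 0.9,
    pool_boost: float = 4.0,
) -> Scenario:
    """The default two-state synthetic study.

    Condition A's tRNA pool favors profile-1-preferred codons and condition
    B's favors profile-2-preferred codons, emulating a proliferation ->
    differentiation shift; half-lives follow a planted linear
    codon-frequency model per condition; a subset of isodecoder count
    features carries planted fold changes. Seeds for each generator are
    derived deterministically from ``seed``.
    """
    from .codons import codon_count_matrix

    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(8)]

    from .reference import build_isodecoder_reference

    genes, _ = gen_trna_set(
        n_families=40, isodecoders_per_family=2, n_duplicated=4, seed=seeds[0]
    )
    isodecoders = build_isodecoder_reference(genes)
    feature_ids = [g.group_id for g in isodecoders][:n_isodecoder_features]
    rng = _rng(seeds[1])
    diff = rng.choice(feature_ids, n_differential, replace=False)
    planted_lfc = {
        f: float(rng.choice([-1, 1]) * rng.uniform(1.0, 2.5)) for f in diff
    }
    counts, sample_conditions, counts_truth = gen_counts(
        feature_ids,
        planted_lfc=planted_lfc,
        dispersion=0.05,
        depth=1e6,
        n_reps=3,
        conditions=conditions,
        seed=seeds[2],
    )

    cds, tx_truth = gen_transcriptome(
        n_genes,
        n_profiles=2,
        profile_divergence=profile_divergence,
        profile_fractions=profile_fractions,
        seed=seeds[3],
    )
    counts_mat = codon_count_matrix(cds)
    freqs = normalized_frequencies(counts_mat)

    hl = {}
    beta_truth = {}
    for i, cond in enumerate(conditions):
        h, t = gen_halflives(freqs, seed=seeds[4] + i)
        hl[cond] = h
        beta_truth[cond] = t.beta
    half_lives = pd.DataFrame(hl)

    expr = {
        cond: gen_expression(list(cds), seed=seeds[5] + i)
        for i, cond in enumerate(conditions)
    }
    expression = pd.DataFrame(expr)

    pools = gen_condition_pools(
        tx_truth.params["preferences"],
        favored_profile={conditions[0]: 0, conditions[1]: 1},
        boost=pool_boost,
        seed=seeds[6],
    )

    # CAI reference: profile-1 (proliferation-like) genes stand in for the
    # highly expressed ribosomal-protein reference set
    ref_genes = [g for g, p in tx_truth.gene_profiles.items() if p == 0][:50]
    reference_cds = {g: cds[g] for g in ref_genes}

    truth = SyntheticTruth(
        seed=seed,
        params={
            "conditions": conditions,
            "profile_fractions": profile_fractions,
            "profile_divergence": profile_divergence,
            "pool_boost": pool_boost,
            "beta_per_condition": beta_truth,
            "preferences": tx_truth.params["preferences"],
        },
        planted_lfc=counts_truth.planted_lfc,
        gene_profiles=tx_truth.gene_profiles,
        condition_pools={c: pools[c].to_dict() for c in pools.columns},
    )
    return Scenario(
        trna_genes=genes,
        counts=counts,
        sample_conditions=sample_conditions,
        cds=cds,
        freqs=freqs,
        half_lives=half_lives,
        expression=expression,
        isoacceptor_pools=pools,
        reference_cds=reference_cds,
        conditions=conditions,
        truth=truth,
    )
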