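"""Codon optimality and translation-efficiency metrics.

Per-codon metrics
-----------------
CSC     Pearson correlation, across genes, of a codon's length-normalized
        frequency with mRNA half-life; >= +0.01 optimal, <= -0.01
        non-optimal, strictly between neutral.
tAI     Wobble-penalized decoding capacity: W_c = sum_j (1 - s_cj) * A_j
        over cognate anticodon abundances A_j, normalized within each
        synonymous family so the best-decoded codon scores 1.
demand  Expression-weighted transcriptome codon usage, renormalized to
        sum to 1 over sense codons.
SDR_c   Supply/demand ratio tAI_c / demand_c.

Per-gene metrics
----------------
tAI_gene and SDR are geometric means of the per-codon values over a coding
sequence; CAI is the geometric mean of relative adaptiveness w (from RSCU
of a highly expressed reference set). dSDR = SDR(condition B) - SDR(A)
ranks genes by predicted gain in translation efficiency between states.

:class:`CodonOptimalityModel` bundles these computations over two cell
states in a fit()/results pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import (
    AA3_OF_CODON,
    SENSE_CODONS,
    SINGLE_FAMILY_CODONS,
    SYNONYMOUS_FAMILIES,
    to_dna,
    wc_anticodon,
)
from .codons import normalized_frequencies
from .reference import WobbleRuleSet, cognate_trnas

logger = logging.getLogger(__name__)

__all__ = [
    "compute_csc",
    "classify_codons",
    "codon_tai",
    "gene_tai",
    "compute_cai",
    "codon_demand",
    "compute_sdr",
    "wc_abundance_map",
    "tai_csc_effect",
    "differential_tai_csc",
    "geneset_halflife_summary",
    "CodonOptimalityModel",
    "CodonOptimalityResults",
]

_CLASS_ORDER = {"non_optimal": -1, "neutral": 0, "optimal": 1}


def _geomean_matrix(
    counts: pd.DataFrame,
    values: pd.Series,
    what: str,
    zero_policy: str = "strict",
) -> pd.Series:
    """Vectorized count-weighted geometric mean per gene.

    Zero/undefined codon values used by any gene follow ``zero_policy``:
    ``strict`` raises; ``floor`` substitutes the smallest positive value;
    ``geomean`` substitutes the geometric mean of the positive values.
    """
    v = values.reindex(counts.columns).to_numpy(dtype=float)
    c = counts.to_numpy(dtype=float)
    positive = v > 0
    bad = (c > 0) & ~positive[None, :]
    if bad.any():
        if zero_policy == "strict":
            g = counts.index[bad.any(axis=1)][0]
            raise ValueError(f"{what}: nonpositive value for codon used by {g}")
        if not positive.any():
            raise ValueError(f"{what}: no positive values to substitute from")
        if zero_policy == "floor":
            sub = v[positive].min()
        elif zero_policy == "geomean":
            sub = float(np.exp(np.log(v[positive]).mean()))
        else:
            raise ValueError(f"unknown zero policy {zero_policy!r}")
        logger.warning(
            "%s: substituted %g for %d undecodable codons",
            what,
            sub,
            int((~positive & (c > 0).any(axis=0)).sum()),
        )
        v = np.where(positive, v, sub)
    logv = np.log(np.where(v > 0, v, 1.0))
    return pd.Series(np.exp((c @ logv) / c.sum(axis=1)), index=counts.index)


# ---------------------------------------------------------------------------
# per-codon metrics


def compute_csc(
    freqs: pd.DataFrame, half_lives: pd.Series, log_half_life: bool = False
) -> pd.Series:
    """Codon stabilization coefficient per codon.

    Pearson correlation across genes between each codon's frequency column
    and the half-life vector (natural scale by default). Genes are the
    intersection of the two inputs; at least 3 are required. Codons whose
    frequency has zero variance get NaN (logged).
    """
    half_lives = half_lives.dropna()
    genes = freqs.index.intersection(half_lives.index)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} genes with both frequency and half-life")
    hl = half_lives.loc[genes].astype(float)
    if (hl <= 0).any():
        raise ValueError("half-lives must be positive")
    y = np.log(hl.to_numpy()) if log_half_life else hl.to_numpy()
    if np.ptp(y) == 0:
        raise ValueError("constant half-life vector: correlation undefined")
    x = freqs.loc[genes].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    n_missing = int(np.isnan(r).sum())
    if n_missing:
        logger.info("CSC undefined for %d zero-variance codons", n_missing)
    return pd.Series(r, index=freqs.columns, name="csc")


def classify_codons(
    csc: pd.Series, pos_threshold: float = 0.01, neg_threshold: float = -0.01
) -> pd.Series:
    """optimal (CSC >= +0.01), non_optimal (CSC <= -0.01), else neutral."""
    def cls(v: float) -> str | float:
        if pd.isna(v):
            return np.nan
        if v >= pos_threshold:
            return "optimal"
        if v <= neg_threshold:
            return "non_optimal"
        return "neutral"

    return csc.map(cls).rename("csc_class")


def codon_tai(
    isoacceptor_abundance: Mapping[str, float],
    rules: WobbleRuleSet | None = None,
    codons: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Raw tAI weights W_c and family-normalized tAI per sense codon.

    W_c = sum over cognate anticodons j of (1 - s_cj) x abundance_j;
    tAI_c = W_c / max(W) over the codon's synonymous family, so exactly one
    codon per decodable family attains (or ties at) 1.0. A requested family
    whose codons all have W = 0 has no decoding capacity and raises
    ``ValueError``. ``codons`` restricts the computation (whole synonymous
    families of the requested codons); default is all 61.
    """
    rules = rules or WobbleRuleSet()
    if codons is None:
        families = dict(SYNONYMOUS_FAMILIES)
    else:
        wanted = {AA3_OF_CODON[to_dna(c)] for c in codons}
        families = {aa: SYNONYMOUS_FAMILIES[aa] for aa in wanted}
    scored = [c for fam in families.values() for c in fam]
    w = {}
    for codon in scored:
        w[codon] = sum(
            (1.0 - s) * abundance
            for _ac, s, abundance in cognate_trnas(codon, isoacceptor_abundance, rules)
        )
    w = pd.Series(w, name="raw_tai_weight").reindex(
        [c for c in SENSE_CODONS if c in set(scored)]
    )
    tai = pd.Series(index=w.index, dtype=float, name="tai")
    for aa, family in families.items():
        fam_max = w[list(family)].max()
        if fam_max <= 0:
            raise ValueError(f"amino-acid family {aa} has no decoding capacity")
        tai[list(family)] = w[list(family)] / fam_max
    return w, tai


def _weighted_geometric_mean(
    values: pd.Series,
    counts: pd.Series,
    what: str,
    zero_policy: str = "strict",
    floor: float | None = None,
) -> float:
    """exp(sum n_c log v_c / sum n_c) with explicit zero handling."""
    used = counts[counts > 0]
    v = values.reindex(used.index).astype(float)
    if v.isna().any():
        raise ValueError(f"{what}: undefined value for {list(v.index[v.isna()])}")
    zeros = v.index[v <= 0]
    if len(zeros):
        if zero_policy == "strict":
            raise ValueError(f"{what}: zero value at codons {list(zeros)}")
        if zero_policy == "floor":
            positive = v[v > 0]
            sub = floor if floor is not None else (
                positive.min() if len(positive) else np.nan
            )
        elif zero_policy == "geomean":
            positive = v[v > 0]
            sub = float(np.exp(np.log(positive).mean())) if len(positive) else np.nan
        else:
            raise ValueError(f"unknown zero policy {zero_policy!r}")
        if not np.isfinite(sub):
            raise ValueError(f"{what}: no positive values to substitute from")
        logger.warning("%s: substituted %g at %d zero codons", what, sub, len(zeros))
        v = v.copy()
        v[zeros] = sub
    n = used.to_numpy(dtype=float)
    return float(np.exp(np.sum(n * np.log(v.to_numpy())) / n.sum()))


def gene_tai(
    codon_counts: pd.Series, tai: pd.Series, zero_policy: str = "strict"
) -> float:
    """tAI_gene: geometric mean of per-codon tAI over the coding sequence.

    ``codon_counts`` is the gene's 61-codon count vector; the geometric mean
    weights each codon by its number of occurrences (equivalent to the
    product over codon positions to the power 1/L). Computed as exp of the
    mean log for numerical safety.
    """
    if codon_counts.sum() < 1:
        raise ValueError("gene has no sense codons")
    return _weighted_geometric_mean(tai, codon_counts, "tAI_gene", zero_policy)


def relative_adaptiveness(
    reference_counts: pd.Series, absent_floor: bool = True
) -> pd.Series:
    """Sharp & Li relative adaptiveness w from pooled reference codon counts.

    w_c = RSCU_c / max family RSCU = count_c / max family count. Codons of a
    family absent from the reference receive the floor 0.5 / (family max
    count) when ``absent_floor`` (logged), else 0.
    """
    ref = reference_counts.reindex(list(SENSE_CODONS)).fillna(0).astype(float)
    w = pd.Series(index=ref.index, dtype=float, name="w")
    for aa, family in SYNONYMOUS_FAMILIES.items():
        fam = ref[list(family)]
        fam_max = fam.max()
        if fam_max <= 0:
            w[list(family)] = np.nan
            continue
        vals = fam / fam_max
        if absent_floor:
            floored = vals.index[vals == 0]
            if len(floored):
                logger.info(
                    "CAI reference lacks %s codons %s; floored",
                    aa,
                    list(floored),
                )
                vals[floored] = 0.5 / fam_max
        w[list(family)] = vals
    return w


def compute_cai(
    codon_counts: pd.DataFrame | pd.Series,
    reference_counts: pd.Series,
    absent_floor: bool = True,
) -> pd.Series | float:
    """Codon adaptation index per gene.

    Geometric mean of the relative adaptiveness w over the gene's codons,
    excluding single-codon families (ATG, TGG) per the standard formulation.
    ``reference_counts`` are pooled codon counts of the reference gene set
    (e.g. ribosomal protein genes).
    """
    w = relative_adaptiveness(reference_counts, absent_floor=absent_floor)

    def one(counts: pd.Series, gene: str) -> float:
        usable = counts.drop(labels=list(SINGLE_FAMILY_CODONS))
        if usable.sum() < 1:
            raise ValueError(f"{gene}: no multi-family codons for CAI")
        ww = w.reindex(usable.index)
        used = usable[usable > 0]
        undefined = ww.reindex(used.index)
        if undefined.isna().any():
            raise ValueError(
                f"{gene}: reference lacks whole families for codons "
                f"{list(undefined.index[undefined.isna()])}"
            )
        return _weighted_geometric_mean(ww, usable, f"CAI[{gene}]")

    if isinstance(codon_counts, pd.Series):
        return one(codon_counts, str(codon_counts.name or "gene"))
    return pd.Series(
        {g: one(codon_counts.loc[g], g) for g in codon_counts.index}, name="cai"
    )


def codon_demand(
    freqs: pd.DataFrame, expression: pd.Series, normalize: bool = True
) -> pd.Series:
    """Expression-weighted codon usage of the transcriptome.

    demand_c = sum_g expression_g x freq_{g,c}, over the genes shared by the
    two inputs, renormalized to sum to 1 over sense codons (making SDR
    dimensionless and invariant to expression units).
    """
    expression = expression.dropna()
    genes = freqs.index.intersection(expression.index)
    if len(genes) == 0:
        raise ValueError("no genes shared by frequencies and expression")
    e = expression.loc[genes].astype(float)
    if (e < 0).any():
        raise ValueError("negative expression values")
    if e.sum() == 0:
        raise ValueError("all-zero expression")
    demand = freqs.loc[genes].mul(e, axis=0).sum(axis=0)
    if normalize:
        demand = demand / demand.sum()
    return demand.rename("demand")


def compute_sdr(
    tai: pd.Series,
    demand: pd.Series,
    codon_counts: pd.DataFrame | None = None,
    zero_policy: str = "strict",
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Supply/demand ratio per codon, and per gene when counts are given.

    SDR_c = tAI_c / demand_c; gene SDR is the geometric mean of SDR_c over
    the gene's codon positions. A codon occurring in any scored gene with
    zero demand raises ``ValueError`` naming it.
    """
    sdr_c = (tai / demand).rename("sdr_c")
    if codon_counts is None:
        return sdr_c
    occurring = codon_counts.sum(axis=0)
    bad = [
        c
        for c in occurring.index[occurring > 0]
        if not np.isfinite(sdr_c[c]) or demand.get(c, 0) <= 0
    ]
    if bad:
        raise ValueError(f"zero demand for occurring codon(s): {bad}")
    gene_sdr = pd.Series(
        {
            g: _weighted_geometric_mean(
                sdr_c, codon_counts.loc[g], f"SDR[{g}]", zero_policy
            )
            for g in codon_counts.index
        },
        name="sdr",
    )
    return sdr_c, gene_sdr


def wc_abundance_map(
    isoacceptor_abundance: Mapping[str, float],
    codons: Iterable[str] = SENSE_CODONS,
) -> pd.Series:
    """Watson-Crick cognate abundance per codon (0 when no such tRNA)."""
    pool = {to_dna(k): float(v) for k, v in isoacceptor_abundance.items()}
    return pd.Series(
        {c: pool.get(wc_anticodon(c), 0.0) for c in codons},
        name="wc_abundance",
    )


# ---------------------------------------------------------------------------
# cross-condition comparisons


def cohens_d(group1: np.ndarray, group2: np.ndarray) -> float:
    """(mean1 - mean2) / pooled SD."""
    n1, n2 = len(group1), len(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 members")
    s1, s2 = np.var(group1, ddof=1), np.var(group2, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    diff = np.mean(group1) - np.mean(group2)
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return float(diff / pooled)


def tai_csc_effect(
    tai: pd.Series,
    csc: pd.Series,
    grouping: str = "sign",
    pos_threshold: float = 0.01,
    neg_threshold: float = -0.01,
) -> dict[str, float]:
    """Effect of codon class on tAI: Cohen's d and Welch's t-test.

    Compares tAI of stabilizing vs destabilizing codons, grouped either by
    CSC sign (``grouping='sign'``) or by the ±0.01 classes
    (``grouping='class'``, neutral codons excluded).
    """
    both = pd.DataFrame({"tai": tai, "csc": csc}).dropna()
    if grouping == "sign":
        g1 = both.loc[both["csc"] > 0, "tai"].to_numpy()
        g2 = both.loc[both["csc"] < 0, "tai"].to_numpy()
    elif grouping == "class":
        g1 = both.loc[both["csc"] >= pos_threshold, "tai"].to_numpy()
        g2 = both.loc[both["csc"] <= neg_threshold, "tai"].to_numpy()
    else:
        raise ValueError("grouping must be 'sign' or 'class'")
    d = cohens_d(g1, g2)
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(g1, g2, equal_var=False)
    return {
        "cohens_d": d,
        "t": float(t),
        "p_value": float(p),
        "n_stabilizing": len(g1),
        "n_destabilizing": len(g2),
    }


def differential_tai_csc(
    tai_a: pd.Series,
    tai_b: pd.Series,
    class_a: pd.Series,
    class_b: pd.Series,
    delta_tai_threshold: float = 0.2,
) -> pd.DataFrame:
    """Categorize codons by joint differential tAI and CSC class between
    conditions.

    delta_tai = tAI(B) - tAI(A) is "differential" when |delta_tai| >=
    threshold; the CSC is differential when the class changed. Categories:
    ``concordant`` (both differential, same direction), ``discordant``
    (both, opposite directions), ``tai_only``, ``csc_only``,
    ``no_difference``.
    """
    codons = tai_a.index
    dtai = (tai_b - tai_a).rename("delta_tai")
    tai_diff = dtai.abs() >= delta_tai_threshold
    ord_a = class_a.map(_CLASS_ORDER)
    ord_b = class_b.map(_CLASS_ORDER)
    csc_dir = np.sign(ord_b - ord_a)
    csc_diff = csc_dir != 0

    def cat(c: str) -> str:
        t, s = bool(tai_diff[c]), bool(csc_diff[c])
        if t and s:
            return (
                "concordant"
                if np.sign(dtai[c]) == csc_dir[c]
                else "discordant"
            )
        if t:
            return "tai_only"
        if s:
            return "csc_only"
        return "no_difference"

    return pd.DataFrame(
        {
            "delta_tai": dtai,
            "csc_class_a": class_a,
            "csc_class_b": class_b,
            "category": pd.Series({c: cat(c) for c in codons}),
        }
    ).loc[codons]


def geneset_halflife_summary(
    genes: Iterable[str], half_lives: Mapping[str, pd.Series]
) -> pd.DataFrame:
    """Mean, SEM and n of half-life for a gene set, per condition.

    SEM = SD/sqrt(n) (sample SD); reported as NaN for single-gene sets.
    An empty intersection with a condition's half-life table is an error.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    rows = {}
    for cond, hl in half_lives.items():
        vals = hl.reindex(genes).dropna()
        if len(vals) == 0:
            raise ValueError(f"no half-life coverage for gene set in {cond!r}")
        rows[cond] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1
            else np.nan,
            "n": len(vals),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# model / results


@dataclass
class CodonOptimalityModel:
    """Joint codon-optimality model of two cell states.

    Parameters
    ----------
    codon_counts
        genes x 61 sense-codon count matrix of the transcriptome under
        study (see :func:`trnadapt.codons.codon_count_matrix`).
    isoacceptor_abundance
        anticodons x conditions table of isoacceptor-level tRNA abundance
        (TMM-normalized condition means).
    half_lives
        genes x conditions mRNA half-lives in hours.
    expression
        genes x conditions mRNA abundance (any proportional unit).
    reference_counts
        pooled codon counts of the CAI reference set (highly expressed
        genes, canonically ribosomal proteins).
    conditions
        the two condition labels (A, B); dSDR = SDR(B) - SDR(A).
    """

    codon_counts: pd.DataFrame
    isoacceptor_abundance: pd.DataFrame
    half_lives: pd.DataFrame
    expression: pd.DataFrame
    reference_counts: pd.Series
    conditions: tuple[str, str]
    wobble_rules: WobbleRuleSet = field(default_factory=WobbleRuleSet)
    csc_pos_threshold: float = 0.01
    csc_neg_threshold: float = -0.01
    delta_tai_threshold: float = 0.2
    zero_policy: str = "strict"

    @classmethod
    def from_tables(
        cls,
        cds: Mapping[str, str],
        isoacceptor_abundance: pd.DataFrame,
        half_lives: pd.DataFrame,
        expression: pd.DataFrame,
        reference_cds: Mapping[str, str],
        conditions: tuple[str, str],
        **kwargs,
    ) -> "CodonOptimalityModel":
        """Build from raw CDS mappings instead of precomputed count matrices."""
        from .codons import codon_count_matrix

        counts = codon_count_matrix(cds)
        ref_counts = codon_count_matrix(reference_cds).sum(axis=0)
        return cls(
            codon_counts=counts,
            isoacceptor_abundance=isoacceptor_abundance,
            half_lives=half_lives,
            expression=expression,
            reference_counts=ref_counts,
            conditions=conditions,
            **kwargs,
        )

    def fit(self) -> "CodonOptimalityResults":
        a, b = self.conditions
        for c in (a, b):
            for df, what in (
                (self.isoacceptor_abundance, "isoacceptor abundance"),
                (self.half_lives, "half-lives"),
                (self.expression, "expression"),
            ):
                if c not in df.columns:
                    raise ValueError(f"condition {c!r} missing from {what}")

        counts = self.codon_counts
        freqs = normalized_frequencies(counts)

        # genes covered by both conditions' half-life and expression tables
        covered = counts.index
        for df in (self.half_lives, self.expression):
            covered = covered.intersection(df[[a, b]].dropna().index)
        n_dropped = len(counts.index) - len(covered)
        if n_dropped:
            logger.info(
                "%d genes without full half-life/expression coverage dropped",
                n_dropped,
            )

        codon_metrics: dict[str, pd.Series] = {}
        gene_metrics: dict[str, pd.Series] = {}
        effects = {}
        for cond in (a, b):
            pool = self.isoacceptor_abundance[cond]
            csc = compute_csc(freqs.loc[covered], self.half_lives[cond])
            klass = classify_codons(
                csc, self.csc_pos_threshold, self.csc_neg_threshold
            )
            w, tai = codon_tai(pool.to_dict(), self.wobble_rules)
            demand = codon_demand(
                freqs.loc[covered], self.expression.loc[covered, cond]
            )
            sdr_c = compute_sdr(tai, demand)
            sdr_gene = _geomean_matrix(
                counts.loc[covered], sdr_c, f"SDR[{cond}]", self.zero_policy
            )
            codon_metrics[f"csc_{cond}"] = csc
            codon_metrics[f"csc_class_{cond}"] = klass
            codon_metrics[f"raw_tai_weight_{cond}"] = w
            codon_metrics[f"tai_{cond}"] = tai
            codon_metrics[f"wc_abundance_{cond}"] = wc_abundance_map(
                pool.to_dict()
            )
            codon_metrics[f"demand_{cond}"] = demand
            codon_metrics[f"sdr_c_{cond}"] = sdr_c
            gene_metrics[f"tai_gene_{cond}"] = _geomean_matrix(
                counts.loc[covered], tai, f"tAI_gene[{cond}]", self.zero_policy
            )
            gene_metrics[f"sdr_{cond}"] = sdr_gene
            gene_metrics[f"half_life_{cond}"] = self.half_lives.loc[covered, cond]
            gene_metrics[f"expression_{cond}"] = self.expression.loc[covered, cond]
            effects[cond] = tai_csc_effect(tai, csc)

        gene_df = pd.DataFrame(gene_metrics)
        gene_df["cai"] = compute_cai(counts.loc[covered], self.reference_counts)
        gene_df["delta_sdr"] = gene_df[f"sdr_{b}"] - gene_df[f"sdr_{a}"]
        codon_df = pd.DataFrame(codon_metrics).loc[list(SENSE_CODONS)]
        codon_df["amino_acid"] = [AA3_OF_CODON[c] for c in codon_df.index]
        codon_df["differential"] = differential_tai_csc(
            codon_df[f"tai_{a}"],
            codon_df[f"tai_{b}"],
            codon_df[f"csc_class_{a}"],
            codon_df[f"csc_class_{b}"],
            self.delta_tai_threshold,
        )["category"]

        return CodonOptimalityResults(
            model=self,
            codon_metrics=codon_df,
            gene_metrics=gene_df,
            tai_csc_effects=effects,
        )


@dataclass
class CodonOptimalityResults:
    """Fitted per-codon and per-gene metrics for the two conditions."""

    model: CodonOptimalityModel
    codon_metrics: pd.DataFrame
    gene_metrics: pd.DataFrame
    tai_csc_effects: dict[str, dict[str, float]]

    @property
    def conditions(self) -> tuple[str, str]:
        return self.model.conditions

    def rank_delta_sdr(self, fraction: float = 0.10) -> dict[str, pd.Index]:
        """Genes in the top and bottom `fraction` of dSDR."""
        if not 0 < fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        ranked = self.gene_metrics.sort_values(
            "delta_sdr", ascending=False, kind="mergesort"
        )
        n = max(1, int(np.floor(len(ranked) * fraction)))
        return {"top": ranked.index[:n], "bottom": ranked.index[-n:]}

    def summary(self) -> str:
        a, b = self.conditions
        cm, gm = self.codon_metrics, self.gene_metrics
        lines = [
            "Codon optimality model: " + f"{a} vs {b}",
            "=" * 46,
            f"genes scored                  {len(gm)}",
            f"codons with defined CSC       "
            f"{int(cm[f'csc_{a}'].notna().sum())} ({a}), "
            f"{int(cm[f'csc_{b}'].notna().sum())} ({b})",
        ]
        for cond in (a, b):
            n_opt = int((cm[f"csc_class_{cond}"] == "optimal").sum())
            n_non = int((cm[f"csc_class_{cond}"] == "non_optimal").sum())
            n_tai1 = int(
                (
                    (cm[f"tai_{cond}"] >= 1.0 - 1e-12)
                    & (cm[f"csc_class_{cond}"] == "optimal")
                ).sum()
            )
            eff = self.tai_csc_effects[cond]
            lines += [
                f"[{cond}] optimal/non-optimal codons  {n_opt}/{n_non}",
                f"[{cond}] optimal codons at tAI=1.0   {n_tai1}",
                f"[{cond}] tAI ~ CSC sign: Cohen's d = {eff['cohens_d']:.3f}, "
                f"Welch p = {eff['p_value']:.3g}",
            ]
        ds = gm["delta_sdr"]
        lines += [
            f"dSDR ({b} - {a}): min {ds.min():.3f}, median {ds.median():.3f}, "
            f"max {ds.max():.3f}",
            f"differential codons (|dtAI| >= "
            f"{self.model.delta_tai_threshold}): "
            f"{int((cm['differential'] != 'no_difference').sum())}",
        ]
        return "\n".join(lines)
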