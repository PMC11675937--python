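"""tRNA-seq count normalization and isoacceptor-level abundance.

Between-sample normalization uses the trimmed mean of M-values (TMM):
scaling factors are precision-weighted means of log2 expression ratios
against a reference sample, after double-trimming on the log-ratio (M) and
absolute-intensity (A) scales, rescaled to a geometric mean of 1.
Isodecoder abundances are averaged (unweighted by default) into isoacceptor
abundances, the anticodon-level decoding supply.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import IsoacceptorGroup

__all__ = [
    "tmm_factors",
    "normalize_counts",
    "aggregate_isoacceptors",
    "condition_means",
    "condition_fold_change",
]


def _upper_quartile(col: pd.Series, lib_size: float) -> float:
    return float(np.quantile(col.to_numpy() / lib_size, 0.75))


def _rank_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping values whose rank lies inside the trim window."""
    n = values.size
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    # average ranks, 1-based (ties share their mean rank)
    order = pd.Series(values).rank(method="average").to_numpy()
    return (order >= lo) & (order <= hi)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    reference_sample: str | None = None,
) -> pd.Series:
    """TMM scaling factor per sample (column) of a count matrix.

    Features with a zero count in either the sample or the reference are
    excluded before trimming. The reference defaults to the sample whose
    upper quartile of count/library-size is closest to the mean upper
    quartile. Factors are rescaled so that their geometric mean is 1.
    """
    if counts.shape[0] < 2:
        raise ValueError("TMM needs at least 2 features")
    lib = counts.sum(axis=0).astype(float)
    zero_libs = lib.index[lib == 0].tolist()
    if zero_libs:
        raise ValueError(f"sample(s) with all-zero counts: {zero_libs}")

    if reference_sample is None:
        uq = pd.Series(
            {s: _upper_quartile(counts[s], lib[s]) for s in counts.columns}
        )
        reference_sample = (uq - uq.mean()).abs().idxmin()
    elif reference_sample not in counts.columns:
        raise ValueError(f"unknown reference sample {reference_sample!r}")

    ref = counts[reference_sample].to_numpy(dtype=float)
    n_ref = lib[reference_sample]

    factors = {}
    for s in counts.columns:
        if s == reference_sample:
            factors[s] = 1.0
            continue
        obs = counts[s].to_numpy(dtype=float)
        n_obs = lib[s]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        trimmed = _rank_keep(m, logratio_trim) & _rank_keep(a, abs_trim)
        if not trimmed.any():  # degenerate tiny tables: fall back untrimmed
            trimmed = np.ones_like(m, dtype=bool)
        # asymptotic variance of M (delta method); weight = 1/variance
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        mt, vt = m[trimmed], v[trimmed]
        with np.errstate(divide="ignore"):
            w = np.where(vt > 0, 1.0 / vt, 0.0)
        factors[s] = float(2 ** (np.sum(w * mt) / np.sum(w))) if w.sum() else 1.0

    f = pd.Series(factors).reindex(counts.columns)
    f /= np.exp(np.mean(np.log(f)))
    return f


def normalize_counts(
    counts: pd.DataFrame, factors: pd.Series, scale: float = 1e6
) -> pd.DataFrame:
    """count / (library size x TMM factor) x scale."""
    if not counts.columns.equals(factors.index):
        if set(counts.columns) != set(factors.index):
            raise ValueError("sample ids of counts and factors do not match")
        factors = factors.reindex(counts.columns)
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    lib = counts.sum(axis=0).astype(float)
    return counts / (lib * factors) * scale


def aggregate_isoacceptors(
    abundance: pd.DataFrame,
    isoacceptor_map: Sequence[IsoacceptorGroup] | Mapping[str, Sequence[str]],
    copy_numbers: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Average isodecoder abundances within each isoacceptor group.

    ``isoacceptor_map`` is either a list of :class:`IsoacceptorGroup` or a
    mapping group-key -> member isodecoder ids. The per-sample isoacceptor
    value is the arithmetic mean of its member isodecoder values (optionally
    copy-number weighted via ``copy_numbers``). Features of the abundance
    table that appear in no group raise ``ValueError``.
    """
    if isinstance(isoacceptor_map, Mapping):
        groups = {k: list(v) for k, v in isoacceptor_map.items()}
    else:
        groups = {g.key: list(g.isodecoder_group_ids) for g in isoacceptor_map}

    mapped = {m for members in groups.values() for m in members}
    unmapped = sorted(set(abundance.index) - mapped)
    if unmapped:
        raise ValueError(f"features absent from isoacceptor map: {unmapped}")

    rows = {}
    for key in sorted(groups):
        members = [m for m in groups[key] if m in abundance.index]
        if not members:
            continue
        block = abundance.loc[members]
        if copy_numbers is None:
            rows[key] = block.mean(axis=0)
        else:
            w = np.array([copy_numbers[m] for m in members], dtype=float)
            rows[key] = block.mul(w, axis=0).sum(axis=0) / w.sum()
    return pd.DataFrame(rows).T[abundance.columns]


def condition_means(
    abundance: pd.DataFrame, sample_conditions: Mapping[str, str]
) -> pd.DataFrame:
    """Per-feature mean across each condition's replicate samples."""
    missing = [s for s in abundance.columns if s not in sample_conditions]
    if missing:
        raise ValueError(f"samples without condition labels: {missing}")
    cond = pd.Series({s: sample_conditions[s] for s in abundance.columns})
    return abundance.T.groupby(cond).mean().T


def condition_fold_change(
    abundance: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    condition_a: str,
    condition_b: str,
    lfc_threshold: float = 0.5,
    pseudocount: float = 0.5,
    q_values: pd.Series | None = None,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-feature log2 fold change of condition means, with a threshold flag.

    log2FC = log2(mean_a / mean_b); the flag is |log2FC| >= lfc_threshold
    (boundary inclusive). When either condition mean is 0, ``pseudocount``
    is added to both means. An optional externally produced q-value column
    tightens the flag to ``flag & (q <= q_threshold)`` (differential testing
    itself is delegated to dedicated tools).
    """
    means = condition_means(abundance, sample_conditions)
    for c in (condition_a, condition_b):
        if c not in means.columns:
            raise ValueError(f"condition {c!r} absent from samples")
    a = means[condition_a].astype(float).copy()
    b = means[condition_b].astype(float).copy()
    needs_pc = (a == 0) | (b == 0)
    a[needs_pc] += pseudocount
    b[needs_pc] += pseudocount
    lfc = np.log2(a / b)
    out = pd.DataFrame(
        {
            f"mean_{condition_a}": means[condition_a],
            f"mean_{condition_b}": means[condition_b],
            "log2fc": lfc,
            "flag": lfc.abs() >= lfc_threshold,
        }
    )
    if q_values is not None:
        q = q_values.reindex(out.index)
        out["q_value"] = q
        out["flag"] = out["flag"] & (q <= q_threshold)
    return out
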