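"""Codon-usage PCA, k-means with elbow selection, hierarchical ordering.

PCA runs on centered (optionally z-scored) amino-acid-normalized codon
frequencies; k-means clusters the same matrix, with the number of clusters
chosen at the point of maximal curvature (largest second difference) of the
inertia curve; hierarchical clustering provides deterministic leaf orders
for heatmap-style output and for grouping genes by their two-condition
tAI_gene pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PCAResult",
    "ClusterAssignment",
    "pca_codon_usage",
    "kmeans_elbow",
    "hierarchical_order",
    "tai_gene_groups",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # genes x components
    loadings: pd.DataFrame  # features x components
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        evf = self.explained_variance_fraction
        if (evf < -1e-12).any() or evf.sum() > 1 + 1e-9:
            raise ValueError("invalid explained variance fractions")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster label in [0, k)
    k: int
    inertia_trace: pd.Series  # candidate k -> inertia
    rule: str
    seed: int


def pca_codon_usage(
    matrix: pd.DataFrame, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """PCA of the gene x feature codon-usage matrix.

    Columns are always centered; ``scale=True`` additionally z-scores them.
    The sign of each component is fixed so its largest-magnitude loading is
    positive, making scores deterministic across runs and libraries.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 features")
    if n_components > min(matrix.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, features)"
        )
    x = matrix.to_numpy(dtype=float)
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # features x components
    for j in range(n_components):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(
            loadings, index=matrix.columns, columns=comp_names
        ),
        explained_variance_fraction=pca.explained_variance_ratio_,
    )


def kmeans_elbow(
    matrix: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_restarts: int = 10,
    k: int | None = None,
) -> ClusterAssignment:
    """K-means with the cluster number chosen by the elbow rule.

    The inertia is computed for every k in ``k_range`` (inclusive); the
    chosen k maximizes the second difference of log-inertia
    (log i[k-1] - 2 log i[k] + log i[k+1]) over the interior candidates —
    the maximal-curvature point of a curve whose decay is roughly
    geometric before the true k and flat after it. Pass ``k`` to override
    the rule while keeping the trace.
    """
    lo, hi = k_range
    if lo < 2 or hi > len(matrix):
        raise ValueError(f"k_range {k_range} outside [2, n_genes]")
    if hi - lo < 2 and k is None:
        raise ValueError("elbow rule needs at least 3 candidate k values")
    x = matrix.to_numpy(dtype=float)
    inertia = {}
    fits = {}
    for kk in range(lo, hi + 1):
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        km.fit(x)
        inertia[kk] = float(km.inertia_)
        fits[kk] = km
    trace = pd.Series(inertia).sort_index()
    if k is None:
        log_trace = np.log(trace.clip(lower=np.finfo(float).tiny))
        second_diff = {
            kk: log_trace[kk - 1] - 2 * log_trace[kk] + log_trace[kk + 1]
            for kk in range(lo + 1, hi)
        }
        k = max(second_diff, key=lambda kk: (second_diff[kk], -kk))
        rule = "max second difference of log-inertia"
    else:
        rule = "user override"
    labels = pd.Series(fits[k].labels_, index=matrix.index, name="cluster")
    return ClusterAssignment(
        labels=labels, k=k, inertia_trace=trace, rule=rule, seed=seed
    )


def hierarchical_order(
    matrix: pd.DataFrame,
    axis: int = 0,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[str], np.ndarray]:
    """Deterministic dendrogram leaf order plus the linkage matrix.

    ``axis=0`` orders rows, ``axis=1`` columns. Rows containing NaN are an
    error (listed).
    """
    data = matrix if axis == 0 else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    nan_rows = data.index[data.isna().any(axis=1)].tolist()
    if nan_rows:
        raise ValueError(f"rows with NaN values: {nan_rows}")
    linkage = hierarchy.linkage(
        data.to_numpy(dtype=float), method=method, metric=metric
    )
    order = hierarchy.leaves_list(linkage)
    return [data.index[i] for i in order], linkage


def tai_gene_groups(
    tai_gene: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    mode: str = "hierarchical",
    n_blocks: int = 4,
    quantile_thresholds: tuple[float, float] = (0.8, 0.8),
    min_up_margin: float = 0.0,
) -> pd.Series:
    """Group genes by their (condition A, condition B) tAI_gene pattern.

    Labels: ``shared_high`` (high in both), ``shared_low`` (low in both),
    ``{condition_b}_up`` (higher adaptation in B than A), ``other``.

    ``mode='hierarchical'`` (default) cuts an average-linkage tree of the
    two-column matrix into ``n_blocks`` blocks and labels each block from
    its centroid relative to the column medians. ``mode='threshold'``
    labels each gene directly from cohort quantile thresholds.
    """
    for c in (condition_a, condition_b):
        if c not in tai_gene.columns:
            raise ValueError(f"condition {c!r} missing from tAI_gene table")
    two = tai_gene[[condition_a, condition_b]].dropna()
    up_label = f"{condition_b}_up"

    if mode == "threshold":
        qa = two[condition_a].quantile(quantile_thresholds[0])
        qb = two[condition_b].quantile(quantile_thresholds[1])

        def label(row: pd.Series) -> str:
            hi_a, hi_b = row[condition_a] >= qa, row[condition_b] >= qb
            if hi_a and hi_b:
                return "shared_high"
            if not hi_a and not hi_b:
                if row[condition_b] - row[condition_a] > min_up_margin and hi_b:
                    return up_label  # pragma: no cover - unreachable guard
                return "shared_low"
            if hi_b and not hi_a:
                return up_label
            return "other"

        return two.apply(label, axis=1).rename("tai_gene_group")

    if mode != "hierarchical":
        raise ValueError("mode must be 'hierarchical' or 'threshold'")
    _, linkage = hierarchical_order(two)
    blocks = hierarchy.fcluster(linkage, t=n_blocks, criterion="maxclust")
    blocks = pd.Series(blocks, index=two.index)
    med_a, med_b = two[condition_a].median(), two[condition_b].median()
    block_label = {}
    for blk, members in two.groupby(blocks):
        ca, cb = members[condition_a].mean(), members[condition_b].mean()
        if ca >= med_a and cb >= med_b:
            block_label[blk] = "shared_high"
        elif ca < med_a and cb < med_b:
            block_label[blk] = "shared_low"
        elif cb >= med_b and ca < med_a:
            block_label[blk] = up_label
        else:
            block_label[blk] = "other"
    return blocks.map(block_label).rename("tai_gene_group")
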