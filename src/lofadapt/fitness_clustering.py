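"""Weighted k-means organization of per-gene fitness profiles.

Genes significant in at least one condition are clustered on their
replicate-level normalized enrichments plus a per-condition average
column.  Average columns carry ten times the weight of replicate columns;
a column weight w enters squared Euclidean distance linearly, which is
implemented by scaling the column by sqrt(w) and running ordinary
k-means.  Cluster labels are canonicalized by descending cluster mean so
results are comparable across runs.

A simple hypergeometric category-enrichment summary (with BH q-values
over all cluster x category pairs) is provided for annotating clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .footprint_stats import NormalizedDataset, SignificanceCalls

__all__ = [
    "ClusterMatrix",
    "ClusterResult",
    "build_cluster_matrix",
    "weighted_kmeans",
    "clip_for_display",
    "cluster_category_enrichment",
    "AVERAGE_WEIGHT",
]

AVERAGE_WEIGHT = 10.0
REPLICATE_WEIGHT = 1.0
DISPLAY_RANGE = (-3.0, 3.0)


@dataclass
class ClusterMatrix:
    """Genes x (replicate + per-condition average) columns with weights."""

    data: pd.DataFrame
    weights: pd.Series  # per column, > 0

    def __post_init__(self) -> None:
        if not (self.weights > 0).all():
            raise ValueError("column weights must be positive")
        if not self.data.columns.equals(self.weights.index):
            raise ValueError("weights must align with matrix columns")

    def weighted_values(self) -> np.ndarray:
        """Columns scaled by sqrt(weight): ordinary Euclidean distance in
        this space equals the weighted distance on the raw columns."""
        return self.data.to_numpy() * np.sqrt(self.weights.to_numpy())


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene -> cluster index (0-based, canonical order)
    centroids: np.ndarray  # in weighted space, canonical order
    wcss: float
    k: int
    seed: int


def build_cluster_matrix(
    calls: SignificanceCalls, normalized: NormalizedDataset
) -> ClusterMatrix:
    """Assemble the clustering input from pipeline outputs.

    Rows are genes significant in >=1 condition; for every condition the
    replicate columns are followed by their arithmetic-mean column, which
    receives ten times the replicate weight.
    """
    genes = calls.any_significant()
    if len(genes) == 0:
        raise ValueError("no significant genes; nothing to cluster")
    blocks = []
    weights = []
    for cond in normalized.conditions:
        reps = normalized.condition_values(cond).loc[genes]
        reps.columns = [f"{cond}:{r}" for r in reps.columns.get_level_values(-1)]
        avg = reps.mean(axis=1).rename(f"{cond}:avg")
        blocks.append(pd.concat([reps, avg], axis=1))
        weights.extend([REPLICATE_WEIGHT] * reps.shape[1] + [AVERAGE_WEIGHT])
    data = pd.concat(blocks, axis=1)
    return ClusterMatrix(data=data, weights=pd.Series(weights, index=data.columns))


def weighted_kmeans(
    matrix: ClusterMatrix, k: int = 9, seed: int = 0, restarts: int = 50
) -> ClusterResult:
    """Best-of-``restarts`` k-means++ on the sqrt(weight)-scaled matrix.

    Deterministic for a given seed; labels are relabeled so cluster 0 has
    the highest centroid mean, descending from there.
    """
    n = matrix.data.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    X = matrix.weighted_values()
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    return ClusterResult(
        assignments=pd.Series(labels, index=matrix.data.index, name="cluster"),
        centroids=km.cluster_centers_[order],
        wcss=float(km.inertia_),
        k=k,
        seed=seed,
    )


def clip_for_display(values, lo: float = DISPLAY_RANGE[0], hi: float = DISPLAY_RANGE[1]):
    """Restrict enrichment values to [lo, hi] for heatmap display."""
    if isinstance(values, pd.DataFrame):
        return values.clip(lower=lo, upper=hi)
    return np.clip(np.asarray(values, dtype=float), lo, hi)


def cluster_category_enrichment(
    assignments: pd.Series,
    categories: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each category in each cluster.

    ``categories`` maps gene -> iterable of category names; genes not in
    the clustering are ignored.  Returns a DataFrame with columns
    ``cluster, category, overlap, cluster_size, category_size, p, q``
    where q is BH over all cluster x category pairs.
    """
    genes = set(assignments.index)
    cat_members: dict[str, set[str]] = {}
    for g, cats in categories.items():
        if g not in genes:
            continue
        for c in cats:
            cat_members.setdefault(c, set()).add(g)
    if not cat_members:
        raise ValueError("categories cover no clustered gene")
    M = len(genes)
    rows = []
    for cl, cl_genes in assignments.groupby(assignments).groups.items():
        cl_set = set(cl_genes)
        for cat, members in sorted(cat_members.items()):
            k = len(cl_set & members)
            p = float(stats.hypergeom.sf(k - 1, M, len(members), len(cl_set)))
            rows.append((cl, cat, k, len(cl_set), len(members), p))
    table = pd.DataFrame(
        rows, columns=["cluster", "category", "overlap", "cluster_size", "category_size", "p"]
    )
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    return table
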