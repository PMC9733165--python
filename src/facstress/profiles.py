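"""Expression-profile clustering of interaction genes.

Genes with significant stressor interactions are clustered by the shape of
their surrogate-corrected, z-scored expression profiles.  Profiles are
summarised to the mean z-score per design cell (the 8 factor-level
combinations), compared by correlation distance under average-linkage
agglomeration, with the cut chosen to maximise the mean silhouette; any
cluster smaller than ``min_size`` (default 10) is dissolved and its genes
reported as unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .design import DEFAULT_FACTORS


def zscore_profiles(expr: pd.DataFrame, genes=None) -> tuple[pd.DataFrame, pd.Series]:
    """Centre and scale each gene's profile across samples.

    Positive z-scores mark samples above the gene's average expression.
    Returns the z matrix and a boolean Series flagging constant genes,
    whose rows are set to all zeros.
    """
    sub = expr if genes is None else expr.loc[list(genes)]
    if sub.shape[0] == 0:
        raise ValueError("empty gene set")
    mat = sub.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] <= 1e-12
    z = (mat - mean) / np.where(sd > 1e-12, sd, 1.0)
    z[constant] = 0.0
    return (
        pd.DataFrame(z, index=sub.index, columns=sub.columns),
        pd.Series(constant, index=sub.index, name="constant"),
    )


@dataclass
class ProfileClustering:
    """Cluster assignment (cluster ids 1..m; 0 = unassigned) plus per-cluster
    mean cell profiles."""

    assignments: pd.Series
    cluster_means: pd.DataFrame
    silhouette: float = float("nan")
    members: dict[int, list[str]] = field(default_factory=dict)

    @property
    def unassigned(self) -> list[str]:
        return list(self.assignments.index[self.assignments == 0])

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def cell_means(z: pd.DataFrame, design: pd.DataFrame, factors=None) -> pd.DataFrame:
    """Average each gene's z-profile over the design cells (factor-level
    combinations), in lexicographic cell order."""
    factors = list(factors or [f for f in DEFAULT_FACTORS if f in design.columns])
    key = design[factors].agg("|".join, axis=1)
    groups = sorted(key.unique())
    out = {g: z.loc[:, key.index[key == g]].mean(axis=1) for g in groups}
    return pd.DataFrame(out)


def cluster_profiles(
    z: pd.DataFrame,
    design: pd.DataFrame,
    min_size: int = 10,
    k_max: int = 8,
    seed: int | None = None,
    min_silhouette: float = 0.25,
    same_shape_dist: float = 0.2,
) -> ProfileClustering:
    """Cluster genes by design-cell mean profiles.

    Agglomerative (average linkage) on correlation distance; the number of
    clusters maximises the mean silhouette over k in [2, k_max]; if even the
    best split scores below ``min_silhouette`` the genes are treated as one
    undivided cluster.  Clusters with fewer than ``min_size`` members are
    dissolved to unassigned.  The procedure is deterministic; gene order is
    fixed by sorting on gene id.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    z = z.sort_index()
    profiles = cell_means(z, design)
    genes = profiles.index
    assignments = pd.Series(0, index=genes, name="cluster", dtype=int)

    if len(genes) < min_size:
        return ProfileClustering(assignments, profiles.iloc[0:0])

    dist = pdist(profiles.to_numpy(), metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)  # constant profiles: maximally uninformative
    if dist.size == 0 or float(dist.max()) < same_shape_dist:
        # all pairwise profile correlations > 1 - same_shape_dist:
        # the genes share one shape and form a single cluster
        assignments[:] = 1
        means = profiles.mean(axis=0).to_frame(name=1).T
        return ProfileClustering(
            assignments, means, members={1: list(genes)}, silhouette=float("nan")
        )

    Z = linkage(dist, method="average")
    from scipy.spatial.distance import squareform

    dmat = squareform(dist)
    best_k, best_score, best_labels = 1, -np.inf, np.ones(len(genes), dtype=int)
    for k in range(2, min(k_max, len(genes) - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dmat, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels

    if best_k == 1 or best_score < min_silhouette:
        best_k, best_labels, best_score = 1, np.ones(len(genes), dtype=int), float("nan")

    # dissolve undersized clusters, then relabel survivors by size desc
    labels = pd.Series(best_labels, index=genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_size]
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    assignments = labels.map(lambda c: remap.get(c, 0)).astype(int)

    members = {
        cid: sorted(assignments.index[assignments == cid]) for cid in remap.values()
    }
    means = pd.DataFrame(
        {cid: profiles.loc[m].mean(axis=0) for cid, m in members.items()}
    ).T
    means.index.name = "cluster"
    return ProfileClustering(
        pd.Series(assignments, name="cluster"), means,
        silhouette=float(best_score), members=members,
    )
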