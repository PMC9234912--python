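"""PCA-based sample ordination and deterministic heatmap ordering.

PCA runs on Z-scored features (correlation PCA): each feature has mean 0 /
SD 1 across samples, so the samples × features matrix is column-centered and
a plain SVD yields scores and per-component variance fractions.  Group
separation in the top-2 component plane is quantified with a silhouette
score.  Heatmap row ordering follows k-means pre-clustering with
average-linkage Euclidean hierarchical ordering within clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .types import OmicsMatrix, SampleMetadata, Scale

__all__ = ["PcaResult", "pca", "group_separation", "heatmap_order"]


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples × components
    variance_fraction: np.ndarray   # per retained component
    all_variance_fraction: np.ndarray  # every component (sums to 1)
    components_used: int


def pca(m: OmicsMatrix, n_components: int = 2) -> PcaResult:
    """SVD-based principal components of the samples × features matrix.

    Requires Z-scored input (features as unit-variance variables).  Sign
    convention: the largest-|loading| entry of each component is positive,
    which makes scores deterministic across BLAS implementations.
    """
    if m.scale != Scale.ZSCORE:
        raise ValueError("pca requires Z-scored input (scale=zscore)")
    if m.n_samples < 3:
        raise ValueError("pca needs at least 3 samples")
    max_comp = min(m.n_samples, m.n_features)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(dims)={max_comp}")
    x = m.values.T  # samples × features, columns centered by Z-score
    x = x - x.mean(axis=0, keepdims=True)  # guard against numerical drift
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| element of each component positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    total = (s ** 2).sum()
    frac = s ** 2 / total if total > 0 else np.zeros_like(s)
    scores = u[:, :n_components] * s[:n_components]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PcaResult(pd.DataFrame(scores, index=m.sample_ids, columns=cols),
                     frac[:n_components], frac, n_components)


def group_separation(result: PcaResult, meta: SampleMetadata) -> dict:
    """Silhouette of the group labels in PC1/PC2 space, plus group centroids.

    Returns a dict with ``separation`` ∈ [−1, 1] (larger = cleaner split) and
    per-group centroid coordinates; the quantitative stand-in for visual
    separation in a score plot.
    """
    pts = result.scores.iloc[:, :2].to_numpy()
    labels = meta.table.loc[result.scores.index, meta.group_col].astype(str).to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("need two groups for a separation score")
    sep = float(silhouette_score(pts, labels))
    centroids = {
        lev: result.scores.iloc[:, :2][labels == lev].mean(axis=0).tolist()
        for lev in dict.fromkeys(labels)
    }
    return {"separation": sep, "centroids": centroids}


def _hierarchical_order(x: np.ndarray) -> np.ndarray:
    if x.shape[0] <= 2:
        return np.arange(x.shape[0])
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="average")
    return np.asarray(hierarchy.leaves_list(link))


def heatmap_order(m: OmicsMatrix, k: int, seed: int = 0
                  ) -> tuple[list[str], dict[str, int], list[str]]:
    """Deterministic heatmap ordering: k-means rows, hierarchy within clusters.

    Rows are canonicalized (sorted by feature ID) before clustering, so the
    result is invariant to input row order.  Clusters are ordered by their
    centroid mean (ascending, ties by smallest member ID); within each
    cluster rows follow average-linkage Euclidean leaf order.  Columns are
    ordered by pure hierarchical clustering of the transpose.
    Returns (row order, row→cluster labels, column order).
    """
    if not 1 <= k <= m.n_features:
        raise ValueError(f"k must be in [1, n_features], got {k}")
    canon = m.data.sort_index(kind="mergesort")
    x = canon.to_numpy(dtype=float)
    ids = [str(i) for i in canon.index]

    if k == 1:
        labels = np.zeros(len(ids), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(x)

    # order clusters by centroid mean, tie-break by smallest member id
    cluster_keys = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        cluster_keys[c] = (float(x[members].mean()), min(ids[i] for i in members))
    cluster_order = sorted(cluster_keys, key=lambda c: cluster_keys[c])

    row_order: list[str] = []
    label_map: dict[str, int] = {}
    for rank, c in enumerate(cluster_order):
        members = np.flatnonzero(labels == c)
        sub = x[members]
        for idx in _hierarchical_order(sub):
            fid = ids[members[idx]]
            row_order.append(fid)
            label_map[fid] = rank

    col_canon = sorted(range(m.n_samples), key=lambda j: str(canon.columns[j]))
    xt = x[:, col_canon].T
    col_order = [str(canon.columns[col_canon[j]]) for j in _hierarchical_order(xt)]
    return row_order, label_map, col_order
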