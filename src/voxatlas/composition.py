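"""Clustering of brain regions by cell-type composition.

Regions are described by their vector of type densities (t- or me-),
normalized to fractions so region size does not dominate, embedded in 2D
and partitioned by K-means. The cluster count is chosen by the elbow
method on the within-cluster sum of squares (WCSS); two clusterings of
the same regions are compared through a row-normalized overlap matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import VoxAtlasError

__all__ = [
    "composition_matrix",
    "embed_2d",
    "elbow_kmeans",
    "overlap_matrix",
    "composition_profile",
]


def composition_matrix(densities: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Drop N/A rows and optionally convert densities to fractions."""
    m = densities.dropna(how="any")
    m = m[m.sum(axis=1) > 0]
    if normalize:
        m = m.div(m.sum(axis=1), axis=0)
    return m


def embed_2d(matrix: pd.DataFrame, seed: int = 0, method: str = "auto") -> pd.DataFrame:
    """Project the composition matrix to 2D.

    ``method='umap'`` uses a UMAP neighbor embedding (if umap-learn is
    importable), ``'pca'`` the first two principal components (exact and
    deterministic); ``'auto'`` prefers UMAP and falls back to PCA.
    Degenerate all-equal inputs are jittered with a warning.
    """
    if len(matrix) < 3:
        raise VoxAtlasError("need >= 3 regions to embed")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("all composition rows identical; jittering")
        X = X + np.random.default_rng(seed).normal(scale=1e-9, size=X.shape)
    if method == "auto":
        try:
            import umap  # noqa: F401

            method = "umap"
        except ImportError:
            method = "pca"
    if method == "umap":
        import umap

        emb = umap.UMAP(
            n_components=2, random_state=seed, n_neighbors=min(15, len(matrix) - 1)
        ).fit_transform(X)
    elif method == "pca":
        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise VoxAtlasError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=matrix.index, columns=["dim1", "dim2"])


def elbow_kmeans(
    points: pd.DataFrame, k_max: int = 10, seed: int = 0
) -> tuple[pd.Series, int, pd.Series]:
    """K-means over k = 1..k_max with elbow selection.

    The WCSS curve is non-increasing; the elbow is formalized as the k
    maximizing the second difference of WCSS (the point of sharpest
    diminishing returns). Returns (WCSS curve, chosen k, labels at k).
    """
    n = len(points)
    if k_max > n:
        warnings.warn(f"k_max={k_max} > {n} points; truncated")
        k_max = n
    X = points.to_numpy(dtype=float)
    wcss = {}
    labels_at = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        wcss[k] = float(km.inertia_)
        labels_at[k] = km.labels_
    curve = pd.Series(wcss, name="wcss")
    if k_max >= 3:
        second_diff = {
            k: curve[k - 1] - 2 * curve[k] + curve[k + 1] for k in range(2, k_max)
        }
        chosen = max(second_diff, key=second_diff.get)
    else:
        chosen = k_max
    labels = pd.Series(labels_at[chosen], index=points.index, name="cluster")
    return curve, chosen, labels


def overlap_matrix(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Percentage of regions of cluster A_i falling in cluster B_j.

    Entry (i, j) = 100·|A_i ∩ B_j| / |A_i|; rows sum to 100.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise VoxAtlasError("clusterings cover different region sets")
    tab = pd.crosstab(labels_a, labels_b.reindex(labels_a.index))
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def composition_profile(
    matrix: pd.DataFrame, region, threshold: float = 0.05
) -> list[tuple]:
    """Dominant types of one region: (type, fraction) with fraction
    strictly above ``threshold``, sorted descending."""
    row = matrix.loc[region].astype(float)
    total = row.sum()
    if total == 0:
        warnings.warn(f"region {region} has all-zero composition")
        return []
    frac = row / total
    keep = frac[frac > threshold].sort_values(ascending=False)
    return list(keep.items())
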