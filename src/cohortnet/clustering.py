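"""Subgroup detection: 2-D embedding, k-means sweep, silhouette decision.

High-dimensional standardised data are first projected to two dimensions
with nonmetric (Kruskal) multidimensional scaling, then partitioned with
k-means for each k in a sweep. Solution quality is scored with the mean
silhouette, and a maximum over k above 0.5 is taken as evidence that
discrete clusters exist. Two silhouette variants are available: the
classical Rousseeuw statistic (the default used for reporting) and a
centroid approximation — per sample, s = (b − a)/max(a, b) with a the
distance to the assigned centroid and b the distance to the nearest other
centroid — which runs in O(nk) but sits systematically above the classical
value. The variant is recorded in the sweep result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .preprocess import ZMatrix

__all__ = [
    "Embedding",
    "ClusterSweepResult",
    "mds_embed",
    "kmeans",
    "mean_silhouette",
    "cluster_sweep",
]


@dataclass
class Embedding:
    coordinates: np.ndarray  # n x 2
    stress: float  # Kruskal stress-1
    seed: int
    n_restarts: int


@dataclass
class ClusterSweepResult:
    embedding: Embedding
    ks: list[int]
    labels: dict[int, np.ndarray]
    centroids: dict[int, np.ndarray]
    mean_silhouettes: dict[int, float]
    threshold: float
    best_k: int
    clusters_present: bool
    silhouette_variant: str


def _as_matrix(z) -> np.ndarray:
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete data required")
    return x


def mds_embed(
    z: ZMatrix | np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 4,
    metric: bool = False,
    max_iter: int = 300,
) -> Embedding:
    """Nonmetric MDS of the pairwise Euclidean distances into ``dims`` axes.

    Minimises Kruskal stress-1 by SMACOF majorisation with monotone
    regression; the best of ``n_restarts`` random starts is kept.
    """
    x = _as_matrix(z)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    d = squareform(pdist(x))
    if np.allclose(d, 0):
        raise ValueError("all rows identical; embedding degenerate")
    mds = MDS(
        n_components=dims,
        metric_mds=metric,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        random_state=seed,
        normalized_stress=not metric,
        max_iter=max_iter,
        eps=1e-9,
    )
    coords = mds.fit_transform(d)
    return Embedding(
        coordinates=coords,
        stress=float(mds.stress_),
        seed=seed,
        n_restarts=n_restarts,
    )


def kmeans(
    embedding: Embedding | np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means on embedded coordinates; best of ``n_restarts``
    k-means++ starts by within-cluster sum of squares."""
    pts = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = pts.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points ({n})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(pts)
    return labels, km.cluster_centers_


def mean_silhouette(
    embedding: Embedding | np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
    variant: str = "centroid",
) -> float:
    """Mean silhouette of a partition.

    ``centroid`` (default): per sample, a = distance to own centroid,
    b = distance to nearest other centroid, s = (b − a)/max(a, b).
    ``classical``: Rousseeuw's pairwise-distance silhouette.
    """
    pts = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    labels = np.asarray(labels)
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if variant == "classical":
        return float(silhouette_score(pts, labels))
    if variant != "centroid":
        raise ValueError(f"unknown silhouette variant {variant!r}")
    # distance of each point to each centroid
    d = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=2)
    a = d[np.arange(len(labels)), labels]
    d_other = d.copy()
    d_other[np.arange(len(labels)), labels] = np.inf
    b = d_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def cluster_sweep(
    z: ZMatrix | np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
    n_restarts: int = 10,
    mds_restarts: int = 4,
    variant: str = "classical",
    embedding: Embedding | None = None,
) -> ClusterSweepResult:
    """Embed once, partition for each k in [k_min, k_max], and decide.

    ``clusters_present`` is True when the maximum mean silhouette over the
    sweep strictly exceeds ``threshold`` (default 0.5).
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    emb = embedding if embedding is not None else mds_embed(
        z, seed=seed, n_restarts=mds_restarts
    )
    ks = list(range(k_min, k_max + 1))
    labels: dict[int, np.ndarray] = {}
    centroids: dict[int, np.ndarray] = {}
    sils: dict[int, float] = {}
    for k in ks:
        lab, cen = kmeans(emb, k, n_restarts=n_restarts, seed=seed + k)
        labels[k] = lab
        centroids[k] = cen
        sils[k] = mean_silhouette(emb, lab, cen, variant=variant)
    best_k = max(ks, key=lambda k: sils[k])
    return ClusterSweepResult(
        embedding=emb,
        ks=ks,
        labels=labels,
        centroids=centroids,
        mean_silhouettes=sils,
        threshold=threshold,
        best_k=best_k,
        clusters_present=max(sils.values()) > threshold,
        silhouette_variant=variant,
    )
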