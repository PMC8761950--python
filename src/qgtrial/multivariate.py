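"""Multivariate structure of genotype means: PCA, k-means, silhouette widths.

PCA is the eigen-decomposition of the trait correlation matrix (standardized
genotype means), so eigenvalues sum to the number of traits. Clustering is
Lloyd's algorithm from k-means++ starts, minimizing the within-cluster
sum-of-squares objective

    J = sum_j sum_{i in cluster j} ||x_i - c_j||^2

with Euclidean distance throughout, and is validated by silhouette widths
S(i) = (b_i - a_i) / max(a_i, b_i) in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "GenotypeMeansMatrix",
    "PCAResult",
    "ClusterResult",
    "genotype_means",
    "pca",
    "kmeans",
    "silhouette_widths",
]


@dataclass(frozen=True)
class GenotypeMeansMatrix:
    genotype_ids: list[str]
    trait_names: list[str]
    values: np.ndarray  # genotypes x traits
    standardized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.trait_names)


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray
    variance_percent: np.ndarray
    cumulative_percent: np.ndarray
    loadings: np.ndarray  # traits x components
    scores: np.ndarray  # genotypes x components

    def to_frame(self) -> pd.DataFrame:
        comps = [f"PC{i + 1}" for i in range(len(self.eigenvalues))]
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "variance_percent": self.variance_percent,
                "cumulative_percent": self.cumulative_percent,
            },
            index=comps,
        )


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    objective_j: float
    silhouette: np.ndarray | None
    cluster_mean_silhouette: np.ndarray | None


def genotype_means(table: pd.DataFrame, standardize: bool = True) -> GenotypeMeansMatrix:
    """Per-genotype means over blocks, optionally column-standardized (ddof=1)."""
    wide = table.pivot_table(index="genotype", columns="trait", values="value", aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("table has missing (genotype, trait) combinations")
    values = wide.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        degenerate = ~(sd > 0)
        if degenerate.any():
            bad = [t for t, d in zip(wide.columns, degenerate) if d]
            raise ValueError(f"cannot standardize zero-variance trait(s): {bad}")
        values = (values - values.mean(axis=0)) / sd
    return GenotypeMeansMatrix(
        genotype_ids=list(wide.index),
        trait_names=list(wide.columns),
        values=values,
        standardized=bool(standardize),
    )


def pca(m: GenotypeMeansMatrix) -> PCAResult:
    """Correlation-matrix PCA of standardized genotype means.

    Components are ordered by decreasing eigenvalue; each loading vector is
    flipped so its largest-magnitude entry is positive (sign convention).
    """
    if not m.standardized:
        raise ValueError("pca expects a standardized genotype-means matrix")
    if len(m.genotype_ids) < 2:
        raise ValueError("need at least 2 genotypes")
    corr = np.corrcoef(m.values, rowvar=False)
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(vec.shape[1])])
    flip[flip == 0] = 1.0
    vec = vec * flip
    pct = 100.0 * lam / lam.sum()
    return PCAResult(
        eigenvalues=lam,
        variance_percent=pct,
        cumulative_percent=np.cumsum(pct),
        loadings=vec,
        scores=m.values @ vec,
    )


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    closest = np.full(n, np.inf)
    for j in range(1, k):
        closest = np.minimum(closest, ((x - centroids[j - 1]) ** 2).sum(axis=1))
        total = closest.sum()
        if total <= 0:
            centroids[j:] = x[rng.integers(n, size=k - j)]
            break
        centroids[j] = x[rng.choice(n, p=closest / total)]
    return centroids


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    prev_j = np.inf
    assign = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d2 = cdist(x, centroids, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        # Empty-cluster repair: reseed at the point farthest from its centroid.
        for j in range(len(centroids)):
            if not (assign == j).any():
                far = int(d2[np.arange(len(x)), assign].argmax())
                centroids[j] = x[far]
                assign[far] = j
        obj = float(((x - centroids[assign]) ** 2).sum())
        if obj > prev_j + 1e-9 * max(1.0, prev_j):
            raise RuntimeError("k-means objective increased between Lloyd iterations")
        new = np.array(
            [x[assign == j].mean(axis=0) for j in range(len(centroids))]
        )
        if np.allclose(new, centroids):
            prev_j = obj
            break
        centroids = new
        prev_j = obj
    return assign, centroids, prev_j


def kmeans(
    m: GenotypeMeansMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """Best-of-``n_restarts`` Lloyd's k-means from k-means++ initialization.

    Deterministic given the seed. Silhouette widths are attached whenever the
    final partition has at least two non-empty clusters.
    """
    x = m.values if isinstance(m, GenotypeMeansMatrix) else np.asarray(m, dtype=float)
    if k < 1 or k > len(x):
        raise ValueError("k must lie in [1, number of points]")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(max(1, n_restarts)):
        assign, cent, obj = _lloyd(x, _kmeans_pp_init(x, k, rng))
        if best is None or obj < best[2]:
            best = (assign, cent, obj)
    assert best is not None
    assign, cent, obj = best
    sil = cluster_sil = None
    if len(np.unique(assign)) >= 2:
        sil, cluster_sil = silhouette_widths(x, assign)
    return ClusterResult(
        k=k,
        assignments=assign,
        centroids=cent,
        objective_j=obj,
        silhouette=sil,
        cluster_mean_silhouette=cluster_sil,
    )


def silhouette_widths(
    m: GenotypeMeansMatrix | np.ndarray, assignments: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point silhouette widths and per-cluster means (Euclidean distance).

    a_i is the mean distance to the point's own cluster (excluding itself),
    b_i the smallest mean distance to another cluster; singleton clusters get
    S_i = 0 by convention.
    """
    x = m.values if isinstance(m, GenotypeMeansMatrix) else np.asarray(m, dtype=float)
    assign = np.asarray(assignments)
    labels = np.unique(assign)
    if len(labels) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    d = cdist(x, x)
    n = len(x)
    s = np.zeros(n)
    for i in range(n):
        own = assign == assign[i]
        if own.sum() == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, assign == lab].mean() for lab in labels if lab != assign[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    cluster_means = np.array([s[assign == lab].mean() for lab in labels])
    return s, cluster_means
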