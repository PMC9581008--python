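"""Sample-level clustering of immunosignatures.

Each sample (array) is a point in peptide space: its per-peptide
intensities are coordinates in an N-dimensional space.  Dendrograms use
the rank-cutoff peptide subset (so N is the cutoff); agglomerative and
k-means clustering for the PCA cluster plots use ALL peptides with no
subset restriction.  Hierarchical clustering is UPGMA (average linkage,
Euclidean distance) cut at the first bifurcation into two clusters;
k-means is run with k = 2 because samples come from two cohorts.
Clustering quality is scored with the Davies-Bouldin, Silhouette and
Calinski-Harabasz indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .arrayio import SynopticTable
from .preprocess import IntensityMatrix


@dataclass
class SampleVectors:
    """Samples as points in peptide space (rows = samples)."""

    sample_ids: list[str]
    cohorts: list[str]
    peptide_ids: list[str]
    coordinates: np.ndarray  # shape (n_samples, n_peptides)

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]

    @property
    def dimension(self) -> int:
        return self.coordinates.shape[1]


def sample_vectors(
    source: IntensityMatrix | SynopticTable, peptide_subset=None
) -> SampleVectors:
    """Build sample points from a matrix or synoptic table.

    ``peptide_subset`` (a list of peptide/spot IDs, e.g. from the
    rank-cutoff selection) restricts and orders the coordinate axes; by
    default all peptides are used.
    """
    if isinstance(source, SynopticTable):
        values = source.sample_values()  # peptides x samples
        cohorts = {s: "control" for s in source.control_samples}
        cohorts |= {s: "treatment" for s in source.treatment_samples}
    else:
        values = source.values
        cohorts = source.cohorts
    if peptide_subset is not None:
        missing = [p for p in peptide_subset if p not in values.index]
        if missing:
            raise ValueError(f"peptides not present: {missing[:20]}")
        values = values.loc[list(peptide_subset)]
    sample_ids = list(values.columns)
    return SampleVectors(
        sample_ids=sample_ids,
        cohorts=[cohorts[s] for s in sample_ids],
        peptide_ids=list(values.index),
        coordinates=values.to_numpy(dtype=float).T,
    )


@dataclass
class ClusterResult:
    sample_ids: list[str]
    labels: np.ndarray  # 0/1 cluster index per sample
    method: str  # "upgma_cut" | "kmeans"
    linkage_tree: np.ndarray | None = None  # scipy linkage matrix (UPGMA)
    centers: np.ndarray | None = None  # (kmeans)
    inertia: float | None = None
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def upgma_tree(points: SampleVectors) -> ClusterResult:
    """UPGMA (average linkage, Euclidean) dendrogram plus 2-cluster cut.

    The returned labels come from cutting at the root's first
    bifurcation; the full merge tree (scipy linkage matrix, with
    non-decreasing merge heights) is attached for dendrogram rendering.
    """
    if points.n_samples < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    Z = linkage(points.coordinates, method="average", metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust") - 1
    return ClusterResult(
        sample_ids=points.sample_ids, labels=labels, method="upgma_cut", linkage_tree=Z
    )


def kmeans2(points: SampleVectors, seed: int = 0, n_restarts: int = 10) -> ClusterResult:
    """k-means with k fixed at 2: Lloyd's algorithm, seeded random restarts.

    The best of ``n_restarts`` runs (lowest within-cluster sum of
    squares) is kept; results are deterministic given the seed.  With
    fewer than 2 distinct points the clustering is degenerate and all
    samples get one label, with a warning.
    """
    if points.n_samples < 2:
        raise ValueError("k-means needs at least 2 samples")
    X = points.coordinates
    if np.unique(X, axis=0).shape[0] < 2:
        warnings.warn("fewer than 2 distinct points; returning a single cluster")
        return ClusterResult(
            sample_ids=points.sample_ids,
            labels=np.zeros(points.n_samples, dtype=int),
            method="kmeans",
            seed=seed,
        )
    km = KMeans(
        n_clusters=2,
        init="random",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return ClusterResult(
        sample_ids=points.sample_ids,
        labels=km.labels_.astype(int),
        method="kmeans",
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
    )


def pca_embed(points: SampleVectors) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA scores on the first two axes.

    Returns (coords, explained) where coords is (n_samples, 2) and
    explained the variance fractions of the two axes.  When the point
    cloud has rank < 2 the missing axis is zero-filled.
    """
    X = points.coordinates
    n_comp = min(2, X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    n_comp = max(n_comp, 1)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    coords = np.zeros((X.shape[0], 2))
    coords[:, :scores.shape[1]] = scores
    explained = np.zeros(2)
    explained[:pca.explained_variance_ratio_.size] = pca.explained_variance_ratio_
    # drop numerically-null axes (rank deficiency)
    for k in range(scores.shape[1]):
        if pca.explained_variance_[k] < 1e-12 * max(pca.explained_variance_[0], 1e-300):
            coords[:, k] = 0.0
            explained[k] = 0.0
    return coords, explained


@dataclass
class QualityIndices:
    """Internal clustering-quality scores (Euclidean metric throughout).

    Any index that is undefined for the given partition (e.g.
    Davies-Bouldin with coincident cluster centroids, or indices on a
    degenerate one-cluster labeling) is reported as NaN rather than
    raising.
    """

    davies_bouldin: float
    silhouette: float
    calinski_harabasz: float

    def as_dict(self) -> dict[str, float]:
        return {
            "davies_bouldin": self.davies_bouldin,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
        }


def quality_indices(points: SampleVectors, labels) -> QualityIndices:
    X = points.coordinates
    labels = np.asarray(labels)

    # coincident cluster centroids make the Davies-Bouldin ratio diverge;
    # report it as unavailable instead of a library's arbitrary fallback
    centroids = np.array([X[labels == lab].mean(axis=0) for lab in np.unique(labels)])
    db_degenerate = False
    if centroids.shape[0] >= 2:
        for i in range(centroids.shape[0]):
            for j in range(i + 1, centroids.shape[0]):
                if np.allclose(centroids[i], centroids[j]):
                    db_degenerate = True

    def _safe(fn) -> float:
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v = float(fn(X, labels))
            return v if np.isfinite(v) else float("nan")
        except ValueError:
            return float("nan")

    return QualityIndices(
        davies_bouldin=float("nan") if db_degenerate else _safe(davies_bouldin_score),
        silhouette=_safe(silhouette_score),
        calinski_harabasz=_safe(calinski_harabasz_score),
    )


def quality_table(points: SampleVectors, results) -> pd.DataFrame:
    """Method x index table for a collection of ClusterResults."""
    rows = []
    for res in results:
        qi = quality_indices(points, res.labels)
        rows.append({"method": res.method, **qi.as_dict()})
    return pd.DataFrame(rows)
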