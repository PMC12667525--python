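"""Treatment-similarity profiling: mean-feature heatmaps, k-means phenotypes.

Two complementary treatment-similarity views are computed from the scaled
feature matrix:

1. *Mean-feature similarity*: each treatment is summarised by the mean
   z-scored feature vector of its organoids, and treatments are compared by
   the Pearson correlation of these vectors.
2. *Phenotype-composition similarity*: organoids are clustered by k-means
   into phenotypic groups (k selected by mean silhouette when not fixed),
   each treatment is summarised by the percentage of its organoids in each
   cluster, and treatments are compared by the Pearson correlation of these
   composition rows.

Both similarity matrices carry a hierarchical-clustering leaf order
(average linkage on distance 1 - r) for heatmap display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentProfile",
    "SimilarityMatrix",
    "ClusterModel",
    "treatment_profiles",
    "pearson_similarity",
    "fit_kmeans",
    "cluster_composition",
    "composition_similarity",
]


@dataclass(frozen=True)
class TreatmentProfile:
    """Mean z-scored feature vector of one treatment's organoids."""

    treatment: str
    mean_z_features: pd.Series
    n_organoids: int


@dataclass
class SimilarityMatrix:
    """Symmetric treatment x treatment Pearson correlation matrix.

    ``r`` is indexed and columned by treatment label; ``ordering`` is the
    leaf order from average-linkage hierarchical clustering on 1 - r,
    suitable for heatmap display. Treatments whose profile vector had zero
    variance get correlation 0 against everything (flagged, not dropped).
    """

    r: pd.DataFrame
    ordering: list[str]
    flagged: list[str]

    @property
    def labels(self) -> list[str]:
        return list(self.r.index)

    def reordered(self) -> pd.DataFrame:
        return self.r.loc[self.ordering, self.ordering]


@dataclass
class ClusterModel:
    """Fitted k-means phenotype model with k-selection diagnostics."""

    k: int
    centroids: np.ndarray
    assignment: pd.Series  # cluster id per organoid_id
    inertia: float
    k_diagnostics: pd.DataFrame  # columns: k, mean_silhouette, inertia
    seed: int


def treatment_profiles(matrix: FeatureMatrix) -> list[TreatmentProfile]:
    """Per-treatment arithmetic mean of the z-scored selected features."""
    if not matrix.scaled:
        raise ValueError("treatment profiles require a scaled matrix")
    treatments = matrix.labels["treatment"]
    if treatments.nunique() < 2:
        raise ValueError("need at least 2 treatments")
    profiles = []
    for label, idx in sorted(treatments.groupby(treatments).groups.items()):
        sub = matrix.selected().loc[idx]
        if len(sub) == 0:
            raise ValueError(f"treatment {label!r} has no organoids")
        profiles.append(
            TreatmentProfile(
                treatment=str(label),
                mean_z_features=sub.mean(axis=0),
                n_organoids=len(sub),
            )
        )
    return profiles


def _pearson_matrix(vectors: pd.DataFrame) -> SimilarityMatrix:
    """Pearson correlation between rows, with zero-variance rows flagged."""
    labels = list(vectors.index)
    if len(labels) < 2 or vectors.shape[1] < 2:
        raise ValueError("need >= 2 treatments and >= 2 features/clusters")
    x = vectors.to_numpy(dtype=np.float64)
    sd = x.std(axis=1)
    flagged = [labels[i] for i in np.nonzero(sd == 0)[0]]
    if flagged:
        logger.warning(
            "zero-variance profile vectors, correlations set to 0: %s", flagged
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    rdf = pd.DataFrame(r, index=labels, columns=labels)
    dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
    order = [labels[i] for i in leaves_list(average(dist))]
    return SimilarityMatrix(r=rdf, ordering=order, flagged=flagged)


def pearson_similarity(profiles: list[TreatmentProfile]) -> SimilarityMatrix:
    """Treatment similarity from mean-feature vectors."""
    vectors = pd.DataFrame(
        {p.treatment: p.mean_z_features for p in profiles}
    ).T
    return _pearson_matrix(vectors)


def fit_kmeans(
    matrix: FeatureMatrix,
    k: int | str = "auto",
    seed: int = 0,
    k_range: tuple[int, int] = (2, 12),
    n_init: int = 10,
) -> ClusterModel:
    """Cluster organoids into phenotypic groups with k-means.

    Lloyd's algorithm with k-means++ initialisation and ``n_init`` restarts.
    With ``k="auto"``, k maximising the mean silhouette over ``k_range`` is
    chosen (ties broken toward smaller k, for parsimony). Deterministic
    under ``seed``.
    """
    if not matrix.scaled:
        raise ValueError("k-means requires a scaled matrix")
    x = matrix.selected().to_numpy(dtype=np.float64)
    n = x.shape[0]

    def _fit(kk: int) -> KMeans:
        if kk > n:
            raise ValueError(f"k={kk} exceeds the number of organoids ({n})")
        return KMeans(
            n_clusters=kk, init="k-means++", n_init=n_init, random_state=seed
        ).fit(x)

    diagnostics = []
    if k == "auto":
        best_k, best_sil, best_model = None, -np.inf, None
        k_lo, k_hi = k_range
        for kk in range(k_lo, min(k_hi, n - 1) + 1):
            model = _fit(kk)
            sil = float(silhouette_score(x, model.labels_))
            diagnostics.append(
                {"k": kk, "mean_silhouette": sil, "inertia": float(model.inertia_)}
            )
            if sil > best_sil:  # strict: ties keep the smaller k
                best_k, best_sil, best_model = kk, sil, model
        k_final, model = best_k, best_model
    else:
        k_final = int(k)
        if k_final < 2:
            raise ValueError("k must be >= 2")
        model = _fit(k_final)
        sil = float(silhouette_score(x, model.labels_)) if k_final < n else np.nan
        diagnostics.append(
            {"k": k_final, "mean_silhouette": sil, "inertia": float(model.inertia_)}
        )
    return ClusterModel(
        k=int(k_final),
        centroids=model.cluster_centers_,
        assignment=pd.Series(model.labels_, index=matrix.values.index, name="cluster"),
        inertia=float(model.inertia_),
        k_diagnostics=pd.DataFrame(diagnostics),
        seed=seed,
    )


def cluster_composition(
    model: ClusterModel, labels: pd.DataFrame
) -> pd.DataFrame:
    """Percentage of each treatment's organoids in each phenotype cluster.

    Rows are treatments, columns cluster ids; every row sums to 100.
    """
    if not model.assignment.index.equals(labels.index):
        missing = labels.index.difference(model.assignment.index).tolist()
        raise ValueError(f"organoids without cluster assignment: {missing}")
    df = pd.DataFrame(
        {"treatment": labels["treatment"], "cluster": model.assignment}
    )
    counts = (
        df.groupby(["treatment", "cluster"], sort=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=range(model.k), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def composition_similarity(table: pd.DataFrame) -> SimilarityMatrix:
    """Treatment similarity from phenotype-cluster composition rows."""
    return _pearson_matrix(table)
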