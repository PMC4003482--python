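"""Trajectory clustering, diet-dependence classification, and PCA.

Scaled trajectories are grouped by complete-linkage agglomerative
clustering on Euclidean distance with the tree cut into exactly k
groups (k-means is available as an alternative mode).  Each cluster's
mean trajectory per diet summarizes its members; clusters are then
classified by how their levels differ between diets across ages:

* independent  -- no age shows a diet difference;
* progressive  -- every age does;
* intermittent -- some, but not all, ages do.

A diet difference at an age requires both statistical significance
(Student t test on the cluster-mean replicate values, p < alpha) and a
minimal effect size (the cluster-mean log10 difference exceeding a
fold-change floor, default twofold).  The effect-size floor keeps the
call about biologically meaningful level differences: with many member
features the replicate standard error becomes arbitrarily small, and
bare t tests would flag the subtle timing differences that delayed
remodeling produces in every cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import FeatureTable
from .trajectories import TrajectoryMatrix

__all__ = [
    "ClusterSet",
    "DependenceSummary",
    "hierarchical_clusters",
    "cluster_mean_trajectory",
    "classify_diet_dependence",
    "dependence_frequencies",
    "pca_project",
]


@dataclass
class ClusterSet:
    """Feature -> cluster assignments (cluster ids 1..k)."""

    k: int
    assignments: pd.Series
    linkage_matrix: np.ndarray | None = None
    classification: pd.DataFrame | None = None  # per-cluster dependence calls

    def members(self, cluster_id: int) -> pd.Index:
        ids = self.assignments.index[self.assignments == cluster_id]
        if len(ids) == 0:
            raise KeyError(f"cluster {cluster_id} is empty")
        return ids

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


@dataclass(frozen=True)
class DependenceSummary:
    """Feature-weighted fractions of the three diet-dependence classes."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("dependence fractions must sum to 1")


def hierarchical_clusters(
    scaled: pd.DataFrame | TrajectoryMatrix,
    k: int = 12,
    method: str = "hierarchical",
) -> ClusterSet:
    """Cut a complete-linkage Euclidean tree into exactly k clusters.

    ``scaled`` is features x variables (for a TrajectoryMatrix, the
    diets' age columns concatenated).  Deterministic given input order.
    ``method='kmeans'`` substitutes k-means with a fixed seed for
    comparison.
    """
    if isinstance(scaled, TrajectoryMatrix):
        scaled = scaled.concatenated()
    n = len(scaled)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} features available")
    arr = scaled.to_numpy(float)
    if np.any(arr.std(axis=1) == 0):
        raise ValueError("constant rows must be excluded before clustering")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(arr)
        labels = km.labels_ + 1
        return ClusterSet(k, pd.Series(labels, index=scaled.index, name="cluster"))
    if method != "hierarchical":
        raise ValueError(f"unknown clustering method {method!r}")
    Z = linkage(arr, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterSet(k, pd.Series(labels, index=scaled.index, name="cluster"), Z)


def cluster_mean_trajectory(
    clusters: ClusterSet, matrix: TrajectoryMatrix
) -> dict[str, pd.DataFrame]:
    """Unweighted mean trajectory of each cluster per diet."""
    out: dict[str, pd.DataFrame] = {}
    for diet, m in matrix.data.items():
        missing = clusters.assignments.index.difference(m.index)
        if len(missing):
            raise KeyError(f"assignments cover features absent from the matrix: {list(missing)[:5]}")
        sub = m.loc[clusters.assignments.index]
        out[diet] = sub.groupby(clusters.assignments).mean()
    return out


def classify_diet_dependence(
    clusters: ClusterSet,
    table: FeatureTable,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    level: str = "cluster",
) -> pd.DataFrame:
    """Classify clusters (or single features) as independent /
    progressive / intermittent.

    At each age, member features' log10 intensities are averaged per
    sample, giving one cluster-mean value per replicate per diet; the
    diets are compared with a Student t test.  An age counts as
    different when p < alpha and the absolute cluster-mean log10
    difference is at least log10(min_fold).  Requires two diets with
    >= 2 replicates at every age.
    """
    diets = table.diets
    if len(diets) != 2:
        raise ValueError("needs exactly two diets")
    units = (
        {c: clusters.members(c) for c in clusters.sizes().index}
        if level == "cluster"
        else {fid: pd.Index([fid]) for fid in clusters.assignments.index}
    )
    arrs = {}
    for d in diets:
        arr = table.design_array(d)
        if arr.shape[2] < 2:
            raise ValueError("need >= 2 replicates per age")
        arrs[d] = arr
    idx = pd.Index(table.feature_ids)
    ages = table.ages
    rows = []
    for unit, members in units.items():
        pos = idx.get_indexer(members)
        if (pos < 0).any():
            raise KeyError("cluster member missing from the table")
        vals = {}
        for d in diets:
            sub = arrs[d][pos]
            if (sub <= 0).any():
                raise ValueError("classification needs features detected in all samples")
            vals[d] = np.log10(sub).mean(axis=0)  # (n_ages, n_reps)
        tt = stats.ttest_ind(vals[diets[1]], vals[diets[0]], axis=1)
        delta = vals[diets[1]].mean(axis=1) - vals[diets[0]].mean(axis=1)
        different = (tt.pvalue < alpha) & (np.abs(delta) >= math.log10(min_fold))
        if different.all():
            cls = "progressive"
        elif different.any():
            cls = "intermittent"
        else:
            cls = "independent"
        row = {"unit": unit, "class": cls, "n_features": len(members)}
        for j, a in enumerate(ages):
            row[f"p_age_{a:g}"] = tt.pvalue[j]
            row[f"delta_log10_age_{a:g}"] = delta[j]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("unit")
    if level == "cluster":
        clusters.classification = out
    return out


def dependence_frequencies(clusters: ClusterSet) -> DependenceSummary:
    """Feature-weighted fractions of dependence classes over clusters."""
    cls = clusters.classification
    if cls is None or cls["class"].isna().any():
        raise ValueError("classify_diet_dependence must run first")
    weighted = cls.groupby("class")["n_features"].sum()
    total = weighted.sum()
    fractions = {c: float(weighted.get(c, 0)) / total for c in ("independent", "progressive", "intermittent")}
    return DependenceSummary(fractions)


def pca_project(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples (rows = observations, columns = scaled features).

    Returns (scores frame, explained-variance ratios).  Sign
    convention: each component's first nonzero loading is positive, so
    scores are reproducible across feature orderings.
    """
    arr = matrix.to_numpy(float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in PCA input")
    n_components = min(n_components, *arr.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(arr)
    evr0 = pca.explained_variance_ratio_[0]
    if not np.isfinite(evr0) or evr0 == 0:
        raise ValueError("degenerate (rank-0) input")
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        nz = np.nonzero(np.abs(load) > 1e-12)[0]
        if len(nz) and load[nz[0]] < 0:
            scores[:, j] *= -1
            pca.components_[j] *= -1
    frame = pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{j + 1}" for j in range(scores.shape[1])]
    )
    return frame, pca.explained_variance_ratio_
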