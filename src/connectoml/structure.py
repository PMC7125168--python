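"""Unsupervised structure checks: z-scoring, two-way hierarchical clustering
and PCA summaries.

These mirror the exploratory arm of the discovery framework: heatmap-style
two-way clustering of the z-scored edge matrix (participants and edges each
get a Ward dendrogram, and the k=2 participant cut is compared against the
diagnosis labels) and PCA score / explained-variance summaries at the three
stages of the funnel — all edges, univariate-significant edges, and the
machine-learning-selected edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .dataset import ConnectomeDataset

__all__ = ["zscore_edges", "ClusteringReport", "hierarchical_clusters", "PCAReport", "pca_report"]

STAGES = ("all_edges", "significant", "selected")


def zscore_edges(X) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each edge column to mean 0, sample SD 1 (ddof=1).

    Returns ``(Z, zero_variance_mask)``; constant columns come back all-zero
    and flagged instead of dividing by zero.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 subjects")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (X - mu) / safe_sd
    z[:, zero_var] = 0.0
    return z, zero_var


@dataclass
class ClusteringReport:
    """Two-way Ward clustering of the z-scored matrix, scored against labels."""

    participant_linkage: np.ndarray  # scipy merge table (n-1, 4)
    edge_linkage: np.ndarray | None
    assignments: np.ndarray  # cluster id in {0..k-1} per subject
    confusion: pd.DataFrame  # cluster × label counts
    misplaced_per_label: dict[str, int]
    n_misplaced: int
    ari: float  # adjusted Rand index vs the labels


def hierarchical_clusters(
    dataset: ConnectomeDataset, k: int = 2, cluster_edges: bool = True
) -> ClusteringReport:
    """Ward/Euclidean clustering of subjects (and edges) on z-scored data.

    The k-cluster participant cut is cross-tabulated against the group
    labels; the misplaced count uses the cluster→label matching that
    maximises agreement, reproducing the "n participants ended up in the
    other group's cluster" reading of a clustered heatmap.
    """
    n = dataset.n_subjects
    if not 1 <= k <= n:
        raise ValueError(f"k={k} invalid for {n} subjects")
    z, _ = zscore_edges(dataset.X)
    part_link = hierarchy.linkage(z, method="ward", metric="euclidean")
    edge_link = None
    if cluster_edges and dataset.n_edges >= 2:
        edge_link = hierarchy.linkage(z.T, method="ward", metric="euclidean")
    if k == 1:
        assign = np.zeros(n, dtype=int)
    else:
        assign = hierarchy.fcluster(part_link, t=k, criterion="maxclust") - 1
    label_names = np.array([dataset.group_names[y] for y in dataset.labels])
    confusion = pd.crosstab(
        pd.Series(assign, name="cluster"), pd.Series(label_names, name="group")
    )
    # best assignment of clusters to labels (k=2: try both pairings)
    counts = confusion.reindex(columns=list(dataset.group_names), fill_value=0)
    best = None
    if k == 2 and counts.shape[0] == 2:
        for perm in ((0, 1), (1, 0)):
            agree = counts.iloc[0, perm[0]] + counts.iloc[1, perm[1]]
            if best is None or agree > best[0]:
                best = (agree, perm)
        _, perm = best
        misplaced = {
            dataset.group_names[perm[0]]: int(counts.iloc[1, perm[0]]),
            dataset.group_names[perm[1]]: int(counts.iloc[0, perm[1]]),
        }
    else:
        # majority label per cluster
        misplaced = {g: 0 for g in dataset.group_names}
        for c in counts.index:
            row = counts.loc[c]
            major = row.idxmax()
            for g in dataset.group_names:
                if g != major:
                    misplaced[g] += int(row[g])
    return ClusteringReport(
        participant_linkage=part_link,
        edge_linkage=edge_link,
        assignments=assign,
        confusion=confusion,
        misplaced_per_label=misplaced,
        n_misplaced=int(sum(misplaced.values())),
        ari=float(adjusted_rand_score(dataset.labels, assign)),
    )


@dataclass
class PCAReport:
    """PCA scores and explained variance at one stage of the funnel."""

    stage: str  # all_edges | significant | selected
    scores: pd.DataFrame  # subjects × PC1..PCk
    explained_pct: np.ndarray  # percent variance per component, non-increasing

    def leading_pct(self, n: int = 2) -> float:
        return float(self.explained_pct[:n].sum())


def pca_report(dataset: ConnectomeDataset, n_components: int = 2, stage: str = "all_edges") -> PCAReport:
    """PCA of the z-scored edge matrix (full SVD, deterministic sign).

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    n = dataset.n_subjects
    max_k = min(n - 1, dataset.n_edges)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components={n_components} invalid; at most {max_k}")
    z, _ = zscore_edges(dataset.X)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    for a in range(n_components):
        lead = np.argmax(np.abs(pca.components_[a]))
        if pca.components_[a, lead] < 0:
            pca.components_[a] *= -1
            scores[:, a] *= -1
    frame = pd.DataFrame(
        scores,
        index=pd.Index(dataset.subject_ids, name="subject_id"),
        columns=[f"PC{a + 1}" for a in range(n_components)],
    )
    frame.insert(0, "group", [dataset.group_names[y] for y in dataset.labels])
    return PCAReport(
        stage=stage,
        scores=frame,
        explained_pct=100.0 * pca.explained_variance_ratio_,
    )
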