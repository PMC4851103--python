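"""Hierarchical clustering, cophenetic correlation, S_Dbw, and NMI.

The pipeline clusters feature-matrix rows with agglomerative hierarchical
clustering: Euclidean distance between objects, average linkage (UPGMA)
between clusters. Two scalar diagnostics drive the window-size search:

* the cophenetic correlation coefficient (CCC) — the Pearson correlation
  between the original pairwise distances and the cophenetic distances read
  off the dendrogram; values near 1 mean the tree represents the data
  faithfully, and a threshold on CCC gates which window sizes are worth
  scoring;
* the S_Dbw validity index — intra-cluster scattering plus inter-cluster
  density; lower is better, and its minimum over candidate partition counts
  picks the number of groups.

Clusterings are plain integer label vectors with labels 1..k, every label
non-empty.
"""

from __future__ import annotations

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import normalized_mutual_info_score

from .windows import FeatureMatrix


def _as_matrix(FV) -> np.ndarray:
    X = FV.values if isinstance(FV, FeatureMatrix) else np.asarray(FV, float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    return X


def linkage_average(FV) -> np.ndarray:
    """UPGMA (average-linkage) tree over Euclidean row distances.

    Returns a scipy linkage matrix (n-1 merges with heights); heights are
    monotone non-decreasing for average linkage on a metric.
    """
    X = _as_matrix(FV)
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 objects to cluster, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return sch.linkage(X, method="average", metric="euclidean")


def cophenetic_distances(tree: np.ndarray) -> np.ndarray:
    """Condensed vector of cophenetic distances t(O_i, O_j) from a tree."""
    return sch.cophenet(tree)


def cophenetic_correlation(FV, tree: np.ndarray) -> float:
    """Cophenetic correlation coefficient (CCC) of a dendrogram.

    Pearson correlation between the n(n-1)/2 original Euclidean distances
    x(O_i, O_j) and the cophenetic distances t(O_i, O_j) — how faithfully
    the dendrogram maintains the original pairwise distances.
    """
    X = _as_matrix(FV)
    n = X.shape[0]
    if n < 3:
        raise ValueError("CCC needs at least 3 objects")
    x = pdist(X)
    t = cophenetic_distances(tree)
    if np.std(x) == 0 or np.std(t) == 0:
        raise ValueError("CCC undefined: zero variance in a distance vector")
    xc = x - x.mean()
    tc = t - t.mean()
    return float((xc @ tc) / np.sqrt((xc @ xc) * (tc @ tc)))


def cut_tree(tree: np.ndarray, k: int) -> np.ndarray:
    """Cut the dendrogram into k groups (remove the k-1 highest links).

    Labels are integers 1..k assigned in order of first appearance along
    the object (time) axis.
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    raw = sch.cut_tree(tree, n_clusters=k).ravel()
    return relabel_first_appearance(raw)


def relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k in order of first appearance."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=np.int64)


def _validate_clustering(X: np.ndarray, labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length does not match number of objects")
    k = int(labels.max())
    present = np.unique(labels)
    if labels.min() < 1 or len(present) != k:
        raise ValueError("labels must be 1..k with every group non-empty")
    return k


def s_dbw(FV, labels: np.ndarray, stdev_variant: str = "printed") -> float:
    """S_Dbw cluster validity index (lower is better).

    ``S_Dbw(k) = Scat(k) + Dens_bw(k)`` with

    * ``Scat(k) = (1/k) sum_i ||sigma(G_i)|| / ||sigma(DS)||`` where
      ``sigma`` is the per-dimension population variance vector and
      ``||.||`` the Euclidean norm (singletons contribute a zero vector);
    * ``Dens_bw(k)`` averages, over ordered cluster pairs, the point density
      at the midpoint of the two cluster centers relative to the larger of
      the two clusters' own densities. ``density(G)`` counts members within
      a neighborhood radius of the center; for a pair the members of both
      clusters are counted around the midpoint. A pair whose own densities
      are both zero contributes 0 (both clusters are ultra-tight relative
      to the radius, so inter-cluster density is vacuously 0).

    The neighborhood radius is ``(1/k) * sqrt(sum_i ||sigma(G_i)||)``
    (``stdev_variant="printed"``); ``stdev_variant="mean"`` uses
    ``sqrt((1/k) * sum_i ||sigma(G_i)||)`` instead.
    """
    X = _as_matrix(FV)
    labels = np.asarray(labels)
    k = _validate_clustering(X, labels)
    if k < 2:
        raise ValueError("S_Dbw needs k >= 2 clusters")
    norm_ds = float(np.linalg.norm(X.var(axis=0)))
    if norm_ds == 0:
        raise ValueError("degenerate dataset: zero variance in every dimension")

    members = [X[labels == i + 1] for i in range(k)]
    centers = np.stack([m.mean(axis=0) for m in members])
    sigma_norms = np.array([np.linalg.norm(m.var(axis=0)) for m in members])

    scat = float(sigma_norms.mean() / norm_ds)

    total = float(sigma_norms.sum())
    if stdev_variant == "printed":
        radius = np.sqrt(total) / k
    elif stdev_variant == "mean":
        radius = np.sqrt(total / k)
    else:
        raise ValueError(f"unknown stdev_variant {stdev_variant!r}")

    def density(points: np.ndarray, center: np.ndarray) -> int:
        dist = cdist(points, center[None, :]).ravel()
        return int(np.count_nonzero(dist <= radius))

    own = np.array([density(members[i], centers[i]) for i in range(k)])
    acc = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            mx = max(own[i], own[j])
            if mx == 0:
                continue
            mid = (centers[i] + centers[j]) / 2.0
            union = np.vstack([members[i], members[j]])
            acc += 2.0 * density(union, mid) / mx
    dens_bw = acc / (k * (k - 1))
    return scat + dens_bw


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information between two labelings.

    Mutual information of the label contingency normalized by the geometric
    mean of the two entropies. A labeling with zero entropy (constant) gives
    NMI = 0 by convention.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label vectors differ in length: {a.shape[0]} vs "
                         f"{b.shape[0]}")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b,
                                              average_method="geometric"))
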