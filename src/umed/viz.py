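"""PCA projection for 2-D cluster display and classification comparison.

The projection is for display and evaluation only: clustering always runs
on the full feature matrix, never on the projected coordinates.

With the n_v feature vectors of l features stored column-wise in
``O_D`` (l x n_v), the transform is ``T_D = A (O_D - m_OD)`` where the rows
of A are the eigenvectors of the population covariance
``C_OD = (1/n_v) (O_D - m_OD)(O_D - m_OD)^T`` ordered by decreasing
eigenvalue. The first two rows give each window a 2-coordinate display
vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import FeatureMatrix


@dataclass(frozen=True)
class Projection2D:
    """First principal components of a feature matrix.

    ``coordinates`` is (n_components x n_v): column k is window W_{k+1}'s
    projected vector. ``explained_fraction`` is the share of total variance
    carried by the retained components; ``component_matrix`` holds the
    retained (orthonormal) eigenvector rows of A.
    """

    coordinates: np.ndarray
    explained_fraction: float
    component_matrix: np.ndarray
    eigenvalues: np.ndarray


def pca_project(FV, n_components: int = 2) -> Projection2D:
    """Project feature-matrix rows onto the leading principal components.

    Covariance uses the population normalization 1/n_v. Each component's
    sign is fixed by making its largest-magnitude loading positive, so the
    projection is deterministic.
    """
    X = FV.values if isinstance(FV, FeatureMatrix) else np.asarray(FV, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors")
    OD = X.T                                  # l x n_v
    n_v = OD.shape[1]
    if n_components > min(OD.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(l, n_v)={min(OD.shape)}"
        )
    centered = OD - OD.mean(axis=1, keepdims=True)
    C = (centered @ centered.T) / n_v
    if not np.any(np.diag(C) > 0):
        raise ValueError("zero-variance data: PCA undefined")
    eigval, eigvec = np.linalg.eigh(C)        # ascending
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    A = eigvec[:, order].T                    # rows = eigenvectors
    # Deterministic sign: largest-magnitude loading of each row positive.
    for r in range(A.shape[0]):
        peak = np.argmax(np.abs(A[r]))
        if A[r, peak] < 0:
            A[r] = -A[r]
    coords = A[:n_components] @ centered
    explained = float(eigval[:n_components].sum() / eigval.sum())
    return Projection2D(coordinates=coords, explained_fraction=explained,
                        component_matrix=A[:n_components],
                        eigenvalues=eigval)


def plot_clusters(FV, labels, ax=None, title: str | None = None):
    """Scatter the 2-D PCA projection colored by cluster label.

    Returns the matplotlib Axes. Axis labels report the explained-variance
    share of the display.
    """
    import matplotlib.pyplot as plt

    proj = pca_project(FV, n_components=2)
    labels = np.asarray(labels)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    markers = "osv^D*Pp<>Xh"
    for g, lab in enumerate(np.unique(labels)):
        mask = labels == lab
        ax.scatter(proj.coordinates[0, mask], proj.coordinates[1, mask],
                   s=18, marker=markers[g % len(markers)], label=f"G{lab}",
                   alpha=0.75)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    if title is None:
        title = (f"Clusters in PCA display "
                 f"({100 * proj.explained_fraction:.0f}% of variance)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
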