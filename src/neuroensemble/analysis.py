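"""Similarity matrices, dendrograms and partition extraction.

The co-assignment similarity ``U[i, j] = sum_r sum_mu t[r][mu, i] t[r][mu, j]``
aggregates membership weights over independent MCMC trials; the activity
similarity ``U~[i, j] = sum_k s[i, k] s[j, k]`` summarizes the raw input.
Both feed hierarchical clustering after conversion to the distance
``D = max(U) - U`` (zero diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SimilarityMatrix",
    "membership_similarity",
    "activity_similarity",
    "build_dendrogram",
    "extract_partition",
    "linkage_to_newick",
]


@dataclass
class SimilarityMatrix:
    """Symmetric neuron-by-neuron similarity with provenance metadata."""

    matrix: np.ndarray
    kind: str                   # "membership" or "activity"
    normalization: str = "raw"  # "raw" or "per-trial"

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    def mean_offdiagonal(self) -> float:
        m = self.matrix
        n = m.shape[0]
        return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def membership_similarity(trials, normalization: str = "raw") -> SimilarityMatrix:
    """Co-assignment similarity summed over trials and ensembles.

    ``trials`` is a sequence of (A, N) membership matrices sharing N.  With
    ``normalization="per-trial"`` the sum is divided by the trial count, so
    the diagonal is bounded by 1.
    """
    trials = [np.asarray(t, dtype=float) for t in trials]
    if not trials:
        raise ValueError("at least one trial is required")
    n = trials[0].shape[1]
    if any(t.shape[1] != n for t in trials):
        raise ValueError("all trials must share the neuron count")
    u = np.zeros((n, n))
    for t in trials:
        u += t.T @ t
    if normalization == "per-trial":
        u /= len(trials)
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    u = 0.5 * (u + u.T)  # exact symmetry despite float summation order
    return SimilarityMatrix(u, kind="membership", normalization=normalization)


def activity_similarity(s) -> SimilarityMatrix:
    """Input-activity similarity: inner products of neuron time courses."""
    s = np.asarray(getattr(s, "values", s), dtype=float)
    u = s @ s.T
    return SimilarityMatrix(0.5 * (u + u.T), kind="activity")


def build_dendrogram(u, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of the similarity matrix.

    Similarity is converted to the distance ``D = max(U) - U`` with zero
    diagonal and fed to scipy linkage.  Returns the scipy linkage matrix.
    """
    m = u.matrix if isinstance(u, SimilarityMatrix) else np.asarray(u, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    d = m.max() - m
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method=method)


def extract_partition(linkage: np.ndarray, n_clusters: int | None = None,
                      height: float | None = None) -> np.ndarray:
    """Cut the merge tree at ``n_clusters`` clusters or at ``height``.

    Returns 0-based cluster labels for all leaves.
    """
    n_leaves = linkage.shape[0] + 1
    if (n_clusters is None) == (height is None):
        raise ValueError("specify exactly one of n_clusters or height")
    if n_clusters is not None:
        if not 1 <= n_clusters <= n_leaves:
            raise ValueError(
                f"n_clusters must be in [1, {n_leaves}], got {n_clusters}")
        labels = hierarchy.fcluster(linkage, n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(linkage, height, criterion="distance")
    return labels - 1


def linkage_to_newick(linkage: np.ndarray, leaf_names=None) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)
    if leaf_names is None:
        leaf_names = [str(i) for i in range(linkage.shape[0] + 1)]

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
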