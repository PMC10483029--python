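"""Density-based estimation of the number of clusters on the learned embedding.

When the number of clusters is unknown, HDBSCAN run on the embedding of the
ensemble's reference member finds it automatically.  Density methods label
low-density points as noise (-1); because every sequence must receive a
cluster id, :func:`resolve_noise` reassigns each noise point to the cluster
of its nearest non-noise neighbor.  This mode is recommended for
fine-grained clusterings (many, well-populated clusters); with few long
sequences density estimates are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN

__all__ = [
    "DensityClusterResult",
    "ResolvedLabels",
    "default_min_cluster_size",
    "density_cluster",
    "resolve_noise",
]


@dataclass
class DensityClusterResult:
    """HDBSCAN output: labels with -1 marking noise points."""

    labels: np.ndarray
    n_clusters_found: int
    noise_fraction: float


@dataclass
class ResolvedLabels:
    """Complete labeling after noise reassignment.

    ``noise_index`` holds the positions that were noise and
    ``noise_distance`` the Euclidean distance to the neighbor that resolved
    each of them (used for the heuristic confidence of resolved points).
    """

    labels: np.ndarray
    noise_index: np.ndarray
    noise_distance: np.ndarray


def default_min_cluster_size(n: int) -> int:
    """max(10, n // 400): resolves clusters down to ~0.25% of the dataset.

    The floor of 10 keeps density estimates meaningful; the fraction is
    chosen so the finest clusters this mode is recommended for (many
    modest-sized clusters) are not merged away.
    """
    return max(10, n // 400)


def density_cluster(
    embedding: np.ndarray, min_cluster_size: int | None = None
) -> DensityClusterResult:
    """Cluster embedding rows with HDBSCAN; deterministic given the inputs."""
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2:
        raise ValueError(f"embedding must be 2-D, got shape {emb.shape}")
    n = emb.shape[0]
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(n)
    if min_cluster_size < 2:
        raise ValueError(f"min_cluster_size must be >= 2, got {min_cluster_size}")
    if n < min_cluster_size:
        raise ValueError(
            f"n={n} sequences is smaller than min_cluster_size={min_cluster_size}"
        )
    if np.allclose(emb, emb[0]):
        # a single zero-diameter blob: one cluster by convention
        labels = np.zeros(n, dtype=np.int64)
        return DensityClusterResult(labels, 1, 0.0)
    labels = (
        HDBSCAN(min_cluster_size=int(min_cluster_size), copy=True)
        .fit(emb)
        .labels_.astype(np.int64)
    )
    found = int(np.unique(labels[labels >= 0]).size)
    noise_fraction = float(np.mean(labels < 0))
    return DensityClusterResult(labels, found, noise_fraction)


def resolve_noise(
    result: DensityClusterResult, embedding: np.ndarray
) -> ResolvedLabels:
    """Assign every noise point the label of its nearest non-noise neighbor.

    Euclidean distance; exact ties go to the lower cluster label.  Raises
    when HDBSCAN found no cluster at all.
    """
    emb = np.asarray(embedding, dtype=np.float64)
    labels = result.labels.copy()
    if result.n_clusters_found == 0:
        raise ValueError(
            "density clustering found no clusters; lower min_cluster_size "
            "or run in parametric mode with an explicit number of clusters"
        )
    noise_idx = np.flatnonzero(labels < 0)
    if noise_idx.size == 0:
        return ResolvedLabels(labels, noise_idx, np.zeros(0))
    core_idx = np.flatnonzero(labels >= 0)
    dist = cdist(emb[noise_idx], emb[core_idx])
    dmin = dist.min(axis=1)
    resolved = np.empty(noise_idx.size, dtype=np.int64)
    for row in range(noise_idx.size):
        tied = core_idx[np.flatnonzero(dist[row] <= dmin[row] + 1e-12)]
        resolved[row] = labels[tied].min()
    labels[noise_idx] = resolved
    return ResolvedLabels(labels, noise_idx, dmin)
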