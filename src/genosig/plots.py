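"""Static plot export: embedding scatter, assignment simplex, loss curves.

These replace an interactive dashboard with files on disk.  The embedding
scatter uses a 2-D UMAP of the learned embedding when umap-learn is able to
run, falling back to the first two principal components otherwise.  The
"polygon" plot places cluster c at angle 2*pi*c/k on the unit circle and
each sequence at the posterior-weighted barycenter of the corners, so a
confidently assigned sequence sits at its cluster's corner and an uncertain
one near the center.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["export_plots", "embedding_scatter", "simplex_plot", "loss_curves"]


def _project_2d(embedding: np.ndarray, seed: int = 0) -> np.ndarray:
    if embedding.shape[1] == 2:
        return embedding
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import umap

            return umap.UMAP(n_components=2, random_state=seed).fit_transform(embedding)
    except Exception:
        centered = embedding - embedding.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        return centered @ vt[:2].T


def embedding_scatter(embedding: np.ndarray, labels: np.ndarray, path: Path) -> None:
    xy = _project_2d(np.asarray(embedding, dtype=np.float64))
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(xy[sel, 0], xy[sel, 1], s=6, label=f"cluster {lab}")
    if np.unique(labels).size <= 15:
        ax.legend(fontsize=7, markerscale=2)
    ax.set_title("learned embedding (2-D projection)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def polygon_corners(k: int) -> np.ndarray:
    """Corner c of the assignment polygon at angle 2*pi*c/k on the unit circle."""
    ang = 2 * np.pi * np.arange(k) / k
    return np.column_stack([np.cos(ang), np.sin(ang)])


def simplex_plot(posterior: np.ndarray, labels: np.ndarray, path: Path) -> None:
    posterior = np.asarray(posterior, dtype=np.float64)
    k = posterior.shape[1]
    corners = polygon_corners(k)
    pts = posterior @ corners
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ring = np.vstack([corners, corners[:1]])
    ax.plot(ring[:, 0], ring[:, 1], color="gray", lw=1)
    present = np.unique(labels)
    for lab in present:
        sel = labels == lab
        ax.scatter(pts[sel, 0], pts[sel, 1], s=6, label=f"cluster {lab}")
    for c in range(k):
        ax.annotate(str(c), corners[c] * 1.08, ha="center", va="center", fontsize=8)
    if present.size <= 15:
        ax.legend(fontsize=7, markerscale=2)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title("cluster-assignment polygon")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loss_curves(traces: Sequence[Sequence], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for member, trace in enumerate(traces):
        totals = [t.total for t in trace]
        ax.plot(range(1, len(totals) + 1), totals, lw=1, label=f"member {member}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("total loss")
    if len(traces) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def export_plots(
    out_dir: str | Path,
    embedding: np.ndarray,
    labels: np.ndarray,
    posterior: np.ndarray,
    traces: Sequence[Sequence],
) -> list[Path]:
    """Write all three static plots; failures warn rather than raise."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for fn, args, name in (
        (embedding_scatter, (embedding, labels), "embedding.png"),
        (simplex_plot, (posterior, labels), "assignment_polygon.png"),
        (loss_curves, (traces,), "loss_curves.png"),
    ):
        target = out_dir / name
        try:
            fn(*args, target)
            paths.append(target)
        except Exception as exc:
            warnings.warn(f"could not write {name}: {exc}", stacklevel=2)
    return paths
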