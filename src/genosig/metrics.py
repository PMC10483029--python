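"""Clustering evaluation: intrinsic and external metrics.

External metrics compare predicted clusters with ground-truth classes:
unsupervised clustering accuracy (ACC; best agreement over injective
cluster-to-class mappings, solved by optimal assignment on the contingency
table), homogeneity and completeness (conditional-entropy based, natural
logarithms).  Intrinsic metrics judge geometric cluster quality without
labels: the Davies-Bouldin index (lower is better) and the mean silhouette
coefficient (higher is better), both computed on the learned embedding by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skmetrics

__all__ = [
    "MetricsReport",
    "unsupervised_accuracy",
    "homogeneity_completeness",
    "davies_bouldin",
    "silhouette",
    "evaluate",
]


@dataclass
class MetricsReport:
    """All metrics for one clustering; external fields are None without labels."""

    n: int
    k_pred: int
    k_true: Optional[int] = None
    db_index: Optional[float] = None
    silhouette: Optional[float] = None
    homogeneity: Optional[float] = None
    completeness: Optional[float] = None
    acc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "db_index": self.db_index,
            "silhouette": self.silhouette,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "acc": self.acc,
            "n": self.n,
            "k_true": self.k_true,
            "k_pred": self.k_pred,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _paired_labels(true_labels, pred_labels):
    """Encode labels as integers, dropping positions without a true label."""
    true_arr = list(true_labels)
    pred_arr = np.asarray(pred_labels)
    if len(true_arr) != pred_arr.shape[0]:
        raise ValueError(
            f"label length mismatch: {len(true_arr)} true vs {pred_arr.shape[0]} predicted"
        )
    keep = [i for i, t in enumerate(true_arr) if t is not None]
    if not keep:
        raise ValueError("no sequences carry a ground-truth label")
    true_kept = [true_arr[i] for i in keep]
    classes = sorted(set(true_kept))
    class_of = {c: i for i, c in enumerate(classes)}
    t = np.array([class_of[c] for c in true_kept], dtype=np.int64)
    p = pred_arr[keep].astype(np.int64)
    return t, p


def unsupervised_accuracy(true_labels, pred_labels) -> float:
    """Best fraction of agreeing sequences over injective cluster->class maps.

    Predicted cluster ids are matched to true classes by maximum-weight
    assignment on the contingency table; when there are more predicted
    clusters than classes, the unmatched clusters contribute nothing.
    Sequences without a true label are excluded.
    """
    t, p = _paired_labels(true_labels, pred_labels)
    k_t = int(t.max()) + 1
    k_p = int(p.max()) + 1
    c = np.zeros((k_p, k_t), dtype=np.int64)
    np.add.at(c, (p, t), 1)
    rows, cols = linear_sum_assignment(c, maximize=True)
    return float(c[rows, cols].sum() / t.size)


def homogeneity_completeness(true_labels, pred_labels) -> tuple[float, float]:
    """Entropy-based external metrics in [0, 1] (natural logarithms).

    homogeneity = 1 - H(true|pred)/H(true); completeness = 1 - H(pred|true)/H(pred);
    both 1.0 by convention when the corresponding denominator entropy is 0.
    """
    t, p = _paired_labels(true_labels, pred_labels)
    h, c, _ = skmetrics.homogeneity_completeness_v_measure(t, p)
    return float(h), float(c)


def _check_intrinsic(points: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=np.float64)
    lab = np.asarray(labels, dtype=np.int64)
    if pts.ndim != 2 or pts.shape[0] != lab.shape[0]:
        raise ValueError("points must be n x d with one label per row")
    if np.unique(lab).size < 2:
        raise ValueError("intrinsic metrics require at least 2 clusters")
    return pts, lab


def davies_bouldin(points: np.ndarray, labels) -> float:
    """Davies-Bouldin index: mean over clusters of max_j (s_i + s_j) / d_ij."""
    pts, lab = _check_intrinsic(points, labels)
    return float(skmetrics.davies_bouldin_score(pts, lab))


def silhouette(points: np.ndarray, labels) -> float:
    """Mean silhouette coefficient; singleton-cluster points score 0."""
    pts, lab = _check_intrinsic(points, labels)
    return float(skmetrics.silhouette_score(pts, lab))


def evaluate(
    dataset,
    pred_labels,
    embedding: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Assemble the full metrics report for one clustering of one dataset.

    External metrics need ground-truth labels on the dataset, intrinsic
    metrics need an embedding; whatever is unavailable is left None.
    Intrinsic metrics are also skipped when the prediction has fewer than
    two clusters (they are undefined there).
    """
    pred = np.asarray(pred_labels, dtype=np.int64)
    n = pred.shape[0]
    if len(dataset) != n:
        raise ValueError("prediction length does not match dataset")
    k_pred = int(np.unique(pred).size)
    report = MetricsReport(n=n, k_pred=k_pred)

    if embedding is not None and k_pred >= 2:
        report.db_index = davies_bouldin(embedding, pred)
        report.silhouette = silhouette(embedding, pred)

    true = dataset.labels
    if any(t is not None for t in true):
        labeled = [t for t in true if t is not None]
        report.k_true = len(set(labeled))
        report.acc = unsupervised_accuracy(true, pred)
        h, c = homogeneity_completeness(true, pred)
        report.homogeneity = h
        report.completeness = c
    return report
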