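"""Information-theoretic consensus over independently seeded models.

Each ensemble member trains from a different random initialization, so its
cluster ids are arbitrary and its mistakes are partly independent.  The
consensus procedure (i) picks the member with the highest average pairwise
normalized mutual information (NMI) against the rest as the reference,
(ii) aligns every other member's cluster ids to the reference by
maximum-agreement bipartite assignment on the label contingency table, and
(iii) takes the per-sequence plurality over aligned labels.  The fraction
of members agreeing with the winning label is reported as that sequence's
confidence score, so confidence lies in [1/m, 1] and equals 1 when the
ensemble is unanimous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score

from .deep import ClusterAssignment, LossTerms, ModelConfig, TrainParams, train_model
from .mimics import MimicPairs

__all__ = [
    "EnsembleResult",
    "pairwise_nmi",
    "select_reference",
    "align_labels",
    "consensus",
    "train_ensemble",
]


@dataclass
class EnsembleResult:
    """Consensus labeling with per-sequence confidence scores."""

    members: list[ClusterAssignment]
    consensus_labels: np.ndarray
    confidence: np.ndarray
    reference_index: int

    def __len__(self) -> int:
        return self.consensus_labels.shape[0]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def reference_embedding(self) -> np.ndarray:
        return self.members[self.reference_index].embedding


def _as_labels(member) -> np.ndarray:
    if hasattr(member, "hard_labels"):
        return np.asarray(member.hard_labels)
    return np.asarray(member, dtype=np.int64)


def pairwise_nmi(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Normalized mutual information (arithmetic-mean normalization) in [0, 1]."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be 1-D of equal length, got {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("empty labelings")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def select_reference(members: Sequence) -> int:
    """Index of the member with maximal average NMI to all others (ties: lowest)."""
    if len(members) == 0:
        raise ValueError("empty ensemble")
    if len(members) == 1:
        return 0
    labels = [_as_labels(m) for m in members]
    m = len(labels)
    nmi = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            nmi[i, j] = nmi[j, i] = pairwise_nmi(labels[i], labels[j])
    avg = nmi.sum(axis=1) / (m - 1)
    return int(np.argmax(avg))


def _contingency(ref: np.ndarray, other: np.ndarray, k_c: int) -> np.ndarray:
    c = np.zeros((k_c, k_c), dtype=np.int64)
    np.add.at(c, (ref, other), 1)
    return c


def align_labels(
    reference_labels: Sequence[int], other_labels: Sequence[int], k_c: int
) -> np.ndarray:
    """Permutation ``perm`` of {0..k_c-1} maximizing agreement of ``perm[other]``
    with the reference; among optima, the lexicographically smallest.

    Solved as a maximum-weight bipartite assignment on the contingency table;
    lexicographic tie-breaking fixes perm[0], perm[1], ... greedily, checking
    at each step that the best completion still attains the optimum.
    """
    ref = np.asarray(reference_labels, dtype=np.int64)
    other = np.asarray(other_labels, dtype=np.int64)
    if ref.shape != other.shape:
        raise ValueError("labelings differ in length")
    if ref.size and (max(ref.max(), other.max()) >= k_c or min(ref.min(), other.min()) < 0):
        raise ValueError(f"labels out of range for k_c={k_c}")
    # weight[o, r] = number of sequences that agree if other-cluster o -> r
    weight = _contingency(ref, other, k_c).T.astype(np.float64)

    def best_total(w: np.ndarray) -> float:
        rows, cols = linear_sum_assignment(w, maximize=True)
        return float(w[rows, cols].sum())

    optimum = best_total(weight)
    perm = np.full(k_c, -1, dtype=np.int64)
    used = np.zeros(k_c, dtype=bool)
    fixed_gain = 0.0
    w = weight.copy()
    for o in range(k_c):
        for r in range(k_c):
            if used[r]:
                continue
            sub = np.delete(np.delete(w, np.arange(o + 1), axis=0), np.flatnonzero(used) .tolist() + [r], axis=1)
            rest = best_total(sub) if sub.size else 0.0
            if fixed_gain + weight[o, r] + rest >= optimum - 1e-9:
                perm[o] = r
                used[r] = True
                fixed_gain += weight[o, r]
                break
    return perm


def consensus(members: Sequence, k_c: int | None = None) -> EnsembleResult:
    """Combine members into a consensus labeling with confidence scores.

    Per sequence the consensus label is the plurality over aligned member
    labels; on ties the reference member's label wins when it is among the
    tied labels, otherwise the lowest tied label.  Confidence is the
    fraction of aligned members voting for the consensus label.
    """
    if len(members) == 0:
        raise ValueError("empty ensemble")
    label_rows = [_as_labels(m) for m in members]
    n = label_rows[0].size
    for row in label_rows:
        if row.size != n:
            raise ValueError("ensemble members cover different numbers of sequences")
    if k_c is None:
        k_c = int(max(row.max() for row in label_rows)) + 1
    ref_idx = select_reference(members)
    ref = label_rows[ref_idx]
    aligned = np.empty((len(members), n), dtype=np.int64)
    for i, row in enumerate(label_rows):
        if i == ref_idx:
            aligned[i] = row
        else:
            perm = align_labels(ref, row, k_c)
            aligned[i] = perm[row]

    m = len(members)
    counts = np.zeros((n, k_c), dtype=np.int64)
    for i in range(m):
        np.add.at(counts, (np.arange(n), aligned[i]), 1)
    top = counts.max(axis=1)
    cons = np.argmax(counts, axis=1)  # lowest tied label by default
    # prefer the reference member's label among tied plurality labels
    ref_is_tied = counts[np.arange(n), ref] == top
    cons = np.where(ref_is_tied, ref, cons)
    confidence = counts[np.arange(n), cons] / m

    mem_list = list(members) if members and hasattr(members[0], "hard_labels") else [
        ClusterAssignment(
            posterior=np.eye(k_c)[row], embedding=np.zeros((n, 2))
        )
        for row in label_rows
    ]
    return EnsembleResult(
        members=mem_list,
        consensus_labels=cons,
        confidence=confidence,
        reference_index=ref_idx,
    )


def train_ensemble(
    features: np.ndarray,
    pairs: MimicPairs,
    config: ModelConfig,
    params: TrainParams = TrainParams(),
    n_members: int = 10,
) -> tuple[EnsembleResult, list[list[LossTerms]]]:
    """Train ``n_members`` independently seeded models and form the consensus.

    Member i trains with seed drawn deterministically from ``config.seed``,
    so the whole ensemble is reproducible from one integer.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_members) % (2**31)
    members: list[ClusterAssignment] = []
    traces: list[list[LossTerms]] = []
    for i in range(n_members):
        cfg_i = ModelConfig(
            input_dim=config.input_dim,
            n_clusters=config.n_clusters,
            hidden_dims=config.hidden_dims,
            embed_dim=config.embed_dim,
            proj_dim=config.proj_dim,
            n_heads=config.n_heads,
            seed=int(seeds[i]),
        )
        assignment, trace = train_model(features, pairs, cfg_i, params)
        members.append(assignment)
        traces.append(trace)
    return consensus(members, config.n_clusters), traces
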