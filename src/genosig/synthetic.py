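"""Synthetic labeled DNA datasets with controllable cluster signal.

Two generators cover the two regimes the clustering pipeline is tested in:

* **Template datasets** — a set of random template sequences, each spawning
  a random number of mutated copies.  Copies carry their template's index as
  ground-truth label, and an identity threshold sets the per-site
  substitution probability (``1 - identity``, with the replacement base
  drawn uniformly, so the realized mismatch rate is ``0.75 * (1 -
  identity)``).  This emulates homologous sequence families at a chosen
  divergence.

* **Markov datasets** — each cluster emits sequences from its own
  first-order Markov chain.  A divergence knob interpolates the per-cluster
  transition matrices toward a shared uniform background: at 0 all clusters
  are statistically identical (no recoverable signal), at 1 they are
  maximally distinct.  This emulates compositional (genomic-signature)
  structure without homology.

Both generators are deterministic functions of their spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import Dataset, SequenceRecord

__all__ = [
    "TemplateDatasetSpec",
    "MarkovDatasetSpec",
    "generate_template_dataset",
    "generate_markov_dataset",
    "default_transition_matrices",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class TemplateDatasetSpec:
    """Template-and-mutated-copies dataset description.

    Defaults give the desk-scale benchmark configuration: 50 templates of
    2000 bp with 50-200 copies each at identity 0.8.
    """

    n_templates: int = 50
    template_length: int = 2000
    copies_min: int = 50
    copies_max: int = 200
    identity_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if self.template_length < 1:
            raise ValueError("template_length must be >= 1")
        if not (1 <= self.copies_min <= self.copies_max):
            raise ValueError(
                f"invalid copies range [{self.copies_min}, {self.copies_max}]"
            )
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError(
                f"identity_threshold must be in (0, 1], got {self.identity_threshold}"
            )


def generate_template_dataset(spec: TemplateDatasetSpec) -> Dataset:
    """Labeled dataset of mutated template copies (copies only, template-major).

    Templates are uniform random over {A,C,G,T}; each copy mutates every
    site independently with probability ``1 - identity_threshold`` to a
    uniformly drawn base.  The copy's label is its template's index.
    """
    rng = np.random.default_rng(spec.seed)
    p_sub = 1.0 - spec.identity_threshold
    records: list[SequenceRecord] = []
    for t in range(spec.n_templates):
        template = rng.integers(0, 4, size=spec.template_length, dtype=np.uint8)
        n_copies = int(rng.integers(spec.copies_min, spec.copies_max + 1))
        label = f"T{t:03d}"
        for c in range(n_copies):
            copy = template.copy()
            if p_sub > 0:
                hit = rng.random(spec.template_length) < p_sub
                copy[hit] = rng.integers(0, 4, size=int(hit.sum()), dtype=np.uint8)
            records.append(
                SequenceRecord(id=f"{label}_C{c:04d}", seq=_decode(copy), label=label)
            )
    return Dataset(records)


def default_transition_matrices(n_clusters: int) -> np.ndarray:
    """Distinct row-stochastic first-order transition matrices, one per cluster.

    Each cluster prefers a characteristic pair of bases (weight 0.35 each
    vs 0.15 for the others), cycling through the six unordered base pairs;
    beyond six clusters the preferred mass shifts progressively to keep the
    matrices distinct.
    """
    pairs = [(0, 3), (1, 2), (0, 2), (1, 3), (0, 1), (2, 3)]  # AT, CG, AG, CT, AC, GT
    mats = np.full((n_clusters, 4, 4), 0.15)
    for c in range(n_clusters):
        i, j = pairs[c % len(pairs)]
        hi = 0.35 + 0.02 * (c // len(pairs))
        lo = (1.0 - 2 * hi) / 2.0
        mats[c, :, :] = lo
        mats[c, :, i] = hi
        mats[c, :, j] = hi
    return mats


@dataclass(frozen=True)
class MarkovDatasetSpec:
    """Compositionally distinct clusters from first-order Markov sources."""

    n_clusters: int = 3
    seqs_per_cluster: int = 100
    seq_length: int = 2000
    divergence: float = 1.0
    seed: int = 0
    transition_matrices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.seqs_per_cluster < 1 or self.seq_length < 1:
            raise ValueError("seqs_per_cluster and seq_length must be >= 1")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError(f"divergence must be in [0, 1], got {self.divergence}")

    def effective_matrices(self) -> np.ndarray:
        base = (
            np.asarray(self.transition_matrices, dtype=np.float64)
            if self.transition_matrices is not None
            else default_transition_matrices(self.n_clusters)
        )
        if base.shape != (self.n_clusters, 4, 4):
            raise ValueError(
                f"transition matrices must have shape ({self.n_clusters}, 4, 4)"
            )
        if np.any(base < 0) or not np.allclose(base.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("transition matrices must be row-stochastic")
        uniform = np.full((4, 4), 0.25)
        return (1.0 - self.divergence) * uniform + self.divergence * base


def generate_markov_dataset(spec: MarkovDatasetSpec) -> Dataset:
    """Labeled dataset sampled from per-cluster Markov chains (cluster-major)."""
    rng = np.random.default_rng(spec.seed)
    mats = spec.effective_matrices()
    records: list[SequenceRecord] = []
    for c in range(spec.n_clusters):
        cum = np.cumsum(mats[c], axis=1)
        n = spec.seqs_per_cluster
        seqs = np.empty((n, spec.seq_length), dtype=np.uint8)
        seqs[:, 0] = rng.integers(0, 4, size=n, dtype=np.uint8)
        r = rng.random((n, spec.seq_length - 1))
        for pos in range(1, spec.seq_length):
            rows = cum[seqs[:, pos - 1]]
            seqs[:, pos] = (r[:, pos - 1, None] > rows).sum(axis=1)
        label = f"M{c:02d}"
        for s in range(n):
            records.append(
                SequenceRecord(id=f"{label}_S{s:04d}", seq=_decode(seqs[s]), label=label)
            )
    return Dataset(records)
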