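"""Mimic sequences: mutated copies used as positive training pairs.

A mimic is an artificially mutated copy of an input sequence.  During
training the network sees (original, mimic) pairs and is pushed to give both
the same cluster assignment and nearby hidden representations, so the
mutation model encodes the level of sequence divergence the clustering
should be invariant to.  The default model is transition-dominated point
mutation (transitions A<->G, C<->T at 1e-2 per site, transversions at
0.5e-2), no indels, no fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import featurize_sequences
from .io import Dataset, SequenceRecord, write_fasta

__all__ = ["MutationModel", "mutate", "MimicPairs", "make_pairs", "write_mimics_fasta"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class MutationModel:
    """Per-site mutation probabilities applied independently at each position.

    ``p_indel`` splits evenly between deletions and single-base insertions;
    ``fragment_fraction`` < 1 first restricts the sequence to a uniformly
    placed contiguous window of that fraction of its length.
    """

    p_transition: float = 1e-2
    p_transversion: float = 0.5e-2
    p_indel: float = 0.0
    fragment_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_transition", "p_transversion", "p_indel"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_transition + self.p_transversion + self.p_indel > 1.0:
            raise ValueError("mutation probabilities must sum to <= 1")
        if not (0.0 < self.fragment_fraction <= 1.0):
            raise ValueError(
                f"fragment_fraction must be in (0, 1], got {self.fragment_fraction}"
            )


def mutate(seq: str, model: MutationModel, rng: np.random.Generator) -> str:
    """One mutated copy of ``seq`` under ``model``; deterministic given rng state.

    Events per site are mutually exclusive: transition (A<->G, C<->T),
    transversion (uniform over the two transversion targets), deletion, or
    insertion of a uniform base immediately before the site.  Indels are
    applied in a single left-to-right pass.  Non-ACGT symbols are never
    substituted but can still be deleted or receive insertions.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)].copy()
    if model.fragment_fraction < 1.0:
        frag_len = max(1, int(round(model.fragment_fraction * codes.size)))
        start = int(rng.integers(0, codes.size - frag_len + 1))
        codes = codes[start : start + frag_len].copy()

    n = codes.size
    u = rng.random(n)
    p_ts, p_tv, p_in = model.p_transition, model.p_transversion, model.p_indel
    is_ts = u < p_ts
    is_tv = (u >= p_ts) & (u < p_ts + p_tv)
    is_indel = (u >= p_ts + p_tv) & (u < p_ts + p_tv + p_in)
    acgt = codes < 4

    out = codes.copy()
    ts = is_ts & acgt
    out[ts] = codes[ts] ^ 2  # A<->G (0,2), C<->T (1,3)
    tv = is_tv & acgt
    if tv.any():
        # the two transversion targets of base b are b^1 and b^3
        flip = rng.integers(0, 2, size=int(tv.sum()))
        out[tv] = codes[tv] ^ np.where(flip == 0, 1, 3).astype(np.uint8)

    indels_applied = bool(is_indel.any())
    if indels_applied:
        is_del = rng.random(int(is_indel.sum())) < 0.5
        ins_base = rng.integers(0, 4, size=int((~is_del).sum())).astype(np.uint8)
        keep = np.ones(n, dtype=bool)
        insertions: list[tuple[int, int]] = []
        j = 0
        b = 0
        for i in np.flatnonzero(is_indel):
            if is_del[j]:
                keep[i] = False
            else:
                insertions.append((i, int(ins_base[b])))
                b += 1
            j += 1
        pieces: list[np.ndarray] = []
        prev = 0
        for pos, base in insertions:
            pieces.append(out[prev:pos][keep[prev:pos]])
            pieces.append(np.array([base], dtype=np.uint8))
            prev = pos
        pieces.append(out[prev:][keep[prev:]])
        out = np.concatenate(pieces) if pieces else out[keep]
        if out.size == 0:
            out = np.array([rng.integers(0, 4)], dtype=np.uint8)

    # map back to characters, preserving untouched ambiguity symbols
    chars = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if model.fragment_fraction < 1.0 or indels_applied:
        result = np.where(out < 4, _BASES[np.minimum(out, 3)], ord("N")).astype(np.uint8)
        # indel/fragment paths lose positional alignment with the source string;
        # ambiguity codes other than N are rare enough to collapse to N there
        restored = result
    else:
        restored = np.where(out < 4, _BASES[np.minimum(out, 3)], chars).astype(np.uint8)
    return restored.tobytes().decode("ascii")


@dataclass
class MimicPairs:
    """Featurized mimics keyed to the index of their originals.

    ``profiles[i * n_mimics + j]`` is the j-th mimic of original ``i``;
    ``orig_index`` repeats each original index ``n_mimics`` times so the
    trainer can look up the paired original row directly.
    """

    orig_index: np.ndarray
    profiles: np.ndarray
    n_mimics: int
    sequences: list[str] | None = None

    def __len__(self) -> int:
        return self.profiles.shape[0]

    def profile_for(self, orig: int, mimic: int) -> np.ndarray:
        return self.profiles[orig * self.n_mimics + mimic]


def make_pairs(
    dataset: Dataset,
    model: MutationModel,
    n_mimics: int = 3,
    k: int = 6,
    add_rev_comp: bool = False,
    seed: int = 0,
    keep_sequences: bool = False,
) -> MimicPairs:
    """Generate and featurize ``n_mimics`` mimics per sequence.

    Mimics are featurized with the same k and strand options as the
    originals.  Generation is deterministic given the seed and is done once
    per run; pair indices reference dataset order.
    """
    if n_mimics < 1:
        raise ValueError(f"n_mimics must be >= 1, got {n_mimics}")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    orig_index = np.empty(len(dataset) * n_mimics, dtype=np.int64)
    for i, rec in enumerate(dataset):
        for j in range(n_mimics):
            orig_index[i * n_mimics + j] = i
            seqs.append(mutate(rec.seq, model, rng))
    ids = [
        f"{dataset[i].id}#mimic{j}"
        for i in range(len(dataset))
        for j in range(n_mimics)
    ]
    profiles = featurize_sequences(seqs, k=k, add_rev_comp=add_rev_comp, ids=ids)
    return MimicPairs(
        orig_index=orig_index,
        profiles=profiles,
        n_mimics=n_mimics,
        sequences=seqs if keep_sequences else None,
    )


def write_mimics_fasta(dataset: Dataset, pairs: MimicPairs, path: str | Path) -> None:
    """Export generated mimic sequences for inspection (requires keep_sequences)."""
    if pairs.sequences is None:
        raise ValueError("mimic sequences were not kept; rerun make_pairs(keep_sequences=True)")
    records = [
        SequenceRecord(
            id=f"{dataset[int(pairs.orig_index[m])].id}#mimic{m % pairs.n_mimics}",
            seq=pairs.sequences[m],
        )
        for m in range(len(pairs))
    ]
    write_fasta(Dataset(records), path)
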