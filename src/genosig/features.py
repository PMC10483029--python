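"""k-mer frequency features and the chaos-game (FCGR) grid arrangement.

Every sequence is summarized by the frequencies of its overlapping k-mers
over the {A,C,G,T} alphabet — its genomic signature.  Windows containing any
other symbol (N or IUPAC ambiguity codes) are skipped, so the counts are
deterministic.  The flat 4^k vector uses lexicographic k-mer order
(A < C < G < T); :func:`to_fcgr` re-indexes the same values onto the
2^k x 2^k frequency chaos game representation grid with corners
A = lower-left, C = upper-left, G = upper-right, T = lower-right.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "count_kmers",
    "normalize",
    "to_fcgr",
    "fcgr_coordinates",
    "featurize_dataset",
    "featurize_sequences",
    "kmer_strings",
    "reverse_complement",
    "reverse_complement_index",
    "write_feature_table",
]

_BASES = "ACGT"
# 256-entry lookup: A,C,G,T -> 0..3, everything else -> 4 (invalid)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (4 marks a non-ACGT symbol)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of all length-k windows plus a validity mask.

    The index of window w_1..w_k is sum_i code(w_i) * 4^(k-1-i), i.e. the
    rank of the k-mer in lexicographic order.
    """
    n_win = codes.size - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c < 4
        idx = idx * 4 + c
    return idx, valid


def count_kmers(seq: str, k: int) -> dict[str, int]:
    """Count all overlapping k-mers of ``seq``; ambiguous windows are skipped.

    Raises if the sequence is shorter than k.  Only observed k-mers appear in
    the returned mapping.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ValueError(
            f"sequence of length {len(seq)} is shorter than k={k}: {seq[:20]!r}"
        )
    idx, valid = _window_codes(_encode(seq), k)
    counts = np.bincount(idx[valid], minlength=4**k)
    kmers = kmer_strings(k)
    return {kmers[i]: int(c) for i, c in enumerate(counts) if c > 0}


def kmer_strings(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order."""
    out = [""]
    for _ in range(k):
        out = [p + b for p in out for b in _BASES]
    return out


def normalize(counts: dict[str, int], k: int | None = None) -> np.ndarray:
    """Turn a k-mer count mapping into a frequency vector of length 4^k.

    Entries follow lexicographic order and sum to 1.  Raises when no valid
    window was counted (e.g. an all-N sequence).
    """
    if k is None:
        if not counts:
            raise ValueError("cannot infer k from an empty count mapping")
        k = len(next(iter(counts)))
    vec = np.zeros(4**k, dtype=np.float64)
    for kmer, c in counts.items():
        if len(kmer) != k:
            raise ValueError(f"k-mer {kmer!r} does not have length k={k}")
        i = 0
        for b in kmer:
            i = i * 4 + _BASES.index(b)
        vec[i] = c
    total = vec.sum()
    if total <= 0:
        raise ValueError("no valid k-mer windows (all windows ambiguous?)")
    return vec / total


def fcgr_coordinates(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) grid position of every k-mer in lexicographic order.

    Rows index the matrix top-down, so the A corner (lower-left) is row
    2^k - 1, col 0.  The first base selects the coarsest quadrant.
    """
    # row bit: A,T -> 1 (bottom half); col bit: G,T -> 1 (right half)
    row_bit = np.array([1, 0, 0, 1], dtype=np.int64)
    col_bit = np.array([0, 0, 1, 1], dtype=np.int64)
    idx = np.arange(4**k, dtype=np.int64)
    rows = np.zeros_like(idx)
    cols = np.zeros_like(idx)
    for j in range(k):
        digit = (idx // 4 ** (k - 1 - j)) % 4
        rows = rows * 2 + row_bit[digit]
        cols = cols * 2 + col_bit[digit]
    return rows, cols


def to_fcgr(freq: np.ndarray, k: int) -> np.ndarray:
    """Arrange a flat 4^k frequency vector onto the 2^k x 2^k FCGR grid."""
    freq = np.asarray(freq, dtype=np.float64)
    if freq.shape != (4**k,):
        raise ValueError(f"expected frequency vector of length {4**k}, got {freq.shape}")
    rows, cols = fcgr_coordinates(k)
    grid = np.zeros((2**k, 2**k), dtype=np.float64)
    grid[rows, cols] = freq
    return grid


def reverse_complement_index(k: int) -> np.ndarray:
    """Permutation p with p[i] = lexicographic index of revcomp(k-mer i)."""
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(idx)
    rem = idx
    for j in range(k):
        digit = rem % 4
        rem = rem // 4
        out = out * 4 + (3 - digit)
    return out


def featurize_sequences(
    seqs: Sequence[str],
    k: int = 6,
    add_rev_comp: bool = False,
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """k-mer frequency matrix (n x 4^k); each row is a probability vector.

    With ``add_rev_comp`` the counts of each k-mer and its reverse complement
    are pooled before normalization, making the signature strand-symmetric.
    Raises per-sequence errors naming the offending sequence.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(seqs)
    mat = np.zeros((n, 4**k), dtype=np.float64)
    rc = reverse_complement_index(k) if add_rev_comp else None
    for i, seq in enumerate(seqs):
        name = ids[i] if ids is not None else f"sequence #{i}"
        if len(seq) < k:
            raise ValueError(f"{name}: length {len(seq)} < k={k}")
        idx, valid = _window_codes(_encode(seq), k)
        counts = np.bincount(idx[valid], minlength=4**k).astype(np.float64)
        if rc is not None:
            counts = counts + counts[rc]
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"{name}: no unambiguous k-mer window at k={k}")
        mat[i] = counts / total
    return mat


def featurize_dataset(dataset, k: int = 6, add_rev_comp: bool = False) -> np.ndarray:
    """Feature matrix for a :class:`~genosig.io.Dataset` (row i = record i)."""
    return featurize_sequences(dataset.seqs, k=k, add_rev_comp=add_rev_comp, ids=dataset.ids)


def write_feature_table(
    matrix: np.ndarray, ids: Sequence[str], k: int, path: str | Path
) -> None:
    """Export the dense feature matrix as TSV with a lexicographic header."""
    header = "id\t" + "\t".join(kmer_strings(k))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for sid, row in zip(ids, matrix):
            fh.write(sid + "\t" + "\t".join(f"{v!r}" for v in row) + "\n")
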