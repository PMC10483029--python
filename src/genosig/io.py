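"""Reading and writing of sequence datasets, label files and cluster assignments.

The on-disk formats are deliberately plain: multi-FASTA for sequences,
two-column TSV (``id<TAB>label``) for ground-truth labels, and three-column
TSV (``id<TAB>cluster<TAB>confidence``) for cluster assignments.  All files
are UTF-8 with Unix newlines, and writing is byte-deterministic given
identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DatasetStats",
    "Dataset",
    "read_fasta",
    "read_labels",
    "write_fasta",
    "write_labels",
    "write_assignments",
    "read_assignments",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A single DNA sequence with an identifier and an optional class label.

    The sequence is stored uppercase; IUPAC ambiguity codes are tolerated
    (they are handled downstream at featurization time).  ``id`` is the FASTA
    header token up to the first whitespace; the full header is kept in
    ``description`` for output purposes only.
    """

    id: str
    seq: str
    label: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DatasetStats:
    count: int
    min_length: int
    avg_length: float
    max_length: int
    label_counts: Optional[dict[str, int]]


@dataclass
class Dataset:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def seqs(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    @property
    def has_labels(self) -> bool:
        return any(r.label is not None for r in self.records)

    def stats(self) -> DatasetStats:
        """Summary statistics, recomputed from the record list every call."""
        if not self.records:
            return DatasetStats(0, 0, 0.0, 0, None)
        lengths = [len(r) for r in self.records]
        label_counts: Optional[dict[str, int]] = None
        if self.has_labels:
            label_counts = {}
            for r in self.records:
                if r.label is not None:
                    label_counts[r.label] = label_counts.get(r.label, 0) + 1
        return DatasetStats(
            count=len(self.records),
            min_length=min(lengths),
            avg_length=sum(lengths) / len(lengths),
            max_length=max(lengths),
            label_counts=label_counts,
        )


def read_fasta(path: str | Path) -> Dataset:
    """Read a multi-FASTA file into a :class:`Dataset`.

    Order is preserved; ids are header tokens up to the first whitespace;
    sequences are uppercased.  Raises on empty files, duplicate ids and
    content that does not start with a FASTA header.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA (line {lineno} does not start with '>')"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(
                id=entry.id, seq=str(entry.seq), description=entry.description
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Dataset(records)


def read_labels(path: str | Path, dataset: Dataset) -> Dataset:
    """Attach ground-truth labels from a two-column TSV file.

    Rows are ``id<TAB>label``.  Records whose id is absent from the file keep
    ``label=None``; label-file ids not present in the dataset produce a
    warning and are skipped.  Malformed rows raise with the row number.
    """
    path = Path(path)
    by_id: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed label row {rowno}: {line!r}")
            by_id[parts[0]] = parts[1]

    known = set(dataset.ids)
    for lid in by_id:
        if lid not in known:
            warnings.warn(
                f"label file id {lid!r} not present in dataset; skipped",
                stacklevel=2,
            )
    records = [
        replace(rec, label=by_id[rec.id]) if rec.id in by_id else rec
        for rec in dataset.records
    ]
    return Dataset(records)


def write_fasta(dataset: Dataset, path: str | Path, width: int = 70) -> None:
    """Write the dataset as multi-FASTA (fixed line width, Unix newlines)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in dataset:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_labels(dataset: Dataset, path: str | Path) -> None:
    """Write present labels as a two-column TSV (id<TAB>label)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in dataset:
            if rec.label is not None:
                fh.write(f"{rec.id}\t{rec.label}\n")


def write_assignments(dataset: Dataset, result, path: str | Path) -> None:
    """Write consensus cluster assignments as a three-column TSV.

    ``result`` must expose ``consensus_labels`` and ``confidence`` covering
    every record in dataset order.  Confidences are written with ``repr`` so
    a read/write round trip is exact.
    """
    labels = list(result.consensus_labels)
    confidence = list(result.confidence)
    if len(labels) != len(dataset) or len(confidence) != len(dataset):
        raise ValueError(
            f"assignment length mismatch: {len(labels)} labels, "
            f"{len(confidence)} confidences for {len(dataset)} records"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tcluster\tconfidence\n")
        for rec, lab, conf in zip(dataset, labels, confidence):
            fh.write(f"{rec.id}\t{int(lab)}\t{float(conf)!r}\n")


def read_assignments(path: str | Path) -> tuple[list[str], list[int], list[float]]:
    """Read a TSV written by :func:`write_assignments`."""
    ids: list[str] = []
    labels: list[int] = []
    confidence: list[float] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "cluster", "confidence"]:
            raise ValueError(f"{path}: unexpected assignment header {header!r}")
        for rowno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed assignment row {rowno}")
            ids.append(parts[0])
            labels.append(int(parts[1]))
            confidence.append(float(parts[2]))
    return ids, labels, confidence
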