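"""Reading, validation, and splitting of fixed-length labeled DNA windows.

Sequence windows are given in coordinates relative to the transcription
start site (TSS): a window described as [-a, +b] has length a + b + 1 and
is stored 0-based with ``tss_index = a`` (e.g. 249 for the [-249, +50]
300-bp window).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or empty."""


class ValidationError(ValueError):
    """Raised when a dataset violates the window-length/alphabet contract."""


class StratificationError(ValueError):
    """Raised when a class is too small to stratify."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled DNA window: ``label`` 1 = promoter, 0 = non-promoter."""

    identifier: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class PromoterDataset:
    """Ordered collection of equal-length labeled windows around a TSS."""

    records: list[SequenceRecord]
    window_length: int
    tss_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.tss_index < self.window_length:
            raise ValueError(
                f"tss_index {self.tss_index} outside window [0, {self.window_length})"
            )
        for rec in self.records:
            if len(rec.sequence) != self.window_length:
                raise ValidationError(
                    f"record {rec.identifier!r} has length {len(rec.sequence)}, "
                    f"expected {self.window_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, indices: Iterable[int]) -> "PromoterDataset":
        recs = [self.records[i] for i in indices]
        return PromoterDataset(recs, self.window_length, self.tss_index)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/test index partition of a PromoterDataset."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


@dataclass
class ValidationReport:
    """Records dropped during validation, with reasons."""

    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for identifier, reason in self.dropped:
                fh.write(f"{identifier}\t{reason}\n")


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path, label: int) -> list[SequenceRecord]:
    """Read a FASTA file (optionally gzipped), labelling every record.

    Sequences are uppercased; length and alphabet are checked later by
    :func:`validate_dataset`, not here.
    """
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FastaParseError(f"{path}: empty file")
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected '>' header, got {first!r}")
        fh.seek(0)
        for entry in SeqIO.parse(fh, "fasta"):
            seq = str(entry.seq).upper()
            if not seq:
                raise FastaParseError(f"{path}: record {entry.id!r} has empty sequence")
            records.append(SequenceRecord(entry.id, seq, label))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(dataset_or_records, path: str | Path) -> None:
    """Write records to FASTA, one line per sequence body."""
    records = getattr(dataset_or_records, "records", dataset_or_records)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n{rec.sequence}\n")


def validate_dataset(
    records: Sequence[SequenceRecord],
    window_length: int,
    tss_index: int,
    ambiguous_policy: str = "drop",
) -> tuple[PromoterDataset, ValidationReport]:
    """Enforce fixed length and the A/C/G/T alphabet.

    Ambiguous bases (N etc.) are handled per ``ambiguous_policy``: ``"drop"``
    removes and reports the record, ``"error"`` aborts. Wrong length is
    always an error — windows must be pre-cut to the declared length.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if ambiguous_policy not in ("drop", "error"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    report = ValidationReport()
    kept: list[SequenceRecord] = []
    for rec in records:
        if len(rec.sequence) != window_length:
            raise ValidationError(
                f"record {rec.identifier!r}: length {len(rec.sequence)} != {window_length}"
            )
        bad = set(rec.sequence) - VALID_BASES
        if bad:
            if ambiguous_policy == "error":
                raise ValidationError(
                    f"record {rec.identifier!r}: non-ACGT characters {sorted(bad)}"
                )
            report.dropped.append(
                (rec.identifier, f"non-ACGT characters: {','.join(sorted(bad))}")
            )
            continue
        kept.append(rec)
    return PromoterDataset(kept, window_length, tss_index), report


def stratified_split(
    dataset: PromoterDataset, test_fraction: float, seed: int
) -> DataSplit:
    """Class-stratified random partition into train and test.

    Per-class test counts are ``round(class_size * test_fraction)`` with
    banker's rounding (ties to nearest even). ``test_fraction=0.2`` gives the
    4:1 train:test protocol.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    test_parts = []
    train_parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise StratificationError(
                f"class {cls} has {len(idx)} members; need at least 2 to stratify"
            )
        n_test = int(np.round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    test = np.sort(np.concatenate(test_parts))
    train = np.sort(np.concatenate(train_parts))
    return DataSplit(train_indices=train, test_indices=test)
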