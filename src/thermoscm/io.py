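"""Reading, validating, filtering and splitting protein sequence datasets.

Positive sequences are thermophilic proteins (the class the scoring card is
trained to recognise); negatives are non-thermophilic/mesophilic proteins.
Sequences are plain FASTA; anything outside the 20 standard one-letter codes
(B, J, O, U, X, Z, gaps, ...) disqualifies a record from model building.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

POSITIVE = "positive"
NEGATIVE = "negative"

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class FastaFormatError(ValueError):
    """Raised when a file is not parseable as FASTA."""


class DuplicateIdError(ValueError):
    """Raised when two records in one file share an identifier."""


class DatasetSizeError(ValueError):
    """Raised when a dataset is too small for the requested operation."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def is_standard(self) -> bool:
        """True if the sequence uses only the 20 standard residues."""
        return bool(self.sequence) and set(self.sequence) <= _STANDARD_SET


@dataclass
class LabeledDataset:
    """A two-class collection of protein records.

    Every record in ``positives`` carries the positive label and likewise for
    ``negatives``; identifiers must be unique across the whole dataset.
    """

    positives: list[ProteinRecord] = field(default_factory=list)
    negatives: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positives = [replace(r, label=POSITIVE) for r in self.positives]
        self.negatives = [replace(r, label=NEGATIVE) for r in self.negatives]
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise DuplicateIdError(f"duplicate record id in dataset: {dup!r}")

    @property
    def records(self) -> list[ProteinRecord]:
        return self.positives + self.negatives

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def _normalize(raw: str) -> str:
    return "".join(raw.split()).upper()


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into normalized (upper-case, whitespace-free) records.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FastaFormatError
        If sequence data precedes the first ``>`` header.
    DuplicateIdError
        If two headers share an identifier.
    """
    path = Path(path)
    with open(path) as handle:
        head = handle.read(1_048_576)
        stripped = head.lstrip()
        if stripped and not stripped.startswith(">"):
            raise FastaFormatError(f"{path}: sequence data before first FASTA header")
        handle.seek(0)
        records = [
            ProteinRecord(id=rec.id, sequence=_normalize(str(rec.seq)))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to *path* in FASTA format (round-trips with read_fasta)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def filter_standard(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[str]]:
    """Split records into (kept, dropped-ids) by the standard-residue rule.

    A record is kept only if its sequence is non-empty and consists solely of
    the 20 standard one-letter codes; every other record's id is reported in
    the dropped list.  Idempotent on its kept output.
    """
    kept = [r for r in records if r.is_standard()]
    dropped = [r.id for r in records if not r.is_standard()]
    return kept, dropped


def split_balanced(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    train_fraction: float,
    seed: int,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Class-balanced train/test split driven by the positive class.

    ``floor(train_fraction * n_pos)`` positives are drawn into the training
    partition and the remainder into the test partition; negatives are
    sampled uniformly without replacement to match the positive count in each
    partition.  The split is a deterministic function of *seed*.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError(f"train_fraction must be in (0, 1], got {train_fraction}")
    n_pos, n_neg = len(positives), len(negatives)
    if n_neg < n_pos:
        raise DatasetSizeError(
            f"need at least as many negatives as positives ({n_neg} < {n_pos})"
        )
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * n_pos))

    pos_order = rng.permutation(n_pos)
    neg_order = rng.choice(n_neg, size=n_pos, replace=False)

    train = LabeledDataset(
        positives=[positives[i] for i in pos_order[:n_train]],
        negatives=[negatives[i] for i in neg_order[:n_train]],
    )
    test = LabeledDataset(
        positives=[positives[i] for i in pos_order[n_train:]],
        negatives=[negatives[i] for i in neg_order[n_train:]],
    )
    return train, test
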