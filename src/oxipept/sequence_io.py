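"""Reading, validating, and writing peptide sequences and label tables.

Peptides are short amino-acid sequences over the 20 canonical one-letter
codes.  Every downstream descriptor (composition/transition/distribution,
skip-dipeptide composition, property averaging, substitution-matrix
weighting) is defined only for canonical residues and requires length >= 2,
so validation is enforced at the boundary: a record either enters the
pipeline fully normalized or is rejected with a precise reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino acids in alphabetical one-letter order.  This ordering is
#: load-bearing: it fixes the feature-vector layout of every encoder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Minimum peptide length.  Transition frequencies divide by L-1 and
#: skip-dipeptide composition needs at least one residue pair.
MIN_LENGTH = 2


class SequenceValidationError(ValueError):
    """A sequence failed canonical-residue or length validation."""


class DatasetError(ValueError):
    """A dataset-level consistency problem (duplicate ids, label mismatch)."""


@dataclass(frozen=True)
class PeptideRecord:
    """A validated peptide: identifier plus canonical residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("peptide id must be non-empty")
        validate_sequence(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Parallel peptide records and binary labels (1 = antioxidant)."""

    records: list[PeptideRecord]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise DatasetError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        bad = sorted({l for l in self.labels} - {0, 1})
        if bad:
            raise DatasetError(f"labels must be 0/1, got {bad}")
        _check_unique_ids(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[PeptideRecord, int]]:
        return iter(zip(self.records, self.labels))

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices],
            [self.labels[i] for i in indices],
        )


def _check_unique_ids(ids: Iterable[str]) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DatasetError(f"duplicate record id: {i!r}")
        seen.add(i)


def validate_sequence(raw: str) -> str:
    """Normalize a raw residue string and validate it.

    Uppercases the input (FASTA convention), then rejects any character
    outside the 20 canonical amino acids — naming the offending character
    and its 1-based position — and any sequence shorter than 2 residues.
    Returns the normalized residue string.  Idempotent on accepted input.
    """
    residues = raw.strip().upper()
    for pos, ch in enumerate(residues, start=1):
        if ch not in _AA_SET:
            raise SequenceValidationError(
                f"noncanonical residue {ch!r} at position {pos}"
            )
    if len(residues) < MIN_LENGTH:
        raise SequenceValidationError(
            f"sequence length {len(residues)} < minimum {MIN_LENGTH}"
        )
    return residues


def read_fasta(
    path: str | Path, *, drop_invalid: bool = False
) -> list[PeptideRecord]:
    """Read peptides from a FASTA file, preserving record order.

    Residues are uppercased.  Invalid records (noncanonical residues or
    length < 2) raise by default; with ``drop_invalid=True`` they are
    skipped with a logged warning instead.  Duplicate ids always raise.
    """
    records: list[PeptideRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(PeptideRecord(rec.id, validate_sequence(str(rec.seq))))
        except SequenceValidationError as exc:
            if drop_invalid:
                logger.warning("dropping record %s: %s", rec.id, exc)
            else:
                raise SequenceValidationError(f"record {rec.id!r}: {exc}") from exc
    _check_unique_ids(r.id for r in records)
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write peptides as single-line FASTA."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta-2line")


def labels_from_headers(records: Sequence[PeptideRecord]) -> list[int] | None:
    """Parse labels from FASTA ids of the form ``name|1`` / ``name|0``.

    Returns None unless every id carries a label suffix.
    """
    labels: list[int] = []
    for r in records:
        _, _, suffix = r.id.rpartition("|")
        if suffix not in ("0", "1"):
            return None
        labels.append(int(suffix))
    return labels


def read_labels(path: str | Path, records: Sequence[PeptideRecord]) -> LabeledDataset:
    """Read a two-column TSV (``id<TAB>label``) and align labels to records.

    The TSV must cover exactly the record ids; an id on either side missing
    from the other is an alignment error, and labels outside {0, 1} are a
    validation error.
    """
    table: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rec_id, label_str = parts
            if lineno == 1 and label_str.lower() == "label":
                continue  # header row
            if label_str not in ("0", "1"):
                raise DatasetError(
                    f"{path}:{lineno}: label must be 0 or 1, got {label_str!r}"
                )
            if rec_id in table:
                raise DatasetError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            table[rec_id] = int(label_str)

    record_ids = {r.id for r in records}
    missing_in_tsv = sorted(record_ids - table.keys())
    missing_in_fasta = sorted(table.keys() - record_ids)
    if missing_in_tsv or missing_in_fasta:
        raise DatasetError(
            "label/record id mismatch: "
            f"ids without labels {missing_in_tsv[:5]}, "
            f"labels without records {missing_in_fasta[:5]}"
        )
    return LabeledDataset(list(records), [table[r.id] for r in records])


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\n")
        for rec, lab in dataset:
            fh.write(f"{rec.id}\t{lab}\n")
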