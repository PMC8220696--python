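"""Reading, validating and writing protein sequences and label tables.

Sequences are plain FASTA (wrapped or single-line); labels are a two-column
delimited table ``id<TAB>label`` (tab or comma, sniffed from the first line).
Validation is strict by default: any character outside the 20 standard
one-letter codes is an error. The ``drop_nonstandard`` policy removes
offending characters instead and logs how many were dropped, which real
antifreeze-protein sets occasionally need (rare ``X`` residues).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS

logger = logging.getLogger(__name__)

_CANONICAL_RE = re.compile(f"^[{AMINO_ACIDS}]+$")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a record violates the canonical-alphabet policy."""


class LabelTableError(ValueError):
    """Raised for malformed or inconsistent label tables."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an amino-acid string."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class ValidationPolicy(str, Enum):
    strict = "strict"
    drop_nonstandard = "drop_nonstandard"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into records, order preserved.

    The id is the header token up to the first whitespace. Errors name the
    offending line (text before the first header) or record (empty body).
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header before sequence data"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: empty FASTA file")
    for rec in records:
        if len(rec.sequence) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence body")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def validate_record(
    rec: ProteinRecord, policy: ValidationPolicy | str = ValidationPolicy.strict
) -> ProteinRecord:
    """Case-fold to upper case and apply the alphabet policy.

    strict: error on any non-canonical character (B, J, O, U, X, Z, '*', '-').
    drop_nonstandard: remove the offending characters; a warning logs the count.
    """
    policy = ValidationPolicy(policy)
    seq = rec.sequence.upper()
    if _CANONICAL_RE.match(seq):
        return ProteinRecord(rec.id, seq)
    if policy is ValidationPolicy.strict:
        bad = next(c for c in seq if c not in AMINO_ACIDS)
        raise SequenceValidationError(
            f"record {rec.id!r}: non-standard residue {bad!r} under strict policy"
        )
    kept = [c for c in seq if c in AMINO_ACIDS]
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        logger.warning(
            "record %r: dropped %d non-standard residue(s)", rec.id, n_dropped
        )
    cleaned = "".join(kept)
    if not cleaned:
        raise SequenceValidationError(
            f"record {rec.id!r}: empty after dropping non-standard residues"
        )
    return ProteinRecord(rec.id, cleaned)


def validate_records(
    records: Iterable[ProteinRecord],
    policy: ValidationPolicy | str = ValidationPolicy.strict,
) -> list[ProteinRecord]:
    return [validate_record(r, policy) for r in records]


def read_labels(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column (id, label) table into an ordered mapping.

    Labels are kept as opaque strings; integer class codes are assigned
    downstream in first-seen record order. Duplicate ids are an error.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            sep = delimiter
            if sep is None:
                sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise LabelTableError(
                    f"{path}: line {lineno}: expected two delimited columns (id, label)"
                )
            rec_id, label = parts
            if rec_id in labels:
                raise LabelTableError(f"{path}: duplicate id {rec_id!r} at line {lineno}")
            labels[rec_id] = label
    if not labels:
        raise LabelTableError(f"{path}: empty label table")
    return labels


def check_label_join(records: Iterable[ProteinRecord], labels: Mapping[str, str]) -> None:
    """Verify records and labels cover each other exactly.

    Raises listing the ids on either side of the mismatch.
    """
    rec_ids = [r.id for r in records]
    rec_set = set(rec_ids)
    missing = [i for i in rec_ids if i not in labels]
    if missing:
        raise LabelTableError(f"records without a label: {missing}")
    extra = [i for i in labels if i not in rec_set]
    if extra:
        raise LabelTableError(f"label ids absent from FASTA: {extra}")
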