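"""Reading, validating and writing protein sequences and class labels.

Sequences live in plain multi-record FASTA (wrapped or unwrapped); labels in a
two-column CSV ``id,label`` with labels in {monomer, oligomer} (any case).
Every downstream module consumes the :class:`ProteinRecord` /
:class:`LabelledRecord` containers defined here.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The canonical 20-letter amino acid alphabet, in the fixed order used for
#: every descriptor block.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: The two oligomeric-state classes, in sorted order.
CLASSES = ("monomer", "oligomer")


class SequenceError(ValueError):
    """Raised for malformed FASTA input or invalid residues."""


class LabelError(ValueError):
    """Raised for missing or unrecognised class labels."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated amino acid sequence.

    The sequence is uppercase and restricted to the 20 canonical one-letter
    codes; ``len(record)`` is the number of residues N.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _ALPHABET_SET:
                raise SequenceError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelledRecord:
    """A protein record paired with its oligomeric-state class."""

    record: ProteinRecord
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise LabelError(f"unknown label {self.label!r}; expected one of {CLASSES}")


def _clean(raw: str) -> str:
    # uppercase, strip whitespace and trailing '*' stop characters
    return raw.upper().replace(" ", "").replace("\t", "").rstrip("*")


def parse_fasta(stream: TextIO | str, on_invalid: str = "error") -> list[ProteinRecord]:
    """Parse FASTA text into a list of :class:`ProteinRecord`.

    Record ids are the header up to the first whitespace; wrapped sequence
    lines are joined; lowercase input is uppercased and trailing ``*`` stop
    characters stripped.

    Parameters
    ----------
    stream:
        A text handle or a FASTA string.
    on_invalid:
        Policy for sequences containing residues outside the 20-letter
        alphabet: ``"error"`` (default) raises :class:`SequenceError` naming
        the id, position and character; ``"drop"`` skips the offending
        sequence with a logged warning.
    """
    if on_invalid not in ("error", "drop"):
        raise ValueError(f"on_invalid must be 'error' or 'drop', got {on_invalid!r}")
    handle = io.StringIO(stream) if isinstance(stream, str) else stream

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(handle, "fasta"):
        rid = entry.id  # header token up to first whitespace
        if rid in seen:
            raise SequenceError(f"duplicate sequence id {rid!r}")
        seen.add(rid)
        seq = _clean(str(entry.seq))
        try:
            records.append(ProteinRecord(id=rid, sequence=seq))
        except SequenceError:
            if on_invalid == "drop":
                logger.warning("dropping sequence %r: non-canonical residues", rid)
                continue
            raise
    if not records and not seen:
        raise SequenceError("no sequences found in FASTA input")
    return records


def write_fasta(records: Iterable[ProteinRecord], stream: TextIO, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns.

    Round-trips with :func:`parse_fasta`: parsing the written text yields an
    identical record list.
    """
    for rec in records:
        stream.write(f">{rec.id}\n")
        seq = rec.sequence
        for start in range(0, len(seq), width):
            stream.write(seq[start : start + width] + "\n")


def read_labels(stream: TextIO | str, records: list[ProteinRecord]) -> list[LabelledRecord]:
    """Match each record to its class label from a two-column CSV.

    The CSV has columns ``id,label`` (a header row with exactly those names is
    optional); labels map case-insensitively onto {monomer, oligomer}. Every
    record must receive exactly one label.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    table: dict[str, str] = {}
    for row in csv.reader(handle):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise LabelError(f"malformed label row: {row!r}")
        rid, raw = row[0].strip(), row[1].strip()
        if rid == "id" and raw == "label":
            continue  # header
        label = raw.lower()
        if label not in CLASSES:
            raise LabelError(f"unknown label {raw!r} for id {rid!r}")
        if rid in table:
            raise LabelError(f"duplicate label row for id {rid!r}")
        table[rid] = label

    labelled = []
    for rec in records:
        if rec.id not in table:
            raise LabelError(f"missing label for sequence id {rec.id!r}")
        labelled.append(LabelledRecord(record=rec, label=table[rec.id]))
    return labelled
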