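"""Artificial self-hit records and 12-column tabular alignment I/O.

To make a MEGAN-like assigner bin every subject of a reference database, each
subject is turned into one fake alignment record in the standard 12-column
tabular layout (qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore) in which the subject is its own perfect query.
Only three fields matter to the assigner — query id, subject id and bit score —
so the bit score merely has to clear the assigner's default minimum of 35 bits.
Here it is set to ``2·L + 20`` for a subject of L residues (floored at 40 for
very short subjects), which grows with length and always clears the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from sapkit.errors import EmptyRecordError, MalformedLineError
from sapkit.refdb_io import ReferenceRecord


@dataclass
class TabularHit:
    """One alignment record in the 12-column tabular layout."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float


def artificial_bit_score(length: int) -> float:
    """Bit score assigned to an artificial self-hit for a subject of ``length`` residues."""
    score = 2 * length + 20
    if length < 8:
        score = max(40, score)
    return float(score)


def make_artificial_record(record: ReferenceRecord) -> TabularHit:
    """Build the artificial self-hit for one reference subject.

    The subject is its own query: identity 100.00, full-length coverage,
    E-value 0 and a length-scaled bit score that always exceeds 35 bits.
    """
    if record.length < 1:
        raise EmptyRecordError(f"record {record.canonical_id!r} has an empty sequence")
    return TabularHit(
        query_id=record.canonical_id,
        subject_id=record.canonical_id,
        percent_identity=100.0,
        alignment_length=record.length,
        mismatches=0,
        gap_opens=0,
        query_start=1,
        query_end=record.length,
        subject_start=1,
        subject_end=record.length,
        evalue=0.0,
        bit_score=artificial_bit_score(record.length),
    )


def _format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    return "%g" % e


def _format_bit_score(b: float) -> str:
    if b == int(b):
        return str(int(b))
    return "%.1f" % b


def format_hit(hit: TabularHit) -> str:
    """Serialise one hit as a TAB-separated 12-field line (no newline)."""
    return "\t".join(
        [
            hit.query_id,
            hit.subject_id,
            "%.2f" % hit.percent_identity,
            str(hit.alignment_length),
            str(hit.mismatches),
            str(hit.gap_opens),
            str(hit.query_start),
            str(hit.query_end),
            str(hit.subject_start),
            str(hit.subject_end),
            _format_evalue(hit.evalue),
            _format_bit_score(hit.bit_score),
        ]
    )


def write_tabular(hits: Iterable[TabularHit], stream: IO[str]) -> int:
    """Write hits as headerless TAB-separated lines; returns the line count."""
    count = 0
    for hit in hits:
        stream.write(format_hit(hit) + "\n")
        count += 1
    return count


def parse_tabular(stream: IO[str]) -> Iterator[TabularHit]:
    """Lazily parse 12-column tabular alignment lines.

    Scientific notation is accepted in the numeric fields.  A non-empty line
    with a field count other than 12 raises :class:`MalformedLineError` naming
    the line number.
    """
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise MalformedLineError(
                f"line {line_no}: expected 12 TAB-separated fields, got {len(fields)}"
            )
        yield TabularHit(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=float(fields[2]),
            alignment_length=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            query_start=int(fields[6]),
            query_end=int(fields[7]),
            subject_start=int(fields[8]),
            subject_end=int(fields[9]),
            evalue=float(fields[10]),
            bit_score=float(fields[11]),
        )
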