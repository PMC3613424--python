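"""Reading and writing protein reference FASTA in the nr defline dialect.

nr merges identical sequences into one record whose defline concatenates the
headers of all merged entries, separated by the SOH control character (0x01).
A record is identified by the GI number of its FIRST sub-header; all other
headers are carried along verbatim but never used for identification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Set

from Bio.SeqIO.FastaIO import SimpleFastaParser

from sapkit.errors import EmptyRecordError, MalformedHeaderError

logger = logging.getLogger(__name__)

SOH = "\x01"

_GI_RE = re.compile(r"^gi\|(\d+)\|")


@dataclass
class ReferenceRecord:
    """One protein subject of the reference database.

    Attributes
    ----------
    primary_gi : int
        GI number parsed from the first sub-header; the record's identity.
    canonical_id : str
        The first whitespace-delimited token of the first sub-header,
        e.g. ``gi|22536352|ref|NP_687203.1``.
    all_headers : list[str]
        Every sub-header of the defline, in order, verbatim.
    sequence : str
        Uppercase amino-acid sequence.
    """

    primary_gi: int
    canonical_id: str
    all_headers: list = field(default_factory=list)
    sequence: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


class _LineCountingReader:
    """Wraps a text stream so the FASTA parser's records can be located by line.

    ``header_lines[k]`` is the 1-based line number of the k-th defline seen.
    """

    def __init__(self, stream: IO[str]):
        self._stream = stream
        self.line_no = 0
        self.header_lines: list = []

    def __iter__(self):
        return self

    def __next__(self) -> str:
        line = next(self._stream)
        self._saw(line)
        return line

    # SimpleFastaParser probes the handle with readline() before iterating.
    def readline(self) -> str:
        line = self._stream.readline()
        if line:
            self._saw(line)
        return line

    def _saw(self, line: str) -> None:
        self.line_no += 1
        if line.startswith(">"):
            self.header_lines.append(self.line_no)


def _record_from_title(title: str, sequence: str, line_no: Optional[int] = None) -> ReferenceRecord:
    headers = title.split(SOH)
    first = headers[0]
    m = _GI_RE.match(first)
    if m is None:
        where = f" at line {line_no}" if line_no is not None else ""
        raise MalformedHeaderError(
            f"first sub-header{where} has no 'gi|<digits>|' prefix: {first!r}"
        )
    if not sequence:
        where = f" at line {line_no}" if line_no is not None else ""
        raise EmptyRecordError(f"record {first!r}{where} has an empty sequence")
    canonical = first.split()[0].rstrip("|")
    return ReferenceRecord(
        primary_gi=int(m.group(1)),
        canonical_id=canonical,
        all_headers=headers,
        sequence=sequence.upper(),
    )


def parse_reference_fasta(stream: IO[str]) -> Iterator[ReferenceRecord]:
    """Lazily parse nr-dialect protein FASTA into :class:`ReferenceRecord`.

    The primary GI is taken from the first SOH-separated sub-header of each
    defline.  A first sub-header without a ``gi|<digits>|`` prefix raises
    :class:`MalformedHeaderError` naming the offending line; an empty sequence
    body raises :class:`EmptyRecordError`.
    """
    reader = _LineCountingReader(stream)
    for idx, (title, sequence) in enumerate(SimpleFastaParser(reader)):
        yield _record_from_title(title, sequence.replace(" ", ""), reader.header_lines[idx])


def write_fasta(records: Iterable[ReferenceRecord], stream: IO[str], wrap: int = 60) -> int:
    """Write records as FASTA with 60-column wrapping; returns the record count.

    SOH-joined multi-headers are emitted exactly as stored.
    """
    count = 0
    for rec in records:
        stream.write(">" + SOH.join(rec.all_headers) + "\n")
        seq = rec.sequence
        for i in range(0, len(seq), wrap):
            stream.write(seq[i : i + wrap] + "\n")
        count += 1
    return count


def extract_by_gi(
    refdb: "IO[str] | Iterable[ReferenceRecord]",
    gi_set: Set[int],
    unmatched_out: Optional[Set[int]] = None,
) -> Iterator[ReferenceRecord]:
    """Stream exactly the records whose primary GI is in ``gi_set``.

    A single pass over the database; memory use is proportional to the GI set,
    never to the database.  GIs absent from the database are not an error:
    their count is logged and, if ``unmatched_out`` is given, the leftover GIs
    are placed there once the stream is exhausted.
    """
    if hasattr(refdb, "read"):
        records: Iterable[ReferenceRecord] = parse_reference_fasta(refdb)  # type: ignore[arg-type]
    else:
        records = refdb  # already parsed
    remaining = set(gi_set)
    for rec in records:
        if rec.primary_gi in remaining:
            remaining.discard(rec.primary_gi)
            yield rec
    if remaining:
        logger.warning("%d GI(s) in the selection were not found in the database", len(remaining))
    if unmatched_out is not None:
        unmatched_out.update(remaining)


def parse_reads_fasta(stream: IO[str]) -> list:
    """Parse DNA reads FASTA into ``[(read_id, sequence), ...]``.

    The read id is the first whitespace-delimited token of the defline.
    """
    return [
        (title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(stream)
    ]


def write_reads_fasta(reads: Iterable, stream: IO[str], wrap: int = 60) -> int:
    """Write ``(read_id, sequence)`` pairs as FASTA; returns the read count."""
    count = 0
    for read_id, seq in reads:
        stream.write(f">{read_id}\n")
        for i in range(0, len(seq), wrap):
            stream.write(seq[i : i + wrap] + "\n")
        count += 1
    return count


def read_gi_list(stream: IO[str]) -> Set[int]:
    """Read a GI list file: one decimal integer per line, ``#`` comments allowed."""
    gis: Set[int] = set()
    for line in stream:
        text = line.split("#", 1)[0].strip()
        if text:
            gis.add(int(text))
    return gis


def write_gi_list(gis: Iterable[int], stream: IO[str]) -> int:
    """Write GIs one per line in sorted order; returns the count."""
    count = 0
    for gi in sorted(gis):
        stream.write(f"{gi}\n")
        count += 1
    return count
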