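"""Reading and writing of FASTA, FASTQ and SAM, plus byte-range FASTQ access.

FASTQ files are treated as strict 4-line records (no wrapped sequence lines),
which is what every modern long-read basecaller emits and what makes
byte-offset arithmetic on shards well defined.  All internal coordinates are
0-based half-open; SAM POS is emitted 1-based per the SAM standard.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any symbol outside {A,C,G,T,N} to N (with a warning)."""
    seq = seq.upper()
    if _NON_ACGTN.search(seq):
        logger.warning("sequence contains non-ACGTN symbols; mapping them to N")
        seq = _NON_ACGTN.sub("N", seq)
    return seq


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional quality string and file offset."""

    id: str
    sequence: str
    quality: Optional[str] = None
    source_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> list[SequenceRecord]:
    """Parse a (possibly line-wrapped) FASTA file into SequenceRecords."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = [
        SequenceRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (strict 4-line records, byte-addressable)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ByteRange:
    """Half-open [start, end) byte interval of a file."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid byte range [{self.start}, {self.end})")


def _line_end(data: bytes, pos: int) -> int:
    """Offset one past the terminator of the line starting at pos."""
    nl = data.find(b"\n", pos)
    return len(data) if nl == -1 else nl + 1


def _is_record_head(data: bytes, pos: int) -> bool:
    """True if the line at pos starts a well-formed 4-line FASTQ record.

    A head is a line starting with '@' such that the line two lines later
    starts with '+' and the line after that has the same length as the
    sequence line.  The length check guards against '@' appearing as the
    first character of a quality string.
    """
    n = len(data)
    if pos >= n or data[pos : pos + 1] != b"@":
        return False
    e0 = _line_end(data, pos)
    if e0 >= n:
        return False
    e1 = _line_end(data, e0)  # sequence line ends at e1
    seq_len = e1 - e0 - (1 if e1 <= n and data[e1 - 1 : e1] == b"\n" else 0)
    if e1 >= n or data[e1 : e1 + 1] != b"+":
        return False
    e2 = _line_end(data, e1)
    e3 = _line_end(data, e2)
    qual_len = e3 - e2 - (1 if data[e3 - 1 : e3] == b"\n" else 0)
    return qual_len == seq_len


def _locate_head(data: bytes, offset: int) -> int:
    n = len(data)
    if offset >= n:
        return n
    # move to the first line start >= offset
    if offset == 0 or data[offset - 1 : offset] == b"\n":
        pos = offset
    else:
        nl = data.find(b"\n", offset)
        if nl == -1:
            raise ValueError("malformed FASTQ: no record head before EOF")
        pos = nl + 1
    while pos < n:
        if _is_record_head(data, pos):
            return pos
        pos = _line_end(data, pos)
    # No head after offset: legal only when the remainder is the tail of the
    # file's final record, which a clean whole-file parse establishes.
    scan = 0
    while scan < n:
        if not _is_record_head(data, scan):
            raise ValueError("malformed FASTQ: no record head before EOF")
        e0 = _line_end(data, scan)
        e1 = _line_end(data, e0)
        e2 = _line_end(data, e1)
        scan = _line_end(data, e2)
    return n


def locate_record_head(path: str, offset: int) -> int:
    """Smallest record-head byte offset >= offset (file size if none at EOF)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if not (0 <= offset <= len(data)):
        raise ValueError(f"offset {offset} outside file of size {len(data)}")
    return _locate_head(data, offset)


def _parse_record_at(data: bytes, pos: int) -> tuple[SequenceRecord, int]:
    """Parse the 4-line record starting at pos; return (record, next offset)."""
    if not _is_record_head(data, pos):
        raise ValueError(f"offset {pos} is not a FASTQ record head")
    e0 = _line_end(data, pos)
    e1 = _line_end(data, e0)
    e2 = _line_end(data, e1)
    e3 = _line_end(data, e2)
    head = data[pos:e0].rstrip(b"\n").decode()
    seq = data[e0:e1].rstrip(b"\n").decode()
    qual = data[e2:e3].rstrip(b"\n").decode()
    rec_id = head[1:].split()[0] if len(head) > 1 else ""
    return (
        SequenceRecord(
            id=rec_id,
            sequence=normalize_sequence(seq),
            quality=qual,
            source_offset=pos,
        ),
        e3,
    )


def read_fastq_range(path: str, byte_range: ByteRange) -> list[SequenceRecord]:
    """Return exactly the records whose heads lie in [start, end).

    Both range endpoints must coincide with a record head or end-of-file,
    which is what refine_split / locate_record_head guarantee.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    n = len(data)
    start, end = byte_range.start, byte_range.end
    if start > n or end > n:
        raise ValueError(f"range [{start}, {end}) outside file of size {n}")
    for endpoint in (start, end):
        if endpoint < n and _locate_head(data, endpoint) != endpoint:
            raise ValueError(f"byte offset {endpoint} is not a record head")
    records: list[SequenceRecord] = []
    pos = start
    while pos < end:
        rec, pos = _parse_record_at(data, pos)
        records.append(rec)
    return records


def read_fastq(path: str) -> list[SequenceRecord]:
    size = os.path.getsize(path)
    return read_fastq_range(path, ByteRange(0, size))


def write_fastq(records: Iterable[SequenceRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def scan_record_offsets(path: str) -> np.ndarray:
    """Byte offsets of every record head, with the file size appended."""
    with open(path, "rb") as fh:
        data = fh.read()
    offsets = []
    pos = 0
    while pos < len(data):
        if not _is_record_head(data, pos):
            raise ValueError(f"malformed FASTQ at byte {pos}")
        offsets.append(pos)
        e0 = _line_end(data, pos)
        e1 = _line_end(data, e0)
        e2 = _line_end(data, e1)
        pos = _line_end(data, e2)
    offsets.append(len(data))
    return np.asarray(offsets, dtype=np.int64)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_QUERY_CONSUMING = frozenset("MIS=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 1-based; 0 for unmapped
    mapq: int
    cigar: str
    seq: str
    qual: str = "*"
    score: Optional[int] = None  # emitted as AS:i: when present
    read_index: int = 0  # input order, used as the deterministic sort key

    @property
    def is_mapped(self) -> bool:
        return not (self.flag & 0x4)

    def validate(self) -> None:
        if not (0 <= self.mapq <= 60):
            raise ValueError(f"{self.qname}: MAPQ {self.mapq} outside [0, 60]")
        if self.is_mapped:
            if self.pos < 1:
                raise ValueError(f"{self.qname}: mapped record with POS {self.pos}")
            ops = _CIGAR_RE.findall(self.cigar)
            if "".join(f"{n}{op}" for n, op in ops) != self.cigar:
                raise ValueError(f"{self.qname}: bad CIGAR {self.cigar!r}")
            qlen = sum(int(n) for n, op in ops if op in _QUERY_CONSUMING)
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.qname}: CIGAR consumes {qlen} query bases, "
                    f"sequence has {len(self.seq)}"
                )
        else:
            if self.rname != "*":
                raise ValueError(f"{self.qname}: unmapped record with RNAME set")

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            "*",
            "0",
            "0",
            self.seq,
            self.qual if self.qual else "*",
        ]
        if self.score is not None:
            fields.append(f"AS:i:{self.score}")
        return "\t".join(fields)


def write_sam(
    records: Sequence[SamRecord],
    reference: SequenceRecord,
    path: str,
    program: str = "rhtmap",
    version: str = "0.1.0",
    command_line: Optional[str] = None,
) -> None:
    """Emit a SAM v1.6 file; records are sorted by their input read index so
    the output is independent of worker scheduling."""
    for rec in records:
        rec.validate()
    ordered = sorted(records, key=lambda r: r.read_index)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference.id}\tLN:{len(reference.sequence)}\n")
        pg = f"@PG\tID:{program}\tPN:{program}\tVN:{version}"
        if command_line:
            pg += f"\tCL:{command_line}"
        fh.write(pg + "\n")
        for rec in ordered:
            fh.write(rec.to_line() + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
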