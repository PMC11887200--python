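"""Readers and writers for FASTA, FASTQ, BED and PAF.

FASTA parsing is case-preserving because lowercase bases in a draft
assembly are meaningful: soft-masking marks unpolished sequence, and the
targeting stage keys off it.  Read (FASTQ/FASTA) sequences, by contrast,
are folded to uppercase on ingest — only the assembly's case carries
information.  All coordinates everywhere in this package are 0-based,
half-open, matching BED and PAF natively.

Gzip input is detected by magic bytes, never by file extension.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio import SeqIO

PathLike = Union[str, Path]

_SEQ_ALPHABET = re.compile(r"[^ACGTNacgtn]")


class FormatError(ValueError):
    """A file violates its format contract (parse or validation failure)."""


def _open_text(path: PathLike) -> IO[str]:
    """Open ``path`` as text, transparently decompressing gzip.

    Detection uses the two gzip magic bytes, so misleading extensions
    (``reads.fq`` that is actually gzipped, or ``.gz`` that is not) are
    handled correctly.
    """
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


@dataclass
class SequenceRecord:
    """A named sequence; ``name`` is the first whitespace token of the header."""

    name: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PafRecord:
    """One read-to-assembly alignment block (12 mandatory PAF columns).

    Columns 13+ are carried opaquely in ``tags`` and round-trip unchanged.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int
    tags: list[str] = field(default_factory=list)

    def validate(self, where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        if self.strand not in ("+", "-"):
            raise FormatError(f"PAF strand must be + or -, got {self.strand!r}{ctx}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise FormatError(
                f"PAF query interval invalid: 0 <= {self.query_start} < "
                f"{self.query_end} <= {self.query_len} fails{ctx}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise FormatError(
                f"PAF target interval invalid: 0 <= {self.target_start} < "
                f"{self.target_end} <= {self.target_len} fails{ctx}"
            )
        if not (self.block_len >= self.n_matches >= 0):
            raise FormatError(
                f"PAF requires block_len >= n_matches >= 0, got "
                f"{self.block_len} / {self.n_matches}{ctx}"
            )
        if not (0 <= self.mapq <= 255):
            raise FormatError(f"PAF mapq out of range: {self.mapq}{ctx}")

    def to_line(self) -> str:
        fields = [
            self.query_name,
            str(self.query_len),
            str(self.query_start),
            str(self.query_end),
            self.strand,
            self.target_name,
            str(self.target_len),
            str(self.target_start),
            str(self.target_end),
            str(self.n_matches),
            str(self.block_len),
            str(self.mapq),
            *self.tags,
        ]
        return "\t".join(fields)


@dataclass
class BedInterval:
    """A BED interval: 0-based half-open ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int


def read_fasta(path: PathLike, validate_alphabet: bool = True) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file, preserving base case.

    Raises :class:`FormatError` on an empty file, a duplicate record name,
    or (when ``validate_alphabet``) a character outside ``ACGTNacgtn``,
    naming the offending record and position.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA record name {rec.id!r} in {path}")
            seen.add(rec.id)
            if not seq:
                raise FormatError(f"record {rec.id!r} in {path} has empty sequence")
            if validate_alphabet:
                bad = _SEQ_ALPHABET.search(seq)
                if bad:
                    raise FormatError(
                        f"illegal character {bad.group()!r} at position "
                        f"{bad.start()} of record {rec.id!r} in {path}"
                    )
            records.append(SequenceRecord(rec.id, seq, desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def read_reads(path: PathLike) -> list[SequenceRecord]:
    """Read long reads from FASTA or FASTQ (either optionally gzipped).

    Sequences are folded to uppercase; FASTQ qualities are discarded (the
    polisher never consults base qualities).  The format is sniffed from
    the first character.
    """
    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == "@":
            fmt = "fastq"
        elif first == ">":
            fmt = "fasta"
        else:
            raise FormatError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, fmt):
            if rec.id in seen:
                raise FormatError(f"duplicate read name {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no reads in {path}")
    return records


def iter_paf(path: PathLike) -> Iterator[PafRecord]:
    """Stream validated PAF records from a (possibly gzipped) file."""
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF line has {len(cols)} columns, needs >= 12"
                )
            try:
                rec = PafRecord(
                    query_name=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_name=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    n_matches=int(cols[9]),
                    block_len=int(cols[10]),
                    mapq=int(cols[11]),
                    tags=cols[12:],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer PAF field: {exc}") from exc
            rec.validate(where=f"{path}:{lineno}")
            yield rec


def read_paf(path: PathLike) -> list[PafRecord]:
    """Read a whole PAF file; see :func:`iter_paf`."""
    return list(iter_paf(path))


def write_paf(records: Iterable[PafRecord], path: PathLike) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(rec.to_line())
            out.write("\n")


def read_bed(path: PathLike) -> list[BedInterval]:
    """Read a BED file (3+ columns); columns 4+ are ignored.

    ``track``/``browser`` lines and ``#`` comments are skipped.  Raises
    :class:`FormatError` for non-integer coordinates or start >= end.
    """
    intervals: list[BedInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinate"
                ) from exc
            if not 0 <= start < end:
                raise FormatError(
                    f"{path}:{lineno}: BED interval requires 0 <= start < end, "
                    f"got {start}..{end}"
                )
            intervals.append(BedInterval(cols[0], start, end))
    return intervals


def write_fastq(records: Sequence[SequenceRecord], path: PathLike) -> None:
    """Write FASTQ with constant placeholder qualities (the polisher never
    reads them)."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@{rec.name}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


def write_fasta(
    records: Sequence[SequenceRecord], path: PathLike, line_width: int = 60
) -> None:
    """Write FASTA with case preserved; round-trips through :func:`read_fasta`."""
    if line_width < 1:
        raise ValueError(f"line_width must be >= 1, got {line_width}")
    with open(path, "w") as out:
        for rec in records:
            header = rec.name if not rec.description else f"{rec.name} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                out.write(rec.sequence[i : i + line_width])
                out.write("\n")
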