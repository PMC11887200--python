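"""Splice polished target sequences back into the draft assembly.

The provenance coordinates are carried in the target FASTA headers
(``{contig}.{index}.{start}-{end}``); parsing is rightmost-first so contig
names containing dots or dashes survive.  Replacements are applied in
descending start order per contig so earlier coordinates stay valid when
indels change a target's length.  Polished slices are emitted uppercase by
default, signalling "polished" downstream (lowercase denotes unpolished
sequence in the drafts this tool targets); ``uppercase=False`` preserves
incoming case for exact round-trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .io_formats import FormatError, SequenceRecord
from .polisher import PolishOutcome

_NAME_RE = re.compile(r"^(?P<contig>.+)\.(?P<index>\d+)\.(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class ParsedTargetName:
    contig: str
    index: int
    start: int
    end: int


def parse_target_name(name: str) -> ParsedTargetName:
    """Recover (contig, index, start, end) from a target name.

    The regex is greedy on the contig part, which is exactly
    rightmost-delimiter parsing: the last ``-`` splits off ``end``, the
    last two ``.`` fields give ``start`` and ``index``.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise FormatError(f"target name {name!r} does not parse as contig.index.start-end")
    parsed = ParsedTargetName(
        m.group("contig"), int(m.group("index")), int(m.group("start")), int(m.group("end"))
    )
    if parsed.start >= parsed.end:
        raise FormatError(f"target name {name!r} has start >= end")
    return parsed


def reinsert(
    assembly: Sequence[SequenceRecord],
    polished: Sequence[PolishOutcome],
    uppercase: bool = True,
) -> list[SequenceRecord]:
    """Replace each provenance slice with its polished sequence.

    Bases outside targets are byte-identical to the input; record order
    and headers are unchanged.  Raises on duplicate target names, unknown
    contigs, out-of-bounds or overlapping provenance intervals.
    """
    by_contig: dict[str, list[tuple[ParsedTargetName, str]]] = {}
    seen: set[str] = set()
    contigs = {rec.name for rec in assembly}
    for out in polished:
        if out.target_name in seen:
            raise ValueError(f"duplicate polished target name {out.target_name!r}")
        seen.add(out.target_name)
        parsed = parse_target_name(out.target_name)
        if parsed.contig not in contigs:
            raise KeyError(
                f"target {out.target_name!r} names unknown contig {parsed.contig!r}"
            )
        by_contig.setdefault(parsed.contig, []).append((parsed, out.sequence))

    result: list[SequenceRecord] = []
    for rec in assembly:
        slices = by_contig.get(rec.name)
        if not slices:
            result.append(rec)
            continue
        slices.sort(key=lambda item: item[0].start, reverse=True)
        prev_start = None
        seq = rec.sequence
        for parsed, new_seq in slices:
            if parsed.end > len(rec.sequence):
                raise ValueError(
                    f"target {parsed.contig}.{parsed.index} interval "
                    f"{parsed.start}-{parsed.end} exceeds contig length "
                    f"{len(rec.sequence)}"
                )
            if prev_start is not None and parsed.end > prev_start:
                raise ValueError(
                    f"overlapping provenance intervals on contig {rec.name!r}"
                )
            prev_start = parsed.start
            insert = new_seq.upper() if uppercase else new_seq
            seq = seq[: parsed.start] + insert + seq[parsed.end :]
        result.append(SequenceRecord(rec.name, seq, rec.description))
    return result
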