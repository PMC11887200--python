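"""Target-region selection: soft-mask scanning, flank extension, excision.

Targets are either maximal runs of soft-masked (lowercase) bases in the
draft assembly, or user-supplied BED intervals; when a BED file is given
it is authoritative and mask scanning is skipped.  Each raw interval is
extended by a fixed flank on both sides (default 64 bp) so the polisher
has anchoring k-mer context, then overlapping or touching extended
intervals are merged.  The excised sequence keeps its original case.

A target's name encodes its provenance — ``{contig}.{index}.{start}-{end}``
with 0-based half-open coordinates and a 1-based ordinal from the 5' end —
so the reinsertion stage can splice polished sequence back without any
side-channel metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import BedInterval, SequenceRecord

_SOFTMASK_RUN = re.compile(r"[acgtn]+")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open ``[start, end)`` on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class FlankPolicy:
    """Flank length added 5' and 3' of every raw target interval."""

    flank_len: int = 64

    def __post_init__(self) -> None:
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


@dataclass
class TargetRegion:
    """A merged, flank-extended target with its excised sequence.

    ``index`` is the 1-based ordinal of this target among its contig's
    targets in 5'→3' order; ``start``/``end`` are post-flank, post-merge
    coordinates on the source contig.
    """

    source_contig: str
    index: int
    start: int
    end: int
    sequence: str
    name: str


def find_softmasked_runs(record: SequenceRecord) -> list[GenomicInterval]:
    """Maximal runs of lowercase bases (a,c,g,t,n), left to right."""
    return [
        GenomicInterval(record.name, m.start(), m.end())
        for m in _SOFTMASK_RUN.finditer(record.sequence)
    ]


def expand_and_merge(
    intervals: Sequence[GenomicInterval], policy: FlankPolicy, contig_len: int
) -> list[GenomicInterval]:
    """Extend each interval by the flank, clamp to the contig, merge.

    Book-ended (touching) extended intervals merge too: a zero-length
    slice between adjacent targets would be useless at reinsertion.
    Output is sorted and pairwise disjoint.
    """
    if not intervals:
        return []
    contig = intervals[0].contig
    for iv in intervals:
        if iv.contig != contig:
            raise ValueError("expand_and_merge requires intervals on one contig")
        if iv.end > contig_len:
            raise ValueError(
                f"interval {iv.contig}:{iv.start}-{iv.end} exceeds contig "
                f"length {contig_len}"
            )
    extended = sorted(
        (max(0, iv.start - policy.flank_len), min(contig_len, iv.end + policy.flank_len))
        for iv in intervals
    )
    merged: list[tuple[int, int]] = [extended[0]]
    for start, end in extended[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end:  # overlap or book-ended
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return [GenomicInterval(contig, s, e) for s, e in merged]


def name_target(contig: str, index: int, start: int, end: int) -> str:
    """Format the provenance-encoding target name.

    The format is ``{contig}.{index}.{start}-{end}``.  Contig names may
    themselves contain dots and dashes; :func:`~targetpolish.reinsertion.
    parse_target_name` parses rightmost-first so the round-trip is exact.
    """
    if index < 1:
        raise ValueError("target index must be >= 1")
    if not start < end:
        raise ValueError("target start must be < end")
    return f"{contig}.{index}.{start}-{end}"


def extract_targets(
    assembly: Sequence[SequenceRecord],
    bed: Optional[Sequence[BedInterval]] = None,
    policy: FlankPolicy = FlankPolicy(),
) -> list[TargetRegion]:
    """Select, extend, merge and excise target regions from the assembly.

    Per contig the raw intervals are the BED intervals for that contig if
    ``bed`` is given (BED is authoritative; mask scanning is skipped),
    else the soft-masked runs.  Targets are returned in assembly order,
    indexed 1..n per contig in 5'→3' order.

    Raises if a BED contig is absent from the assembly or out of bounds.
    """
    by_contig: dict[str, SequenceRecord] = {rec.name: rec for rec in assembly}
    if bed is not None:
        unknown = {iv.contig for iv in bed} - set(by_contig)
        if unknown:
            raise KeyError(
                f"BED contig(s) not in assembly: {', '.join(sorted(unknown))}"
            )
        for iv in bed:
            if iv.end > len(by_contig[iv.contig]):
                raise ValueError(
                    f"BED interval {iv.contig}:{iv.start}-{iv.end} exceeds "
                    f"contig length {len(by_contig[iv.contig])}"
                )

    targets: list[TargetRegion] = []
    for rec in assembly:
        if bed is not None:
            raw = [
                GenomicInterval(iv.contig, iv.start, iv.end)
                for iv in bed
                if iv.contig == rec.name
            ]
            raw.sort(key=lambda iv: (iv.start, iv.end))
        else:
            raw = find_softmasked_runs(rec)
        if not raw:
            continue
        for idx, iv in enumerate(expand_and_merge(raw, policy, len(rec)), start=1):
            seq = rec.sequence[iv.start : iv.end]
            targets.append(
                TargetRegion(
                    source_contig=rec.name,
                    index=idx,
                    start=iv.start,
                    end=iv.end,
                    sequence=seq,
                    name=name_target(rec.name, idx, iv.start, iv.end),
                )
            )
    return targets


def targets_to_records(targets: Sequence[TargetRegion]) -> list[SequenceRecord]:
    """Render targets as FASTA records (header = target name, case kept)."""
    return [SequenceRecord(t.name, t.sequence) for t in targets]
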