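"""Liftover of read-to-assembly PAF records into target coordinates.

Each alignment block is intersected with the (disjoint) target regions of
its contig.  For every overlapped target one new record is emitted whose
target fields are rebased to the excised target sequence; reads touching
no target are discarded, which is the whole point of targeted polishing —
downstream stages never see off-target evidence.

Query coordinates are clipped proportionally (colinear assumption) rather
than via CIGAR: PAF here drives read-to-target assignment and Bloom-filter
population, not base-exact alignment, and mapper PAF may carry no CIGAR at
all.  For minus-strand alignments the query is clipped from the opposite
end, because PAF query coordinates are always on the original read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import PafRecord
from .targeting import TargetRegion

logger = logging.getLogger(__name__)


class TargetIndex:
    """Per-contig interval lookup from assembly coordinates to targets."""

    def __init__(self, targets: Sequence[TargetRegion]):
        self._trees: dict[str, IntervalTree] = {}
        for t in targets:
            tree = self._trees.setdefault(t.source_contig, IntervalTree())
            if tree.overlaps(t.start, t.end):
                raise ValueError(
                    f"overlapping targets on {t.source_contig} at "
                    f"{t.start}-{t.end}; targets must be disjoint"
                )
            tree.addi(t.start, t.end, t)

    def overlapping(self, contig: str, start: int, end: int) -> list[TargetRegion]:
        """Targets overlapping ``[start, end)`` on ``contig``, sorted by start."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda t: t.start)
        return hits


def build_target_index(targets: Sequence[TargetRegion]) -> TargetIndex:
    return TargetIndex(targets)


@dataclass
class LiftStats:
    """Counts logged by :func:`lift_paf`."""

    n_input: int = 0
    n_lifted: int = 0
    n_discarded: int = 0
    discarded_reads: set = field(default_factory=set)


def lift_record(
    rec: PafRecord, index: TargetIndex, min_overlap: int = 1
) -> list[PafRecord]:
    """Rebase one PAF record onto every target it overlaps.

    Returns zero or more records (zero when the block touches no target,
    two or more when it spans several disjoint targets — each emitted
    record is independent evidence for its target).  ``n_matches`` and
    ``block_len`` are scaled by the retained fraction of the block,
    floored, with floors of 0 raised to 1.
    """
    out: list[PafRecord] = []
    t_span = rec.target_end - rec.target_start
    q_span = rec.query_end - rec.query_start
    for target in index.overlapping(rec.target_name, rec.target_start, rec.target_end):
        ov_start = max(rec.target_start, target.start)
        ov_end = min(rec.target_end, target.end)
        if ov_end - ov_start < min_overlap:
            continue
        clip_left = ov_start - rec.target_start
        clip_right = rec.target_end - ov_end
        # Colinear proportional clipping of the query interval; minus-strand
        # blocks are clipped from the opposite read end.
        shrink_start = clip_left * q_span // t_span
        shrink_end = clip_right * q_span // t_span
        if rec.strand == "-":
            shrink_start, shrink_end = shrink_end, shrink_start
        q_start = rec.query_start + shrink_start
        q_end = rec.query_end - shrink_end
        # Proportional floors can collapse tiny overlaps; keep >= 1 bp.
        if q_end <= q_start:
            q_end = min(rec.query_len, q_start + 1)
            q_start = q_end - 1
        frac = (ov_end - ov_start) / t_span
        n_matches = int(rec.n_matches * frac)
        block_len = int(rec.block_len * frac)
        if rec.n_matches > 0 and n_matches == 0:
            n_matches = 1
        if rec.block_len > 0 and block_len == 0:
            block_len = 1
        n_matches = min(n_matches, block_len)
        out.append(
            replace(
                rec,
                query_start=q_start,
                query_end=q_end,
                target_name=target.name,
                target_len=len(target.sequence),
                target_start=ov_start - target.start,
                target_end=ov_end - target.start,
                n_matches=n_matches,
                block_len=block_len,
                tags=list(rec.tags),
            )
        )
    return out


def lift_paf(
    records: Iterable[PafRecord],
    index: TargetIndex,
    min_overlap: int = 1,
    stats: LiftStats | None = None,
) -> list[PafRecord]:
    """Lift every record; discard reads overlapping no target.

    Input order is preserved.  Counts (input, lifted, discarded) are
    logged at INFO level and accumulated into ``stats`` when given.
    """
    stats = stats if stats is not None else LiftStats()
    out: list[PafRecord] = []
    for rec in records:
        stats.n_input += 1
        lifted = lift_record(rec, index, min_overlap=min_overlap)
        if lifted:
            out.extend(lifted)
            stats.n_lifted += len(lifted)
        else:
            stats.n_discarded += 1
            stats.discarded_reads.add(rec.query_name)
    logger.info(
        "liftover: %d input records -> %d lifted, %d discarded",
        stats.n_input,
        stats.n_lifted,
        stats.n_discarded,
    )
    return out
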