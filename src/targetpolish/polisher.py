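"""The k-mer edit engine: Bloom-filter-guided correction of target sequences.

The engine scans each target left to right at a schedule of k-mer sizes
(largest first for specificity, then smaller k for sensitivity in thinly
covered stretches).  Wherever the current k-mer is absent from the reads'
Bloom filter, the base just past the last supported k-mer is the suspect:
candidate substitutions, insertions and deletions are enumerated there and
scored by the fraction of the following ``verify_window`` k-mers that the
filter supports after the edit.  A candidate is accepted only when its
support strictly exceeds both the unedited support and ``accept_fraction``;
after an accepted edit the scan rewinds k-1 bases so the new junction
k-mers are themselves verified.

There is no randomness anywhere in the engine: identical inputs give
byte-identical outputs, and targets are independent, so processing order
(or by-target parallelism) cannot change results.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import PafRecord
from .kmer_bloom import BloomFilterSet, build_filters
from .targeting import TargetRegion

logger = logging.getLogger(__name__)

_EDIT_PRIORITY = {"sub": 0, "del": 1, "ins": 2}


@dataclass(frozen=True)
class PolishParams:
    """Tunables of the edit engine.

    verify_window
        Number of subsequent k-mers checked per candidate edit; ``None``
        means "use k".  The default is small (4) on purpose: a window of
        j k-mers spans k+j-1 bases, and in the error-dense regions this
        tool targets (a few percent per base) a wide window almost always
        overlaps the *next* uncorrected error, capping the support any
        correct edit can reach.  With gap g bases to the next error, a
        correct edit scores min(g, j)/j, so j must be small relative to
        the expected error spacing.
    accept_fraction
        Fraction of those k-mers that must be present for a substitution
        to be accepted (strict inequality).  The default 0.45 with j=4
        demands 2 of 4 verification k-mers: a correct edit passes
        whenever it is followed by >= 2 clean bases (so even one of a
        pair of errors two bases apart is correctable), while a wrong
        edit needs two simultaneous Bloom false positives (~p^2 per
        candidate).
    indel_accept_fraction
        Stricter threshold applied to insertion and deletion candidates
        (default 0.7, i.e. 3 of 4 k-mers with the default window): a
        wrong substitution is locally contained, but a wrong indel
        shifts the reading frame of every downstream k-mer and tends to
        trigger compensating edits.
    max_indel
        Longest insertion or deletion attempted at one site.
    backtrack
        How many positions before the apparent absent-run start are also
        offered to the edit search.  A false-positive k-mer at the true
        run start shifts the apparent start right and would otherwise
        misplace the suspect base.
    """

    k_values: tuple[int, ...] = (32, 28, 24, 20)
    verify_window: Optional[int] = 4
    accept_fraction: float = 0.45
    indel_accept_fraction: float = 0.7
    max_indel: int = 5
    rounds_per_k: int = 1
    backtrack: int = 2

    def __post_init__(self) -> None:
        if not self.k_values:
            raise ValueError("k_values must be non-empty")
        if list(self.k_values) != sorted(set(self.k_values), reverse=True):
            raise ValueError("k_values must be strictly descending")
        if not 0.0 < self.accept_fraction <= 1.0:
            raise ValueError("accept_fraction must be in (0, 1]")
        if not 0.0 < self.indel_accept_fraction <= 1.0:
            raise ValueError("indel_accept_fraction must be in (0, 1]")
        if self.max_indel < 1 or self.rounds_per_k < 1:
            raise ValueError("max_indel and rounds_per_k must be >= 1")
        if self.backtrack < 0:
            raise ValueError("backtrack must be >= 0")

    def window_for(self, k: int) -> int:
        return self.verify_window if self.verify_window is not None else k


@dataclass(frozen=True)
class Edit:
    """One accepted edit, for the audit log."""

    type: str  # sub | ins | del
    position: int  # 0-based position in the target at time of application
    ref: str
    alt: str
    support: float
    k: int


@dataclass
class PolishOutcome:
    """Polished sequence for one target plus edit statistics."""

    target_name: str
    sequence: str
    n_subs: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_sites_visited: int = 0
    edits: list[Edit] = field(default_factory=list)

    @property
    def n_edits(self) -> int:
        return self.n_subs + self.n_ins + self.n_del


def kmer_support(
    seq: str, pos: int, params: PolishParams, filters: BloomFilterSet, k: int
) -> float:
    """Fraction of the next ``min(j, available)`` k-mers present in the filter.

    Windows containing non-ACGT characters count as absent.  Returns 0.0
    when no window fits.
    """
    j = params.window_for(k)
    sub = seq[pos : pos + k + j - 1]
    profile = filters.filters[k].presence_profile(sub)
    if len(profile) == 0:
        return 0.0
    return float(profile.sum()) / len(profile)


def _score(seq: str, pos: int, params: PolishParams, filters: BloomFilterSet, k: int) -> float:
    return kmer_support(seq, pos, params, filters, k)


def try_edit_at(
    seq: str, pos: int, params: PolishParams, filters: BloomFilterSet, k: int
) -> Optional[Edit]:
    """Best acceptable edit for the absent k-mer starting at ``pos``.

    The edited base is ``pos + k - 1`` — the first base not covered by the
    preceding (supported) k-mer.  Candidates: the 3 substitutions;
    deletions of 1..max_indel bases; insertions of 1..max_indel bases,
    longer insertions grown greedily base by base.  Ties break by edit
    type (substitution > deletion > insertion), then lexicographically.
    Returns None when no candidate strictly beats both the unedited
    support and ``accept_fraction``.
    """
    e = pos + k - 1
    if e >= len(seq):
        return None
    baseline = _score(seq, pos, params, filters, k)
    ref = seq[e]
    candidates: list[tuple[float, int, str, Edit]] = []

    for b in "ACGT":
        if b == ref.upper():
            continue
        cand = seq[:e] + b + seq[e + 1 :]
        s = _score(cand, pos, params, filters, k)
        candidates.append((s, _EDIT_PRIORITY["sub"], b, Edit("sub", e, ref, b, s, k)))

    # a perfect substitution cannot be beaten (ties resolve by type priority)
    if not any(c[0] >= 1.0 for c in candidates):
        for d in range(1, params.max_indel + 1):
            if e + d > len(seq):
                break
            cand = seq[:e] + seq[e + d :]
            s = _score(cand, pos, params, filters, k)
            candidates.append(
                (s, _EDIT_PRIORITY["del"], f"{d:02d}", Edit("del", e, seq[e : e + d], "", s, k))
            )

    if not any(c[0] >= 1.0 for c in candidates):
        # Insertions are grown greedily, guided by the left-anchored score
        # (windows verifying prefix+insert against the reads), but each
        # candidate is *accepted* on the junction-anchored score at
        # pos+len(ins), whose every window crosses the insert back into the
        # pre-existing downstream sequence.  Scoring insertions only on
        # left-anchored windows would let the engine "rebuild" read
        # sequence indefinitely without ever verifying the junction.
        ins = ""
        for _ in range(params.max_indel):
            best_b, best_left = None, -1.0
            for b in "ACGT":
                cand = seq[:e] + ins + b + seq[e:]
                s = _score(cand, pos, params, filters, k)
                if s > best_left:
                    best_b, best_left = b, s
            ins += best_b
            cand = seq[:e] + ins + seq[e:]
            s = _score(cand, pos + len(ins), params, filters, k)
            candidates.append(
                (s, _EDIT_PRIORITY["ins"], ins, Edit("ins", e, "", ins, s, k))
            )
            if s >= 1.0:
                break

    def _threshold(kind: str) -> float:
        # a wrong indel shifts the frame and invites compensating edits
        # downstream, so indels must clear a higher bar than substitutions
        if kind == "sub":
            return params.accept_fraction
        return max(params.accept_fraction, params.indel_accept_fraction)

    acceptable = [
        c
        for c in candidates
        if c[0] > baseline and c[0] > _threshold(c[3].type)
    ]
    if not acceptable:
        return None
    acceptable.sort(key=lambda c: (-c[0], c[1], c[2]))
    return acceptable[0][3]


def _apply(seq: str, edit: Edit) -> str:
    e = edit.position
    if edit.type == "sub":
        return seq[:e] + edit.alt + seq[e + 1 :]
    if edit.type == "del":
        return seq[:e] + seq[e + len(edit.ref) :]
    if edit.type == "ins":
        return seq[:e] + edit.alt + seq[e:]
    raise ValueError(f"unknown edit type {edit.type!r}")


def polish_target(
    target: TargetRegion, filters: BloomFilterSet, params: PolishParams = PolishParams()
) -> PolishOutcome:
    """Polish one target with its per-target filters.

    Targets shorter than the smallest k are returned unchanged; k values
    longer than the target are skipped.  A target whose every k-mer is
    supported is a fixed point.
    """
    outcome = PolishOutcome(target.name, target.sequence)
    seq = target.sequence
    usable_ks = [k for k in params.k_values if k <= len(seq)]
    for k in usable_ks:
        filt = filters.filters[k]
        for _ in range(params.rounds_per_k):
            seq, made = _scan_pass(seq, filt, filters, params, k, outcome)
            if not made:
                break
    outcome.sequence = seq
    return outcome


def _scan_pass(seq, filt, filters, params, k, outcome) -> tuple[str, int]:
    """One left-to-right pass at one k; returns (new seq, edits applied).

    Every accepted edit must strictly reduce the target's absent-k-mer
    count, else it is reverted and the site is skipped for the rest of
    the pass.  Membership filters cannot measure repeat copy number, so
    without this progress rule a microsatellite can absorb an unbounded
    run of "supported" repeat-unit insertions that never resolve the
    absent run that triggered them.
    """
    applied = 0
    scan_from = 0
    skipped: list[int] = []  # run starts with reverted (no-progress) edits
    max_edits = len(seq) // 4 + 64
    while True:
        profile = filt.presence_profile(seq)
        # attempt edits only at the start of each maximal absent run: that
        # is the first k-mer not covered by a preceding supported one, so
        # its last base is the suspect position
        absent = ~profile
        starts = absent.copy()
        starts[1:] &= profile[:-1]
        ends = absent.copy()
        ends[:-1] &= profile[1:]
        run_starts = np.flatnonzero(starts)
        run_ends = np.flatnonzero(ends)
        i = int(np.searchsorted(run_starts, scan_from))
        advanced = False
        n_absent = int(absent.sum())
        skipped_set = set(skipped)
        for pos, last in zip(run_starts[i:], run_ends[i:]):
            pos, last = int(pos), int(last)
            if pos in skipped_set:
                continue
            outcome.n_sites_visited += 1
            # Candidate anchors: the run start (suspect = its last base),
            # a couple of earlier positions (a spuriously present k-mer at
            # the true run start shifts the apparent start right), and the
            # run end (for an isolated error the last absent k-mer starts
            # at the error, however much of the run's left side is masked
            # by read-error k-mers).
            anchors = [pos - b for b in range(params.backtrack + 1)]
            if last - (k - 1) > pos:
                anchors.append(last - (k - 1))
            best: Optional[Edit] = None
            for p in anchors:
                if p < 0:
                    continue
                cand = try_edit_at(seq, p, params, filters, k)
                if cand is not None and (
                    best is None
                    or (cand.support, -_EDIT_PRIORITY[cand.type])
                    > (best.support, -_EDIT_PRIORITY[best.type])
                ):
                    best = cand
            edit = best
            if edit is None:
                continue
            new_seq = _apply(seq, edit)
            if int((~filt.presence_profile(new_seq)).sum()) >= n_absent:
                # supported but unproductive (e.g. a repeat-unit
                # insertion): revert and leave the site alone this pass
                skipped.append(pos)
                skipped_set.add(pos)
                continue
            delta = len(new_seq) - len(seq)
            if delta:
                skipped = [
                    s + delta if s > edit.position else s for s in skipped
                ]
            seq = new_seq
            outcome.edits.append(edit)
            if edit.type == "sub":
                outcome.n_subs += 1
            elif edit.type == "ins":
                outcome.n_ins += 1
            else:
                outcome.n_del += 1
            applied += 1
            # rewind so the new junction k-mers are re-verified; never past
            # the start of the run we just edited (it may hold more errors)
            scan_from = max(0, min(pos, edit.position - (k - 1)))
            advanced = True
            break
        if not advanced or applied >= max_edits:
            return seq, applied


def group_reads_by_target(
    lifted: Iterable[PafRecord], reads: Mapping[str, str]
) -> Dict[str, list[str]]:
    """Clipped read subsequences per target, from lifted PAF records.

    The lifted query interval selects the portion of the read that maps
    inside the target, so each target's filters see only local evidence.
    Strand is irrelevant (canonical k-mers).
    """
    by_target: Dict[str, list[str]] = {}
    for rec in lifted:
        try:
            read_seq = reads[rec.query_name]
        except KeyError:
            raise KeyError(
                f"lifted PAF references unknown read {rec.query_name!r}"
            ) from None
        by_target.setdefault(rec.target_name, []).append(
            read_seq[rec.query_start : rec.query_end]
        )
    return by_target


def _polish_one(job) -> PolishOutcome:
    """Worker for one target (picklable for process pools)."""
    target, read_seqs, fset, params, fpr, min_kmer_count = job
    if fset is None:
        fset = build_filters(
            target.name, read_seqs, params.k_values, fpr, min_count=min_kmer_count
        )
    return polish_target(target, fset, params)


def polish_all(
    targets: Sequence[TargetRegion],
    lifted: Sequence[PafRecord],
    reads: Mapping[str, str],
    params: PolishParams = PolishParams(),
    fpr: float = 0.01,
    filter_sets: Optional[Mapping[str, BloomFilterSet]] = None,
    min_kmer_count: int = 2,
    threads: int = 1,
) -> list[PolishOutcome]:
    """Polish every target independently; order-invariant and deterministic.

    ``filter_sets`` overrides per-target filter construction (used e.g. to
    study a single shared whole-assembly filter); by default one
    BloomFilterSet is built per target from its lifted reads.  With
    ``threads > 1`` targets are polished in worker processes; results are
    collected in target order, so output is identical to a serial run.
    """
    known = {t.name for t in targets}
    for rec in lifted:
        if rec.target_name not in known:
            raise KeyError(f"lifted PAF references unknown target {rec.target_name!r}")
    by_target = group_reads_by_target(lifted, reads)
    jobs = [
        (
            target,
            None if filter_sets is not None else by_target.get(target.name, []),
            None if filter_sets is None else filter_sets[target.name],
            params,
            fpr,
            min_kmer_count,
        )
        for target in targets
    ]
    if threads > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            outcomes = list(pool.map(_polish_one, jobs))
    else:
        outcomes = [_polish_one(job) for job in jobs]
    logger.info(
        "polished %d targets: %d subs, %d ins, %d del",
        len(outcomes),
        sum(o.n_subs for o in outcomes),
        sum(o.n_ins for o in outcomes),
        sum(o.n_del for o in outcomes),
    )
    return outcomes
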