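"""Synthetic data: truth genome, error-injected soft-masked draft, long reads.

The generator emulates the input state this tool is built for: a draft
assembly that is accurate except in identifiable windows — gap-filled with
raw read sequence and soft-masked lowercase — where substitution and indel
errors are concentrated, plus long reads sampled from the underlying truth
with their own (independent) error process.  A truth PAF of read origins,
projected onto draft coordinates, lets the whole pipeline run without an
external mapper.

Everything is driven by one explicit PCG64 generator seeded from the
config, so a fixed seed reproduces every byte on any platform.  What this
fixture does *not* emulate: ONT-style homopolymer bias, quality strings,
chimeric reads, or real repeat structure — passing tests show the engine's
correction mechanics, not performance on real genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .io_formats import PafRecord, SequenceRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic data.

    Defaults: a 200 kb two-contig genome with ten 2 kb soft-masked windows
    carrying 2% substitutions and 0.5% indels, covered 30x by ~10 kb reads
    at 1% error.  Each window additionally has one diverged paralog copy
    (98% identity) planted elsewhere in the genome — the segmental-
    duplication-like structure that makes read locality matter: a filter
    fed by all reads also contains the paralog's k-mers, which can mask a
    window error or lend support to a paralog-allele edit, whereas a
    per-target filter sees only locally mapped reads.  Set
    ``paralogs_per_window=0`` for a fully uniform-random genome.
    """

    genome_len: int = 200_000
    n_contigs: int = 2
    n_target_windows: int = 10
    window_len: int = 2_000
    sub_rate_in_window: float = 0.02
    indel_rate_in_window: float = 0.005
    read_len_mean: int = 10_000
    coverage: float = 30.0
    read_error_rate: float = 0.01
    paralogs_per_window: int = 1
    paralog_identity: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate_in_window, self.indel_rate_in_window, self.read_error_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if self.n_contigs < 1 or self.genome_len < self.n_contigs:
            raise ValueError("need at least 1 bp per contig")
        if not 0.0 < self.paralog_identity <= 1.0:
            raise ValueError("paralog_identity must be in (0, 1]")
        if self.paralogs_per_window < 0:
            raise ValueError("paralogs_per_window must be >= 0")


@dataclass(frozen=True)
class ErrorEvent:
    contig: str
    truth_pos: int
    type: str  # sub | ins | del
    ref: str  # truth bases consumed (sub: 1 base; del: deleted run; ins: "")
    alt: str  # draft bases emitted (sub: 1 base; ins: inserted run; del: "")


@dataclass
class ErrorLedger:
    """Exactly the injected truth→draft differences, plus window provenance."""

    events: List[ErrorEvent] = field(default_factory=list)
    # truth-coordinate windows per contig, sorted, non-overlapping
    windows: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def events_for(self, contig: str) -> List[ErrorEvent]:
        return sorted(
            (e for e in self.events if e.contig == contig), key=lambda e: e.truth_pos
        )

    def counts(self) -> Dict[str, int]:
        out = {"sub": 0, "ins": 0, "del": 0}
        for e in self.events:
            out[e.type] += 1
        return out

    def apply(self, truth: Sequence[SequenceRecord]) -> List[SequenceRecord]:
        """Replay the ledger onto the truth; reproduces the draft exactly
        (including lowercase windows)."""
        out = []
        for rec in truth:
            events = self.events_for(rec.name)
            pieces: List[str] = []
            cursor = 0
            for ev in events:
                pieces.append(rec.sequence[cursor : ev.truth_pos])
                if ev.type == "sub":
                    pieces.append(ev.alt)
                    cursor = ev.truth_pos + 1
                elif ev.type == "ins":
                    pieces.append(ev.alt + rec.sequence[ev.truth_pos])
                    cursor = ev.truth_pos + 1
                else:  # del
                    cursor = ev.truth_pos + len(ev.ref)
            pieces.append(rec.sequence[cursor:])
            seq = "".join(pieces)
            # lowercase the windows (draft coordinates)
            arr = list(seq)
            for w_start, w_end in self.windows.get(rec.name, []):
                d_start = self.to_draft_coord(rec.name, w_start, side="left")
                d_end = self.to_draft_coord(rec.name, w_end, side="left")
                arr[d_start:d_end] = seq[d_start:d_end].lower()
            out.append(SequenceRecord(rec.name, "".join(arr)))
        return out

    def _projection(self, contig: str) -> Tuple[np.ndarray, np.ndarray]:
        """Breakpoints and cumulative offsets for truth→draft projection."""
        thresholds, deltas = [], []
        for ev in self.events_for(contig):
            if ev.type == "ins":
                thresholds.append(ev.truth_pos)
                deltas.append(len(ev.alt))
            elif ev.type == "del":
                thresholds.append(ev.truth_pos + len(ev.ref))
                deltas.append(-len(ev.ref))
        return np.asarray(thresholds, dtype=np.int64), np.cumsum(
            np.asarray(deltas, dtype=np.int64)
        )

    def to_draft_coord(self, contig: str, truth_pos: int, side: str = "right") -> int:
        """Draft coordinate of a truth position (positions inside a deleted
        run map to the deletion site).  ``side="left"`` excludes an
        insertion sitting exactly at ``truth_pos`` — used for window start
        boundaries, whose leading insertion belongs inside the window."""
        thresholds, cum = self._projection(contig)
        i = int(np.searchsorted(thresholds, truth_pos, side=side))
        return truth_pos + (int(cum[i - 1]) if i else 0)


def _contig_lengths(config: FixtureConfig) -> List[int]:
    base = config.genome_len // config.n_contigs
    lens = [base] * config.n_contigs
    lens[0] += config.genome_len - base * config.n_contigs
    return lens


def _plan(config: FixtureConfig):
    """Window and paralog placement, a pure function of the config.

    Both :func:`make_truth` (which must plant paralog copies of the
    window regions) and :func:`make_draft` (which must inject errors into
    exactly those windows) derive the same plan from the same stream.
    """
    rng = np.random.default_rng([config.seed, 0xD])
    lens = _contig_lengths(config)
    windows = _place_windows(config, lens, rng)
    margin = 1000
    names = [f"ctg{i}" for i in range(1, len(lens) + 1)]
    occupied: Dict[str, List[Tuple[int, int]]] = {
        n: [(max(0, s - margin), e + margin) for s, e in windows.get(n, [])]
        for n in names
    }
    paralogs: List[Tuple[str, int, int, str, int]] = []
    weights = np.asarray(lens, dtype=float) / sum(lens)
    for contig in names:
        for w_start, w_end in windows.get(contig, []):
            for _ in range(config.paralogs_per_window):
                span = w_end - w_start
                placed = False
                for _attempt in range(10_000):
                    di = int(rng.choice(len(names), p=weights))
                    dst_contig, dst_len = names[di], lens[di]
                    if dst_len < span + 2 * margin:
                        continue
                    dst = int(rng.integers(margin, dst_len - margin - span + 1))
                    if all(
                        dst + span + 200 <= s or dst >= e + 200
                        for s, e in occupied[dst_contig]
                    ):
                        occupied[dst_contig].append((dst, dst + span))
                        paralogs.append((contig, w_start, w_end, dst_contig, dst))
                        placed = True
                        break
                if not placed:
                    raise ValueError("could not place paralog copies; genome too small")
    return lens, windows, paralogs


def make_truth(config: FixtureConfig) -> List[SequenceRecord]:
    """Random ACGT contigs plus diverged paralog copies of the windows.

    The base sequence is uniform-random; each planned target window is
    then copied to its planned destination with substitutions at rate
    ``1 - paralog_identity``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 0xA])
    lens, windows, paralogs = _plan(config)
    seqs: Dict[str, list] = {}
    for i, length in enumerate(lens, start=1):
        seqs[f"ctg{i}"] = list("".join(_BASES[c] for c in rng.integers(0, 4, size=length)))
    mut_rng = np.random.default_rng([config.seed, 0xE])
    for src_contig, w_start, w_end, dst_contig, dst in paralogs:
        copy = seqs[src_contig][w_start:w_end]
        for idx in range(len(copy)):
            if mut_rng.random() > config.paralog_identity:
                copy[idx] = _BASES[
                    (_BASES.index(copy[idx]) + int(mut_rng.integers(1, 4))) % 4
                ]
        seqs[dst_contig][dst : dst + len(copy)] = copy
    return [SequenceRecord(name, "".join(chars)) for name, chars in seqs.items()]


def _place_windows(
    config: FixtureConfig, lens: List[int], rng: np.random.Generator
) -> Dict[str, List[Tuple[int, int]]]:
    """Non-overlapping windows, margin from contig ends, spaced so their
    flank-extended targets stay distinct."""
    margin, min_gap = 1000, 500
    total = sum(lens)
    per_contig = [round(config.n_target_windows * L / total) for L in lens]
    while sum(per_contig) < config.n_target_windows:
        per_contig[int(np.argmax(lens))] += 1
    while sum(per_contig) > config.n_target_windows:
        per_contig[int(np.argmax(per_contig))] -= 1
    windows: Dict[str, List[Tuple[int, int]]] = {}
    for i, (length, n_win) in enumerate(zip(lens, per_contig), start=1):
        name = f"ctg{i}"
        placed: List[Tuple[int, int]] = []
        usable = length - 2 * margin - config.window_len
        if n_win and usable < 0:
            raise ValueError("windows do not fit on contig; shrink window_len")
        attempts = 0
        while len(placed) < n_win:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("could not place non-overlapping windows")
            start = int(rng.integers(margin, length - margin - config.window_len + 1))
            end = start + config.window_len
            if all(start >= e + min_gap or end + min_gap <= s for s, e in placed):
                placed.append((start, end))
        windows[name] = sorted(placed)
    return windows


def make_draft(
    truth: Sequence[SequenceRecord], config: FixtureConfig
) -> Tuple[List[SequenceRecord], ErrorLedger]:
    """Inject window-confined errors into the truth and soft-mask the windows.

    Everything outside the windows is uppercase and error-free; inside,
    substitutions and indels (length 1-3, short-biased) are injected at the
    configured per-base rates and the window is rendered lowercase.
    """
    rng = np.random.default_rng([config.seed, 0xB])
    _lens, windows, _paralogs = _plan(config)
    ledger = ErrorLedger(windows=windows)
    drafts = []
    for rec in truth:
        pieces: List[str] = []
        cursor = 0
        for w_start, w_end in ledger.windows.get(rec.name, []):
            pieces.append(rec.sequence[cursor:w_start])
            window_out: List[str] = []
            p = w_start
            while p < w_end:
                base = rec.sequence[p]
                u = rng.random()
                if u < config.sub_rate_in_window:
                    alt = _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]
                    ledger.events.append(ErrorEvent(rec.name, p, "sub", base, alt))
                    window_out.append(alt)
                    p += 1
                elif u < config.sub_rate_in_window + config.indel_rate_in_window:
                    length = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
                    if rng.random() < 0.5 and p + length < w_end:
                        ref = rec.sequence[p : p + length]
                        ledger.events.append(ErrorEvent(rec.name, p, "del", ref, ""))
                        p += length
                    else:
                        ins = "".join(_BASES[c] for c in rng.integers(0, 4, size=length))
                        ledger.events.append(ErrorEvent(rec.name, p, "ins", "", ins))
                        window_out.append(ins + base)
                        p += 1
                else:
                    window_out.append(base)
                    p += 1
            pieces.append("".join(window_out).lower())
            cursor = w_end
        pieces.append(rec.sequence[cursor:])
        drafts.append(SequenceRecord(rec.name, "".join(pieces)))
    return drafts, ledger


def _mutate_read(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base errors: 3/4 substitution, 1/8 insertion, 1/8 deletion."""
    if rate <= 0.0:
        return seq
    n = len(seq)
    u = rng.random(n)
    err = u < rate
    if not err.any():
        return seq
    kind = u[err] / rate  # uniform in [0,1) given an error
    positions = np.flatnonzero(err)
    out: List[str] = []
    cursor = 0
    for pos, frac in zip(positions, kind):
        out.append(seq[cursor:pos])
        base = seq[pos]
        if frac < 0.75:  # substitution
            out.append(_BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4])
            cursor = pos + 1
        elif frac < 0.875:  # insertion before this base
            out.append(_BASES[int(rng.integers(0, 4))] + base)
            cursor = pos + 1
        else:  # deletion of this base
            cursor = pos + 1
            out.append("")
    out.append(seq[cursor:])
    return "".join(out)


def make_reads(
    truth: Sequence[SequenceRecord],
    config: FixtureConfig,
    ledger: Optional[ErrorLedger] = None,
) -> Tuple[List[SequenceRecord], List[PafRecord]]:
    """Sample long reads from the truth plus a PAF of their true origins.

    Read lengths are lognormal around ``read_len_mean``; strands are
    random; errors are applied per base at ``read_error_rate``.  When a
    ledger is given the PAF target coordinates are the read's true truth
    interval projected onto *draft* coordinates (what a mapper would
    report against the draft), so the pipeline needs no external mapper.
    """
    rng = np.random.default_rng([config.seed, 0xC])
    lens = [len(r) for r in truth]
    total_needed = config.genome_len * config.coverage
    weights = np.asarray(lens, dtype=float) / sum(lens)
    sigma = 0.25
    mu = math.log(config.read_len_mean) - sigma * sigma / 2.0

    draft_lens: Dict[str, int] = {}
    for rec in truth:
        delta = 0
        if ledger is not None:
            for ev in ledger.events_for(rec.name):
                delta += len(ev.alt) - len(ev.ref)
        draft_lens[rec.name] = len(rec) + delta

    reads: List[SequenceRecord] = []
    paf: List[PafRecord] = []
    sampled = 0
    i = 0
    while sampled < total_needed:
        i += 1
        ci = int(rng.choice(len(truth), p=weights))
        rec = truth[ci]
        rlen = int(np.clip(rng.lognormal(mu, sigma), 200, len(rec)))
        start = int(rng.integers(0, len(rec) - rlen + 1))
        end = start + rlen
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = rec.sequence[start:end]
        if strand == "-":
            fragment = _revcomp(fragment)
        read_seq = _mutate_read(fragment, config.read_error_rate, rng)
        name = f"read{i}"
        reads.append(SequenceRecord(name, read_seq))
        if ledger is not None:
            t_start = ledger.to_draft_coord(rec.name, start)
            t_end = ledger.to_draft_coord(rec.name, end)
        else:
            t_start, t_end = start, end
        span = t_end - t_start
        paf.append(
            PafRecord(
                query_name=name,
                query_len=len(read_seq),
                query_start=0,
                query_end=len(read_seq),
                strand=strand,
                target_name=rec.name,
                target_len=draft_lens[rec.name],
                target_start=t_start,
                target_end=t_end,
                n_matches=max(1, int(span * (1.0 - config.read_error_rate))),
                block_len=max(1, span),
                mapq=60,
            )
        )
        sampled += rlen
    return reads, paf


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _alignment_events(query: str, target: str) -> List[Tuple[int, str, int]]:
    """(target_pos, type, length) difference events from a global alignment
    of ``query`` against ``target`` (type: sub per base, ins/del per run)."""
    res = edlib.align(query, target, mode="NW", task="path")
    events: List[Tuple[int, str, int]] = []
    t = 0
    for length, op in _iter_cigar(res["cigar"]):
        if op == "=":
            t += length
        elif op == "X":
            for off in range(length):
                events.append((t + off, "sub", 1))
            t += length
        elif op == "I":  # present in query, absent from target
            events.append((t, "ins", length))
        elif op == "D":  # absent from query, present in target
            events.append((t, "del", length))
            t += length
    return events


def _iter_cigar(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def evaluate(
    polished: Sequence[SequenceRecord],
    truth: Sequence[SequenceRecord],
    ledger: ErrorLedger,
    flank: int = 64,
) -> Dict[str, float]:
    """Truth-aware assessment of a polished assembly.

    Globally aligns each polished contig against its truth contig and
    classifies every residual difference event by truth position:
    inside a window extended by ``flank`` (residual target error) or
    outside (off-target change — the pipeline must never introduce these).
    Reductions are reported relative to the injected ledger events.
    """
    truth_by_name = {r.name: r for r in truth}
    before = ledger.counts()
    errors_before = before["sub"] + before["ins"] + before["del"]
    after_sub = after_indel = offtarget = 0
    for rec in polished:
        if rec.name not in truth_by_name:
            raise KeyError(f"polished contig {rec.name!r} not in truth")
        tru = truth_by_name[rec.name]
        if rec.sequence.upper() == tru.sequence.upper():
            continue
        zones = [
            (max(0, s - flank), min(len(tru), e + flank))
            for s, e in ledger.windows.get(rec.name, [])
        ]
        for pos, kind, _length in _alignment_events(
            rec.sequence.upper(), tru.sequence.upper()
        ):
            in_zone = any(s <= pos < e for s, e in zones)
            if not in_zone:
                offtarget += 1
            elif kind == "sub":
                after_sub += 1
            else:
                after_indel += 1
    errors_after = after_sub + after_indel
    before_indel = before["ins"] + before["del"]

    def _pct(before_n: int, after_n: int) -> float:
        if before_n == 0:
            return 100.0 if after_n == 0 else 0.0
        return 100.0 * (before_n - after_n) / before_n

    return {
        "errors_before": errors_before,
        "errors_after": errors_after,
        "errors_after_sub": after_sub,
        "errors_after_indel": after_indel,
        "pct_reduction_sub": _pct(before["sub"], after_sub),
        "pct_reduction_indel": _pct(before_indel, after_indel),
        "pct_reduction_total": _pct(errors_before, errors_after),
        "offtarget_changes": offtarget,
    }
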