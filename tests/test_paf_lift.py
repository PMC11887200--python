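import numpy as np
import pytest

from targetpolish.io_formats import PafRecord
from targetpolish.paf_lift import LiftStats, build_target_index, lift_paf, lift_record
from targetpolish.targeting import TargetRegion, name_target


def make_target(contig, index, start, end):
    return TargetRegion(
        source_contig=contig,
        index=index,
        start=start,
        end=end,
        sequence="A" * (end - start),
        name=name_target(contig, index, start, end),
    )


def make_record(tname, tlen, tstart, tend, qlen=1000, strand="+", nm=None):
    span = tend - tstart
    rec = PafRecord(
        "read", qlen, 0, qlen, strand, tname, tlen, tstart, tend,
        nm if nm is not None else span, span, 60,
    )
    rec.validate()
    return rec


def random_disjoint_targets(rng, contig, contig_len, n):
    cuts = np.sort(rng.choice(np.arange(1, contig_len), size=2 * n, replace=False))
    targets = []
    for i in range(n):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if e > s:
            targets.append(make_target(contig, i + 1, s, e))
    return targets


class TestTargetIndex:
    def test_query_spanning_two_targets_returns_both(self):
        idx = build_target_index(
            [make_target("c1", 1, 10, 20), make_target("c1", 2, 30, 40)]
        )
        assert len(idx.overlapping("c1", 15, 35)) == 2

    def test_query_in_gap_returns_empty(self):
        idx = build_target_index(
            [make_target("c1", 1, 10, 20), make_target("c1", 2, 30, 40)]
        )
        assert idx.overlapping("c1", 20, 30) == []
        assert idx.overlapping("cX", 0, 100) == []

    def test_overlapping_targets_rejected_at_construction(self):
        with pytest.raises(ValueError, match="disjoint"):
            build_target_index(
                [make_target("c1", 1, 10, 30), make_target("c1", 2, 20, 40)]
            )

    def test_results_equal_linear_scan_on_random_queries(self):
        rng = np.random.default_rng(3)
        targets = random_disjoint_targets(rng, "c1", 100_000, 300)
        idx = build_target_index(targets)
        for _ in range(500):
            s = int(rng.integers(0, 99_000))
            e = int(rng.integers(s + 1, 100_000))
            expected = sorted(
                (t for t in targets if t.start < e and s < t.end),
                key=lambda t: t.start,
            )
            assert idx.overlapping("c1", s, e) == expected


class TestLiftRecord:
    def test_hand_arithmetic_example(self):
        idx = build_target_index([make_target("c1", 1, 150, 250)])
        (out,) = lift_record(make_record("c1", 500, 100, 300), idx)
        assert out.target_name == "c1.1.150-250"
        assert (out.target_start, out.target_end, out.target_len) == (0, 100, 100)

    def test_record_inside_target_is_unclipped(self):
        idx = build_target_index([make_target("c1", 1, 100, 900)])
        rec = make_record("c1", 1000, 200, 700, nm=450)
        (out,) = lift_record(rec, idx)
        assert out.target_end - out.target_start == 500
        assert out.n_matches == 450 and out.block_len == 500
        assert (out.query_start, out.query_end) == (rec.query_start, rec.query_end)

    def test_off_target_record_discarded(self):
        idx = build_target_index([make_target("c1", 1, 150, 250)])
        assert lift_record(make_record("c1", 500, 300, 400), idx) == []
        assert lift_record(make_record("c2", 500, 150, 250), idx) == []

    def test_record_spanning_two_targets_splits(self):
        idx = build_target_index(
            [make_target("c1", 1, 100, 200), make_target("c1", 2, 300, 400)]
        )
        outs = lift_record(make_record("c1", 1000, 50, 450), idx)
        assert [o.target_name for o in outs] == ["c1.1.100-200", "c1.2.300-400"]

    def test_minus_strand_clips_opposite_query_end(self):
        # asymmetric clipping: 50 bp off the left, 20 bp off the right
        idx = build_target_index([make_target("c1", 1, 150, 280)])
        plus = lift_record(make_record("c1", 500, 100, 300, strand="+"), idx)[0]
        minus = lift_record(make_record("c1", 500, 100, 300, strand="-"), idx)[0]
        # same 100bp clipped off each side of the block, so the kept query
        # interval is mirrored between strands
        assert plus.query_start == minus.query_len - minus.query_end
        assert plus.query_end == minus.query_len - minus.query_start

    def test_min_overlap_filter(self):
        idx = build_target_index([make_target("c1", 1, 150, 250)])
        rec = make_record("c1", 500, 245, 260)
        assert len(lift_record(rec, idx, min_overlap=1)) == 1
        assert lift_record(rec, idx, min_overlap=10) == []


class TestLiftPaf:
    def test_all_off_target_gives_empty_output_and_counts(self):
        idx = build_target_index([make_target("c1", 1, 500, 600)])
        stats = LiftStats()
        recs = [make_record("c1", 1000, 0, 100) for _ in range(5)]
        assert lift_paf(recs, idx, stats=stats) == []
        assert (stats.n_input, stats.n_lifted, stats.n_discarded) == (5, 0, 5)

    def test_unknown_contig_records_are_discarded_not_fatal(self):
        idx = build_target_index([make_target("c1", 1, 0, 100)])
        assert lift_paf([make_record("cZ", 500, 0, 100)], idx) == []

    def test_fuzzed_outputs_satisfy_coordinate_and_conservation_invariants(self):
        rng = np.random.default_rng(17)
        targets = random_disjoint_targets(rng, "c1", 50_000, 60)
        idx = build_target_index(targets)
        by_name = {t.name: t for t in targets}
        for _ in range(500):
            s = int(rng.integers(0, 49_000))
            e = int(rng.integers(s + 1, 50_000))
            rec = make_record("c1", 50_000, s, e, strand=str(rng.choice(["+", "-"])))
            outs = lift_record(rec, idx)
            lifted_span = 0
            for out in outs:
                t = by_name[out.target_name]
                assert 0 <= out.target_start < out.target_end <= len(t.sequence)
                assert 0 <= out.query_start < out.query_end <= out.query_len
                assert 0 <= out.n_matches <= out.block_len
                lifted_span += out.target_end - out.target_start
            assert lifted_span <= rec.target_end - rec.target_start

    def test_relifting_against_whole_target_index_is_identity(self):
        rng = np.random.default_rng(29)
        targets = random_disjoint_targets(rng, "c1", 20_000, 20)
        idx = build_target_index(targets)
        recs = []
        for _ in range(100):
            s = int(rng.integers(0, 19_000))
            e = int(rng.integers(s + 1, 20_000))
            recs.append(make_record("c1", 20_000, s, e))
        lifted = lift_paf(recs, idx)
        whole = build_target_index(
            [
                make_target(t.name, 1, 0, len(t.sequence))
                for t in targets
            ]
        )
        for rec in lifted:
            (again,) = lift_record(rec, whole)
            assert (again.target_start, again.target_end) == (
                rec.target_start,
                rec.target_end,
            )
            assert (again.query_start, again.query_end) == (
                rec.query_start,
                rec.query_end,
            )
            assert again.n_matches == rec.n_matches
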