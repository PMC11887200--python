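import numpy as np
import pytest

import edlib

from targetpolish.io_formats import PafRecord
from targetpolish.kmer_bloom import build_filters, canonical_kmer
from targetpolish.polisher import (
    PolishParams,
    kmer_support,
    polish_all,
    polish_target,
    try_edit_at,
)
from targetpolish.targeting import TargetRegion, name_target


def make_target(seq, contig="c", index=1, start=0):
    return TargetRegion(
        source_contig=contig,
        index=index,
        start=start,
        end=start + len(seq),
        sequence=seq,
        name=name_target(contig, index, start, start + len(seq)),
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def truth_2kb():
    rng = np.random.default_rng(101)
    return random_seq(rng, 2000)


class TestKmerSupport:
    def test_verbatim_substring_of_reads_scores_one(self):
        rng = np.random.default_rng(1)
        read = random_seq(rng, 300)
        fset = build_filters("t", [read, read], k_values=(16,))
        assert kmer_support(read[50:200], 10, PolishParams(k_values=(16,)), fset, 16) == 1.0

    def test_empty_filters_score_zero(self):
        fset = build_filters("t", [], k_values=(16,))
        assert kmer_support("ACGT" * 20, 0, PolishParams(k_values=(16,)), fset, 16) == 0.0

    def test_matches_sliding_window_scalar_oracle(self):
        rng = np.random.default_rng(2)
        reads = [random_seq(rng, 200) for _ in range(3)]
        fset = build_filters("t", reads, k_values=(9,), min_count=1)
        params = PolishParams(k_values=(9,), verify_window=6)
        probe = reads[0][:60] + random_seq(rng, 60)
        filt = fset.filters[9]
        for pos in range(0, len(probe) - 9):
            j = min(6, len(probe) - 9 + 1 - pos)
            expected = (
                sum(
                    canonical_kmer(probe, p, 9) is not None
                    and filt.contains(probe[p : p + 9])
                    for p in range(pos, pos + j)
                )
                / j
            )
            assert kmer_support(probe, pos, params, fset, 9) == pytest.approx(expected)


class TestTryEditAt:
    def setup_method(self):
        self.params = PolishParams(k_values=(8,))
        # periodic truth: minimal worked case for substitutions
        self.periodic = "ACGTACGTACGTACGTACGT"
        self.periodic_fset = build_filters(
            "t", [self.periodic], k_values=(8,), min_count=1
        )
        # random truth: unambiguous context for indel cases (in a perfect
        # repeat an indel of one unit is legitimately equally supported)
        rng = np.random.default_rng(33)
        self.truth = random_seq(rng, 80)
        self.fset = build_filters("t", [self.truth] * 2, k_values=(8,))

    def test_substitution_restoring_truth(self):
        draft = self.periodic[:10] + "T" + self.periodic[11:]  # truth has G at 10
        edit = try_edit_at(draft, 10 - 7, self.params, self.periodic_fset, 8)
        assert (edit.type, edit.position, edit.alt) == ("sub", 10, "G")

    def test_insertion_restores_deleted_base(self):
        draft = self.truth[:30] + self.truth[31:]
        edit = try_edit_at(draft, 30 - 7, self.params, self.fset, 8)
        assert (edit.type, edit.position, edit.alt) == ("ins", 30, self.truth[30])

    def test_deletion_removes_inserted_base(self):
        extra = "G" if self.truth[30] != "G" else "C"
        draft = self.truth[:30] + extra + self.truth[30:]
        edit = try_edit_at(draft, 30 - 7, self.params, self.fset, 8)
        assert (edit.type, edit.position, edit.ref) == ("del", 30, extra)

    def test_no_edit_without_supporting_evidence(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 200)
        unrelated = build_filters("t", [seq, seq], k_values=(8,))
        draft = self.truth[:30] + "T" + self.truth[31:]
        assert try_edit_at(draft, 30 - 7, self.params, unrelated, 8) is None


class TestPolishTarget:
    def test_no_reads_is_identity(self):
        target = make_target("ACGT" * 100)
        fset = build_filters(target.name, [], k_values=(32, 20))
        out = polish_target(target, fset, PolishParams(k_values=(32, 20)))
        assert out.sequence == target.sequence
        assert out.n_edits == 0

    def test_fully_supported_sequence_is_fixed_point(self, truth_2kb):
        target = make_target(truth_2kb)
        fset = build_filters(target.name, [truth_2kb] * 3, k_values=(32, 28, 24, 20))
        out = polish_target(target, fset)
        assert out.sequence == truth_2kb
        assert out.n_edits == 0

    def test_target_shorter_than_smallest_k_is_skipped(self):
        target = make_target("ACGTACGTAC")
        fset = build_filters(target.name, ["ACGTACGTAC"], k_values=(32, 20))
        out = polish_target(target, fset, PolishParams(k_values=(32, 20)))
        assert out.sequence == target.sequence and out.n_sites_visited == 0

    def _mutate(self, rng, truth, sub_rate=0.02, indel_rate=0.005):
        out = []
        for ch in truth:
            u = rng.random()
            if u < sub_rate:
                out.append("ACGT"[("ACGT".index(ch) + int(rng.integers(1, 4))) % 4])
            elif u < sub_rate + indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append("ACGT"[int(rng.integers(0, 4))] + ch)
            else:
                out.append(ch)
        return "".join(out)

    def test_recovers_injected_errors_with_clean_reads(self, truth_2kb):
        rng = np.random.default_rng(7)
        draft = self._mutate(rng, truth_2kb)
        dist_before = edlib.align(draft, truth_2kb)["editDistance"]
        # 30 error-free reads tiling the region
        reads = [truth_2kb] * 30
        target = make_target(draft)
        fset = build_filters(target.name, reads, k_values=(32, 28, 24, 20))
        out = polish_target(target, fset)
        dist_after = edlib.align(out.sequence, truth_2kb)["editDistance"]
        assert dist_before >= 40  # the draft really was corrupted
        assert dist_after <= 0.1 * dist_before  # >=90% of errors reverted

    def test_second_pass_applies_no_more_edits_than_first(self, truth_2kb):
        rng = np.random.default_rng(9)
        draft = self._mutate(rng, truth_2kb)
        reads = [truth_2kb] * 30
        target = make_target(draft)
        fset = build_filters(target.name, reads, k_values=(32, 28, 24, 20))
        first = polish_target(target, fset)
        second = polish_target(make_target(first.sequence), fset)
        assert second.n_edits <= first.n_edits

    def test_every_applied_edit_meets_its_support_threshold(self, truth_2kb):
        rng = np.random.default_rng(11)
        draft = self._mutate(rng, truth_2kb)
        target = make_target(draft)
        params = PolishParams()
        fset = build_filters(target.name, [truth_2kb] * 30, k_values=params.k_values)
        out = polish_target(target, fset, params)
        assert out.n_edits > 0
        for edit in out.edits:
            floor = (
                params.accept_fraction
                if edit.type == "sub"
                else max(params.accept_fraction, params.indel_accept_fraction)
            )
            assert edit.support > floor
        assert out.n_edits <= out.n_sites_visited


class TestPolishAll:
    def _setup(self, rng):
        truths = [random_seq(rng, 500), random_seq(rng, 500)]
        targets = [
            make_target(truths[0], contig="c1"),
            make_target(truths[1], contig="c2"),
        ]
        reads = {"r1": truths[0], "r2": truths[0], "r3": truths[1], "r4": truths[1]}
        lifted = [
            PafRecord(name, 500, 0, 500, "+", t.name, 500, 0, 500, 500, 500, 60)
            for name, t in [
                ("r1", targets[0]),
                ("r2", targets[0]),
                ("r3", targets[1]),
                ("r4", targets[1]),
            ]
        ]
        return targets, lifted, reads

    def test_target_order_does_not_change_outcomes(self):
        rng = np.random.default_rng(21)
        targets, lifted, reads = self._setup(rng)
        fwd = polish_all(targets, lifted, reads)
        rev = polish_all(targets[::-1], lifted, reads)
        assert {o.target_name: o.sequence for o in fwd} == {
            o.target_name: o.sequence for o in rev
        }

    def test_target_without_reads_is_unchanged(self):
        rng = np.random.default_rng(22)
        targets, lifted, reads = self._setup(rng)
        lifted = [r for r in lifted if r.target_name == targets[0].name]
        outs = polish_all(targets, lifted, reads)
        assert outs[1].sequence == targets[1].sequence
        assert outs[1].n_edits == 0

    def test_unknown_target_name_raises(self):
        rng = np.random.default_rng(23)
        targets, lifted, reads = self._setup(rng)
        stray = PafRecord("r1", 500, 0, 500, "+", "ghost.1.0-500", 500, 0, 500, 500, 500, 60)
        with pytest.raises(KeyError, match="ghost"):
            polish_all(targets, lifted + [stray], reads)

    def test_unknown_read_name_raises(self):
        rng = np.random.default_rng(24)
        targets, lifted, reads = self._setup(rng)
        del reads["r1"]
        with pytest.raises(KeyError, match="r1"):
            polish_all(targets, lifted, reads)

    def test_parallel_equals_serial(self):
        rng = np.random.default_rng(25)
        targets, lifted, reads = self._setup(rng)
        serial = polish_all(targets, lifted, reads)
        parallel = polish_all(targets, lifted, reads, threads=2)
        assert [o.sequence for o in serial] == [o.sequence for o in parallel]
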