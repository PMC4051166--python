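"""Correctness classification, shift rule, metrics and repeat recovery."""

import numpy as np
import pytest

from mapbench.genome_forge import RepeatMap, build_repeat_genome, random_contig
from mapbench.io_formats import (
    AlignmentObservation,
    ReadTruth,
    parse_sam,
)
from mapbench.map_eval import (
    Category,
    ShiftPolicy,
    build_truth_sam,
    classify_read,
    evaluate_mapping,
    evaluate_repeats,
    hit_satisfies,
    summarize,
)
from mapbench.simulate import SimulationConfig, simulate_dataset


def _hit(truth, **kw):
    base = dict(
        read_id=truth.read_id, mapped=True, contig=truth.contig,
        start=truth.start, end=truth.end, strand=truth.strand,
        clip_left=0, clip_right=0,
        n_ins=truth.n_ins, n_del=truth.n_del, n_sub=truth.n_sub,
    )
    base.update(kw)
    return AlignmentObservation(**base)


class TestClassifyRead:
    """The stringent rule: exact start, end and edit counts, with a per-end
    shift absorbing homopolymer indels at alignment extremities."""

    def test_homopolymer_start_shift_reconciled(self):
        # expected alignment: start 4031012, end 4031103, two deletions, no
        # insertions, one substitution; the mapper starts at 4031014 and
        # reports only the substitution — the 2-base shift re-counts the two
        # missing deletions, so the read is correctly mapped
        truth = ReadTruth("read1", "genome", 4031012, 4031103, "+", 0, 2, 1)
        hit = _hit(truth, start=4031014, n_del=0)
        for shift in (2, 5):
            out = classify_read(truth, [hit], ShiftPolicy(shift))
            assert out.category is Category.CORRECT
            assert out.satisfying_hit == hit

    def test_shift_cannot_forgive_substitution_mismatch(self):
        # the positional shift reconciles one missing deletion, but the
        # substitution counts differ, so the read is incorrectly mapped
        truth = ReadTruth("read2", "genome", 4031012, 4031103, "+", 0, 1, 1)
        hit = _hit(truth, start=4031013, n_del=0, n_sub=2)
        out = classify_read(truth, [hit], ShiftPolicy(5))
        assert out.category is Category.INCORRECT

    def test_perfect_hit_zero_shift(self):
        truth = ReadTruth("r1", "c", 100, 199, "+", 1, 2, 3)
        assert classify_read(truth, [_hit(truth)], ShiftPolicy(0)).category \
            is Category.CORRECT

    def test_no_mapped_hit_is_unmapped(self):
        truth = ReadTruth("r1", "c", 100, 199, "+", 0, 0, 0)
        unmapped = AlignmentObservation("r1", False)
        assert classify_read(truth, [], ShiftPolicy(5)).category is Category.UNMAPPED
        assert classify_read(truth, [unmapped], ShiftPolicy(5)).category \
            is Category.UNMAPPED

    def test_random_reads_split_by_mapping(self):
        truth = ReadTruth.random("r1")
        mapped = AlignmentObservation("r1", True, "c", 5, 10, "+")
        assert classify_read(truth, [mapped], ShiftPolicy(5)).category \
            is Category.RANDOM_MAPPED
        assert classify_read(truth, [], ShiftPolicy(5)).category \
            is Category.RANDOM_REJECTED

    def test_clipping_counts_as_missing_insertions(self):
        # 3 clipped bases at the left are 3 insertions the mapper dropped
        truth = ReadTruth("r1", "c", 100, 199, "+", 3, 0, 0)
        hit = _hit(truth, clip_left=3, n_ins=0)
        assert classify_read(truth, [hit], ShiftPolicy(3)).category \
            is Category.CORRECT
        # ... but clipping beyond the shift budget disqualifies the hit
        assert classify_read(truth, [hit], ShiftPolicy(2)).category \
            is Category.INCORRECT

    def test_wrong_strand_or_contig_incorrect(self):
        truth = ReadTruth("r1", "c", 100, 199, "+", 0, 0, 0)
        assert classify_read(truth, [_hit(truth, strand="-")],
                             ShiftPolicy(5)).category is Category.INCORRECT
        assert classify_read(truth, [_hit(truth, contig="other")],
                             ShiftPolicy(5)).category is Category.INCORRECT

    def test_any_satisfying_hit_suffices(self):
        truth = ReadTruth("r1", "c", 100, 199, "+", 0, 0, 0)
        bad = _hit(truth, start=500, end=599)
        assert classify_read(truth, [bad, _hit(truth)], ShiftPolicy(0)).category \
            is Category.CORRECT

    def test_read_id_mismatch_raises(self):
        truth = ReadTruth("r1", "c", 100, 199, "+", 0, 0, 0)
        with pytest.raises(ValueError):
            classify_read(truth, [AlignmentObservation("r2", True, "c", 100,
                                                       199, "+")], ShiftPolicy(0))

    def test_zero_shift_agrees_with_bruteforce_field_compare(self, rng):
        """With max_shift=0 the rule degenerates to exact equality of all
        fields and zero clipping; check against a direct comparison on
        10,000 randomized truth/hit pairs."""
        policy = ShiftPolicy(0)
        for i in range(10_000):
            start = int(rng.integers(1, 10**6))
            span = int(rng.integers(20, 400))
            truth = ReadTruth(
                "r", "c", start, start + span, "+",
                int(rng.integers(0, 4)), int(rng.integers(0, 4)),
                int(rng.integers(0, 4)),
            )
            hit = AlignmentObservation(
                "r", True, "c",
                start + int(rng.integers(-1, 2)),
                start + span + int(rng.integers(-1, 2)),
                "+",
                int(rng.integers(0, 2)), int(rng.integers(0, 2)),
                int(rng.integers(0, 4)), int(rng.integers(0, 4)),
                int(rng.integers(0, 4)),
            )
            expected = (
                hit.start == truth.start
                and hit.end == truth.end
                and hit.clip_left == 0 and hit.clip_right == 0
                and hit.n_ins == truth.n_ins
                and hit.n_del == truth.n_del
                and hit.n_sub == truth.n_sub
            )
            assert hit_satisfies(truth, hit, policy) is expected


class TestSummarize:
    def test_all_correct(self):
        truth = ReadTruth("r", "c", 1, 50, "+", 0, 0, 0)
        outcomes = [
            classify_read(truth, [_hit(truth)], ShiftPolicy(0))
            for _ in range(50)
        ]
        s = summarize(outcomes)
        assert (s.precision, s.recall, s.f_measure) == (1.0, 1.0, 1.0)

    def test_printed_formula_values(self):
        """TP=9, FP=1, FN=10: precision .9, recall 9/19, F = 2PR/(P+R)."""
        truth = ReadTruth("r", "c", 100, 199, "+", 0, 0, 0)
        outcomes = (
            [classify_read(truth, [_hit(truth)], ShiftPolicy(0))] * 9
            + [classify_read(truth, [_hit(truth, start=500, end=599)],
                             ShiftPolicy(0))]
            + [classify_read(truth, [], ShiftPolicy(0))] * 10
        )
        s = summarize(outcomes)
        assert s.precision == pytest.approx(0.9)
        assert s.recall == pytest.approx(9 / 19)
        assert s.f_measure == pytest.approx(2 * 0.9 * (9 / 19) / (0.9 + 9 / 19))
        assert s.f_measure == pytest.approx(0.6207, abs=1e-4)

    def test_all_unmapped_degenerate_convention(self):
        truth = ReadTruth("r", "c", 1, 50, "+", 0, 0, 0)
        s = summarize([classify_read(truth, [], ShiftPolicy(0))] * 5)
        assert (s.precision, s.recall, s.f_measure) == (0.0, 0.0, 0.0)

    def test_random_policy_literal_vs_exclude(self):
        outcomes = (
            [classify_read(ReadTruth("a", "c", 1, 50, "+", 0, 0, 0),
                           [_hit(ReadTruth("a", "c", 1, 50, "+", 0, 0, 0))],
                           ShiftPolicy(0))] * 19
            + [classify_read(ReadTruth.random("b"), [], ShiftPolicy(0))]
        )
        excl = summarize(outcomes, "exclude_random")
        lit = summarize(outcomes, "literal")
        assert excl.recall == 1.0
        assert lit.recall == pytest.approx(19 / 20)
        assert excl.fraction_mapped == lit.fraction_mapped == 0.95

    def test_category_counts_partition(self):
        outcomes = [
            classify_read(ReadTruth.random("a"), [], ShiftPolicy(0)),
            classify_read(ReadTruth("b", "c", 1, 50, "+", 0, 0, 0), [],
                          ShiftPolicy(0)),
        ]
        s = summarize(outcomes)
        assert sum(s.category_counts.values()) == len(outcomes)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize([])


class TestPerfectSamRoundTrip:
    def test_truth_sam_all_correct(self, small_reference, tmp_path):
        """A SAM built from the truth table classifies every non-random
        read CORRECT; precision = recall = F = 1 and fraction mapped equals
        the non-random fraction."""
        cfg = SimulationConfig(n_reads=2000, mean_length=150, seed=21)
        truths, seqs = simulate_dataset(cfg, small_reference)
        sam = tmp_path / "perfect.sam"
        build_truth_sam(truths, small_reference, sam, seqs)
        _, summary = evaluate_mapping(truths, parse_sam(sam), ShiftPolicy(5))
        assert summary.precision == 1.0
        assert summary.recall == 1.0
        assert summary.f_measure == 1.0
        assert summary.fraction_mapped == pytest.approx(0.95)

    def test_corruption_monotonicity(self, small_reference, tmp_path):
        """Shifting every hit start beyond the allowance turns every CORRECT
        read INCORRECT and precision collapses."""
        cfg = SimulationConfig(n_reads=500, mean_length=150, seed=22,
                               random_fraction=0.0)
        truths, seqs = simulate_dataset(cfg, small_reference)
        sam = tmp_path / "perfect.sam"
        build_truth_sam(truths, small_reference, sam, seqs)
        hits = parse_sam(sam)
        policy = ShiftPolicy(5)
        _, clean = evaluate_mapping(truths, hits, policy)
        assert clean.precision == 1.0
        shifted = {
            rid: [
                AlignmentObservation(
                    h.read_id, h.mapped, h.contig,
                    h.start + policy.max_shift + 1,
                    h.end + policy.max_shift + 1,
                    h.strand, h.clip_left, h.clip_right,
                    h.n_ins, h.n_del, h.n_sub,
                )
                for h in hs
            ]
            for rid, hs in hits.items()
        }
        _, corrupt = evaluate_mapping(truths, shifted, policy)
        assert corrupt.category_counts["CORRECT"] == 0
        assert corrupt.category_counts["INCORRECT"] == 500
        assert corrupt.precision == 0.0


class TestEvaluateRepeats:
    @pytest.fixture()
    def repeat_setup(self):
        rng = np.random.default_rng(31)
        contig, rmap = build_repeat_genome(50_000, 5, 500, 0.0, rng)
        offset = 40
        truth = ReadTruth(
            "r1", contig.name,
            rmap.intervals[0][0] + offset, rmap.intervals[0][0] + offset + 99,
            "+", 0, 0, 0,
        )
        hits = [
            AlignmentObservation("r1", True, contig.name, s + offset,
                                 s + offset + 99, "+")
            for s, _ in rmap.intervals
        ]
        return contig, rmap, truth, hits

    def test_full_recovery_is_class_n(self, repeat_setup):
        _, rmap, truth, hits = repeat_setup
        res = evaluate_repeats([truth], {"r1": hits}, rmap, ShiftPolicy(5))
        assert res.per_read["r1"] == 5
        assert res.histogram[5] == 100.0

    def test_removing_hits_lowers_class_monotonically(self, repeat_setup):
        _, rmap, truth, hits = repeat_setup
        for k in range(5, 0, -1):
            res = evaluate_repeats([truth], {"r1": hits[:k]}, rmap,
                                   ShiftPolicy(5))
            assert res.per_read["r1"] == k

    def test_read_outside_repeats_excluded(self, repeat_setup):
        contig, rmap, _, _ = repeat_setup
        outside = ReadTruth("r2", contig.name, 10, 109, "+", 0, 0, 0)
        res = evaluate_repeats([outside], {}, rmap, ShiftPolicy(5))
        assert res.n_repeat_reads == 0 and "r2" not in res.per_read

    def test_unequal_intervals_rejected(self):
        with pytest.raises(ValueError):
            RepeatMap(((1, 500), (1000, 1400)), 500, 0.0)
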