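import numpy as np
import pytest

from popvar.io import Interval, IntervalTrack
from popvar.sv import (
    ConsensusSV,
    SVCall,
    af_spectrum,
    annotate_repeat_overlap,
    filter_gap_overlap,
    intake_filter,
    merge_across_samples,
    merge_within_sample,
    reciprocal_overlap,
)


def dele(start, end, sample="s1", caller="pindel", chrom="chr1", support=5):
    return SVCall(chrom, start, end, "deletion", sample, caller, support)


class TestIntakeFilter:
    def test_below_50bp_dropped(self):
        kept, dropped = intake_filter([dele(100, 148)])  # 49 bp
        assert kept == []
        assert dropped["too_short"] == 1

    def test_caller_specific_caps(self):
        calls = [
            dele(100, 12_099, caller="pindel"),  # 12 kb > 10 kb cap
            dele(100, 12_099, caller="crest", sample="s2"),
        ]
        kept, dropped = intake_filter(calls)
        assert [c.caller for c in kept] == ["crest"]
        assert dropped["over_caller_cap"] == 1

    def test_fixture_counts(self):
        calls = (
            [dele(1000 * i, 1000 * i + 500) for i in range(1, 8)]  # 7 valid
            + [dele(100, 120), dele(200, 210)]  # 2 too short
            + [dele(50_000, 65_000, caller="pindel")]  # 1 over cap
        )
        kept, dropped = intake_filter(calls)
        assert len(kept) == 7
        assert dropped == {"too_short": 2, "over_caller_cap": 1}


class TestReciprocalOverlap:
    def test_identical(self):
        assert reciprocal_overlap(dele(100, 200), dele(100, 200)) == 1.0

    def test_shifted_arithmetic(self):
        # [100,200] vs [110,210], 1-based inclusive: overlap 91, lengths 101
        assert reciprocal_overlap(dele(100, 200), dele(110, 210)) == pytest.approx(91 / 101)

    def test_disjoint(self):
        assert reciprocal_overlap(dele(100, 200), dele(300, 400)) == 0.0

    def test_type_mismatch_zero(self):
        ins = SVCall("chr1", 100, 200, "inversion", "s1")
        assert reciprocal_overlap(dele(100, 200), ins) == 0.0


class TestMergeWithinSample:
    def test_mean_breakpoints(self):
        merged = merge_within_sample([dele(100, 200), dele(110, 210)])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (105, 205)
        assert merged[0].support == 10

    def test_low_overlap_unmerged(self):
        merged = merge_within_sample([dele(100, 200), dele(180, 280)])
        assert len(merged) == 2

    def test_three_way_merge_order_invariant(self, rng):
        calls = [dele(100, 300), dele(110, 310), dele(120, 320)]
        reference = merge_within_sample(calls)
        assert len(reference) == 1
        for _ in range(5):
            shuffled = list(calls)
            rng.shuffle(shuffled)
            got = merge_within_sample(shuffled)
            assert [(c.start, c.end, c.support) for c in got] == [
                (c.start, c.end, c.support) for c in reference
            ]

    def test_idempotent(self):
        calls = [dele(100, 300), dele(110, 310), dele(500, 900), dele(2000, 2500)]
        once = merge_within_sample(calls)
        twice = merge_within_sample(once)
        assert [(c.start, c.end) for c in once] == [(c.start, c.end) for c in twice]

    def test_insertions_merged_by_breakpoint_distance(self):
        a = SVCall("chr1", 1000, 1000, "insertion", "s1")
        b = SVCall("chr1", 1050, 1050, "insertion", "s1")
        c = SVCall("chr1", 1200, 1200, "insertion", "s1")
        merged = merge_within_sample([a, b, c])
        assert len(merged) == 2
        assert {m.start for m in merged} == {1025, 1200}

    def test_multiple_samples_rejected(self):
        with pytest.raises(ValueError):
            merge_within_sample([dele(1, 100, sample="s1"), dele(1, 100, sample="s2")])


class TestMergeAcrossSamples:
    def test_jittered_carriers_one_consensus(self):
        calls = [
            dele(1000, 2000, sample="s1"),
            dele(1010, 2010, sample="s2"),
            dele(990, 1995, sample="s3"),
        ]
        out = merge_across_samples(calls, cohort_size=10)
        assert len(out) == 1
        assert out[0].carriers == frozenset({"s1", "s2", "s3"})
        assert out[0].af == pytest.approx(0.3)

    def test_size_discordant_not_merged(self):
        # reciprocal overlap 0.4: stays two records
        a = dele(1000, 1399, sample="s1")  # length 400
        b = dele(1000, 1999, sample="s2")  # length 1000, overlap 400
        out = merge_across_samples([a, b], cohort_size=2)
        assert len(out) == 2

    def test_private_sv_rare_af(self):
        out = merge_across_samples([dele(1000, 2000)], cohort_size=597)
        assert out[0].af == pytest.approx(1 / 597)
        assert out[0].af < 0.005

    def test_carrier_conservation_on_shuffled_fixture(self, rng):
        calls = []
        for k in range(6):
            base = 10_000 * (k + 1)
            for s in range(4):
                calls.append(dele(base + s, base + 2000 + s, sample=f"s{s}"))
        for _ in range(3):
            shuffled = list(calls)
            rng.shuffle(shuffled)
            out = merge_across_samples(shuffled, cohort_size=4)
            # every input call lands in exactly one consensus record
            assert sum(len(c.members) for c in out) == len(calls)
            assert len(out) == 6

    def test_no_residual_overlap_above_threshold(self, rng):
        starts = rng.integers(1000, 50_000, 30)
        calls = [
            dele(int(s), int(s) + int(l), sample=f"s{i % 5}")
            for i, (s, l) in enumerate(zip(starts, rng.integers(100, 3000, 30)))
        ]
        out = merge_across_samples(calls, cohort_size=5, min_overlap=0.5)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert reciprocal_overlap(out[i], out[j]) <= 0.5


class TestGapFilter:
    def _track(self, *ivs):
        return IntervalTrack([Interval("chr1", s, e) for s, e in ivs])

    def test_mostly_gap_removed(self):
        sv = merge_across_samples([dele(100, 200)], cohort_size=1)
        out = filter_gap_overlap(sv, self._track((100, 190)))
        assert out == []  # 91/101 > 0.8 covered

    def test_no_overlap_retained(self):
        sv = merge_across_samples([dele(100, 200)], cohort_size=1)
        assert len(filter_gap_overlap(sv, self._track((500, 900)))) == 1

    def test_half_covered_retained(self):
        sv = merge_across_samples([dele(101, 200)], cohort_size=1)
        assert len(filter_gap_overlap(sv, self._track((101, 150)))) == 1

    def test_union_of_gaps_not_per_gap(self):
        # two gaps each covering 45%: union 90% > 0.8 -> removed
        sv = merge_across_samples([dele(1, 100)], cohort_size=1)
        out = filter_gap_overlap(sv, self._track((1, 45), (50, 94)))
        assert out == []


class TestAfSpectrum:
    def _consensus(self, afs, sv_type="deletion"):
        return [
            ConsensusSV("chr1", 100 * i, 100 * i + 50, sv_type, frozenset({"s"}), af)
            for i, af in enumerate(afs, 1)
        ]

    def test_af_one_in_last_bin(self):
        table = af_spectrum(self._consensus([1.0, 1.0]))
        assert table["all"].iloc[-1] == 2
        assert table["all"].iloc[:-1].sum() == 0

    def test_hand_tally(self):
        afs = [0.001, 0.004, 0.01, 0.04, 0.1, 0.4, 0.6, 0.9, 1.0, 0.003]
        table = af_spectrum(self._consensus(afs), bin_edges=[0.0, 0.005, 0.05, 0.5, 1.0])
        assert list(table["all"]) == [3, 2, 2, 3]
        assert table["frac_all"].iloc[0] == pytest.approx(0.3)

    def test_type_specific_columns(self):
        cons = self._consensus([0.1, 0.2]) + self._consensus([0.9], sv_type="insertion")
        table = af_spectrum(cons)
        assert table["deletion"].sum() == 2
        assert table["insertion"].sum() == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            af_spectrum([])


class TestRepeatAnnotation:
    def _repeats(self):
        return IntervalTrack(
            [Interval("chr1", 1000, 2000, "tandem"), Interval("chr1", 5000, 6000, "interspersed")]
        )

    def test_inside_repeat_flagged(self):
        cons = [ConsensusSV("chr1", 1200, 1300, "deletion", frozenset({"s"}), 0.1)]
        flags, _ = annotate_repeat_overlap(cons, self._repeats())
        assert flags["in_tandem"].iloc[0]
        assert not flags["in_interspersed"].iloc[0]

    def test_one_bp_touch_flagged(self):
        cons = [ConsensusSV("chr1", 2000, 2500, "deletion", frozenset({"s"}), 0.1)]
        flags, _ = annotate_repeat_overlap(cons, self._repeats())
        assert flags["in_tandem"].iloc[0]

    def test_planted_fraction(self):
        cons = [
            ConsensusSV("chr1", 1000 + i, 1100 + i, "deletion", frozenset({"s"}), 0.1)
            for i in range(7)
        ] + [
            ConsensusSV("chr1", 10_000 + 500 * i, 10_100 + 500 * i, "deletion", frozenset({"s"}), 0.1)
            for i in range(3)
        ]
        flags, summary = annotate_repeat_overlap(cons, self._repeats())
        frac = flags.groupby("sv_type")["in_tandem"].mean()["deletion"]
        assert frac == pytest.approx(0.7)
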