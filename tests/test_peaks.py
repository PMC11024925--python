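import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnrewire import (TSS, annotate_promoter_proximal, build_peak_union,
                       classify_differential, density_matrix,
                       filter_low_summit, normalize_tag_counts)
from grnrewire.peaks import LABEL_A, LABEL_B, LABEL_UNCHANGED

from conftest import make_peak, naive_union, union_intervals


class TestUnion:
    def test_overlapping_summit_windows_merge(self):
        # summit-mode extension 100: [0,200) and [150,350) -> one [0,350)
        peaks = [make_peak("a", "chr1", 90, 110, summit=100),
                 make_peak("b", "chr1", 240, 260, summit=250)]
        (merged,) = build_peak_union([peaks], 100, mode="chip")
        assert (merged.interval.start, merged.interval.end) == (0, 350)
        assert merged.members == ["a", "b"]

    def test_distant_summits_stay_separate(self):
        peaks = [make_peak("a", "chr1", 90, 110, summit=100),
                 make_peak("b", "chr1", 490, 510, summit=500)]
        assert len(build_peak_union([peaks], 100, mode="chip")) == 2

    def test_single_set_equals_extended_input(self):
        peaks = [make_peak("a", "chr1", 1000, 1400, summit=1200)]
        (m,) = build_peak_union([peaks], 200, mode="dnase")
        assert (m.interval.start, m.interval.end) == (800, 1600)
        assert m.summit == 1200 and m.peak_id == "a"

    def test_mixed_chromosomes_never_merge(self):
        peaks = [make_peak("a", "chr1", 100, 200),
                 make_peak("b", "chr2", 100, 200)]
        assert len(build_peak_union([peaks], 200)) == 2

    def test_merged_summit_from_highest_count_member(self):
        peaks = [make_peak("a", "chr1", 100, 200, summit=150,
                           counts={"s": 5}),
                 make_peak("b", "chr1", 150, 250, summit=220,
                           counts={"s": 50})]
        (m,) = build_peak_union([peaks], 100)
        assert m.summit == 220
        assert m.counts == {"s": 55}

    def test_summit_tie_breaks_leftmost(self):
        peaks = [make_peak("a", "chr1", 100, 200, summit=150,
                           counts={"s": 5}),
                 make_peak("b", "chr1", 150, 250, summit=220,
                           counts={"s": 5})]
        (m,) = build_peak_union([peaks], 100)
        assert m.summit == 150

    def test_empty_input_gives_empty_union(self):
        assert build_peak_union([[]], 100) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 3000),
                              st.integers(10, 300)), max_size=25),
           st.sampled_from(["dnase", "chip"]))
    def test_matches_naive_merge_oracle(self, raw, mode):
        peaks = [make_peak(f"p{i}", f"chr{c + 1}", s, s + w)
                 for i, (c, s, w) in enumerate(raw)]
        assert union_intervals(peaks, 100, mode) == \
            naive_union(peaks, 100, mode)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3000), st.integers(10, 300)),
                    max_size=20))
    def test_union_is_idempotent(self, raw):
        # merged output is disjoint and non-bookended, so a merge-only
        # (extension 0) second pass reproduces it exactly
        peaks = [make_peak(f"p{i}", "chr1", s, s + w)
                 for i, (s, w) in enumerate(raw)]
        once = build_peak_union([peaks], 200)
        assert union_intervals(once, 0, "dnase") == sorted(
            (p.interval.chrom, p.interval.start, p.interval.end)
            for p in once)


class TestSummitFilter:
    def test_strictly_less_than_threshold_removed(self):
        peaks = [make_peak(f"p{i}", "chr1", 0, 100, counts={"s": c})
                 for i, c in enumerate([9, 10, 11])]
        kept = filter_low_summit(peaks, 10)
        assert [p.counts["s"] for p in kept] == [10, 11]

    def test_zero_threshold_is_identity(self):
        peaks = [make_peak("p", "chr1", 0, 100, counts={"s": 0})]
        assert filter_low_summit(peaks, 0) == peaks

    def test_all_below_threshold_gives_empty(self):
        peaks = [make_peak("p", "chr1", 0, 100, counts={"s": 3})]
        assert filter_low_summit(peaks, 10) == []


class TestNormalization:
    def test_explicit_library_total(self):
        peaks = [make_peak("p", "chr1", 0, 100, counts={"s": 50})]
        out, totals = normalize_tag_counts(peaks, {"s": 100_000})
        assert out[0].normalized["s"] == 500.0
        assert totals == {"s": 100_000.0}

    def test_per_sample_sums_as_divisor(self):
        peaks = [make_peak("a", "chr1", 0, 100, counts={"s": 10}),
                 make_peak("b", "chr1", 200, 300, counts={"s": 90})]
        out, _ = normalize_tag_counts(peaks)
        assert out[0].normalized["s"] == pytest.approx(1e5)
        assert out[1].normalized["s"] == pytest.approx(9e5)
        assert sum(p.normalized["s"] for p in out) == pytest.approx(1e6)

    def test_zero_total_names_sample(self):
        peaks = [make_peak("p", "chr1", 0, 100, counts={"bad": 0})]
        with pytest.raises(ValueError, match="bad"):
            normalize_tag_counts(peaks)


class TestDifferentialRule:
    def _call(self, a, b, k=3.0, c=0.0):
        p = make_peak("p", "chr1", 0, 100, counts={"sa": a, "sb": b})
        (call,) = classify_differential([p], ["sa"], ["sb"], k, c,
                                        use_normalized=False)
        return call

    def test_nine_fold_is_specific(self):
        call = self._call(90, 10)
        assert call.fold_change == 9.0 and call.label == LABEL_A

    def test_pseudocount_shrinks_fold(self):
        call = self._call(30, 10, c=1.0)
        assert call.fold_change == pytest.approx(31 / 11)
        assert call.label == LABEL_UNCHANGED

    def test_equal_counts_unchanged(self):
        call = self._call(42, 42, k=1.0001)
        assert call.fold_change == 1.0 and call.label == LABEL_UNCHANGED

    def test_exact_threshold_is_specific(self):
        assert self._call(30, 10).label == LABEL_A
        assert self._call(10, 30).label == LABEL_B

    def test_zero_denominator_demands_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            self._call(5, 0, c=0.0)

    def test_replicates_averaged(self):
        p = make_peak("p", "chr1", 0, 100,
                      counts={"a1": 80, "a2": 100, "b1": 10, "b2": 10})
        (call,) = classify_differential([p], ["a1", "a2"], ["b1", "b2"],
                                        3.0, 0.0, use_normalized=False)
        assert call.fold_change == 9.0

    def test_overlapping_condition_sets_rejected(self):
        p = make_peak("p", "chr1", 0, 100, counts={"s": 1})
        with pytest.raises(ValueError, match="overlap"):
            classify_differential([p], ["s"], ["s"], 3.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    def test_antisymmetry_under_condition_swap(self, a, b):
        fwd = self._call(a, b, c=1.0)
        rev = self._call(b, a, c=1.0)
        assert fwd.fold_change * rev.fold_change == pytest.approx(1.0)
        flip = {LABEL_A: LABEL_B, LABEL_B: LABEL_A,
                LABEL_UNCHANGED: LABEL_UNCHANGED}
        assert rev.label == flip[fwd.label]


class TestPromoterProximity:
    CATALOG = [TSS("G1", "chr1", 10_000)]

    def _status(self, summit):
        p = make_peak("p", "chr1", summit - 50, summit + 50, summit=summit)
        return annotate_promoter_proximal([p], self.CATALOG)["p"]

    def test_within_limit_is_proximal(self):
        assert self._status(10_000 + 1400) == "proximal"

    def test_just_beyond_limit_is_distal(self):
        assert self._status(10_000 + 1501) == "distal"

    def test_tss_at_summit_is_proximal(self):
        assert self._status(10_000) == "proximal"

    def test_other_chromosome_is_distal(self):
        p = make_peak("p", "chr2", 9_000, 11_000)
        assert annotate_promoter_proximal([p], self.CATALOG)["p"] == "distal"


class TestDensityMatrix:
    def test_uniform_coverage_fills_each_bin(self):
        p = make_peak("p", "chr1", 4000, 4400, summit=4200)
        cov = {"chr1": np.ones(10_000)}
        dm = density_matrix([p], {"p": 2.0}, cov, window=2000, bin_size=10)
        assert dm.values.shape == (1, 200)
        assert np.all(dm.values == 10.0)

    def test_zero_coverage_gives_zero_matrix(self):
        p = make_peak("p", "chr1", 4000, 4400)
        dm = density_matrix([p], {}, {"chr1": np.zeros(10_000)})
        assert not dm.values.any()

    def test_truncated_window_matches_per_position_sum(self):
        rng = np.random.default_rng(0)
        cov = {"chr1": rng.random(3000)}
        p = make_peak("p", "chr1", 0, 40, summit=5)   # window runs off 5' end
        dm = density_matrix([p], {"p": 1.0}, cov, window=2000, bin_size=10)
        expected = np.zeros(2000)
        expected[995:] = cov["chr1"][:1005]           # summit-1000 .. summit+1000
        assert np.allclose(dm.values[0],
                           expected.reshape(200, 10).sum(axis=1))
        assert dm.values[0].sum() == pytest.approx(cov["chr1"][:1005].sum())

    def test_rows_ranked_by_descending_fold(self):
        peaks = [make_peak(f"p{i}", "chr1", 1000 * i + 2000,
                           1000 * i + 2400) for i in range(3)]
        dm = density_matrix(peaks, {"p0": 1.0, "p1": 9.0, "p2": 3.0},
                            {"chr1": np.zeros(10_000)})
        assert dm.peak_ids == ["p1", "p2", "p0"]

    def test_window_must_divide_into_bins(self):
        with pytest.raises(ValueError):
            density_matrix([], {}, {}, window=2000, bin_size=30)
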