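import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ernatlas.intervals import (
    Annotation,
    GenomicInterval,
    NoReferenceTSSError,
    TSS,
    TagSet,
    distance_to_nearest_tss,
    distance_to_point,
    edge_distance,
    merge_intervals,
    total_coverage,
    window_around,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, "x")

    def test_touching_intervals_share_no_base(self):
        assert not iv(0, 10).overlaps(iv(10, 20))
        assert iv(0, 10).overlaps(iv(9, 20))


class TestMergeIntervals:
    def test_overlapping_pair_merges(self):
        assert merge_intervals([iv(0, 10), iv(5, 20)]) == [iv(0, 20)]

    def test_disjoint_pass_through_sorted(self):
        assert merge_intervals([iv(20, 30), iv(0, 10)]) == [iv(0, 10), iv(20, 30)]

    def test_empty_input(self):
        assert merge_intervals([]) == []

    def test_random_against_per_base_oracle(self, rng):
        """Union base count of 50 random intervals equals merged lengths."""
        for _ in range(10):
            ivs = []
            for _ in range(50):
                s = int(rng.integers(0, 500))
                ivs.append(iv(s, s + int(rng.integers(1, 40))))
            covered = set()
            for v in ivs:
                covered.update(range(v.start, v.end))
            merged = merge_intervals(ivs)
            assert sum(m.length for m in merged) == len(covered)
            assert total_coverage(ivs) == len(covered)
            # disjoint and sorted
            for a, b in zip(merged[:-1], merged[1:]):
                assert a.end <= b.start

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 50))))
    def test_merge_idempotent(self, raw):
        ivs = [iv(s, s + w) for s, w in raw]
        once = merge_intervals(ivs)
        assert merge_intervals(once) == once


class TestDistanceToNearestTSS:
    def make_ann(self, positions, chrom="chr1"):
        return Annotation(tss_list=[TSS(f"g{i}", chrom, p) for i, p in enumerate(positions)])

    def test_simple_gap(self):
        assert distance_to_nearest_tss(iv(1500, 1700), self.make_ann([1000])) == 500

    def test_tss_inside_peak_is_zero(self):
        assert distance_to_nearest_tss(iv(1500, 1700), self.make_ann([1600])) == 0

    def test_minimum_over_multiple_tss(self):
        # TSSs {1000, 5000}, peak [2800, 3000): left gap 1800, right gap 2001
        assert distance_to_nearest_tss(iv(2800, 3000), self.make_ann([1000, 5000])) == 1800

    def test_no_tss_on_chromosome_signals(self):
        with pytest.raises(NoReferenceTSSError):
            distance_to_nearest_tss(iv(0, 10), self.make_ann([100], chrom="chr2"))

    def test_agrees_with_exhaustive_scan(self, rng):
        positions = sorted(rng.integers(0, 1_000_000, size=1000).tolist())
        ann = self.make_ann(positions)
        for _ in range(100):
            s = int(rng.integers(0, 999_000))
            region = iv(s, s + int(rng.integers(1, 1000)))
            brute = min(distance_to_point(region, p) for p in positions)
            assert distance_to_nearest_tss(region, ann) == brute


class TestWindowAround:
    def test_centered(self):
        assert window_around(5000, 1000, 10 ** 6) == GenomicInterval(".", 4000, 6000)

    def test_left_clip(self):
        assert window_around(300, 1000, 10 ** 6) == GenomicInterval(".", 0, 1300)

    def test_right_clip(self):
        assert window_around(5000, 1000, 5500) == GenomicInterval(".", 4000, 5500)

    def test_length_bounded(self, rng):
        for _ in range(50):
            c = int(rng.integers(0, 10_000))
            w = window_around(c, 500, 10_000)
            assert w.length <= 1000

    def test_center_outside_chromosome(self):
        with pytest.raises(ValueError):
            window_around(10 ** 6, 100, 10 ** 6)


class TestTagSet:
    def test_counts_are_half_open(self):
        ts = TagSet({"chr1": [5, 10, 15]})
        assert ts.count_in("chr1", 5, 15) == 2  # 15 excluded
        assert ts.count_in("chr2", 0, 100) == 0

    def test_stranded_counts(self):
        ts = TagSet({"chr1": [1, 2, 3]}, strands={"chr1": np.array(["+", "+", "-"])})
        assert ts.count_in("chr1", 0, 10, strand="+") == 2
        assert ts.count_in("chr1", 0, 10, strand="-") == 1

    def test_total_tags_lower_bound(self):
        with pytest.raises(ValueError):
            TagSet({"chr1": [1, 2, 3]}, total_tags=2)


def test_edge_distance_conventions():
    assert edge_distance(iv(0, 10), iv(10, 20)) == 0  # adjacent
    assert edge_distance(iv(0, 10), iv(15, 20)) == 5
    assert edge_distance(iv(15, 20), iv(0, 10)) == 5
    assert edge_distance(iv(0, 10), iv(5, 20)) == 0  # overlap
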