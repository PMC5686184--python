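import itertools

import numpy as np
import pytest

from ernatlas.classify import (
    DegenerateClusteringError,
    REFERENCE_TOTAL_TAGS,
    assign_orientation,
    count_center_tags,
    depth_corrected_threshold,
    kmeans_classify,
)
from ernatlas.intervals import GenomicInterval, TagSet


def brute_force_two_means(counts):
    """Best 2-partition of log2(n+1) by within-cluster SS, all partitions."""
    x = np.log2(np.asarray(counts) + 1.0)
    n = len(x)
    best, best_mask = np.inf, None
    for bits in itertools.product([0, 1], repeat=n):
        mask = np.array(bits, dtype=bool)
        if mask.all() or not mask.any():
            continue
        sse = ((x[mask] - x[mask].mean()) ** 2).sum() + \
              ((x[~mask] - x[~mask].mean()) ** 2).sum()
        if sse < best - 1e-12:
            best, best_mask = sse, mask
    return best_mask


class TestCountCenterTags:
    def test_empty_chromosome(self):
        ts = TagSet({"chr2": [1, 2]})
        assert count_center_tags(GenomicInterval("chr1", 0, 2000), ts) == 0

    def test_window_edges(self):
        # candidate [4000, 6000): center 5000, window [4000, 6000)
        iv = GenomicInterval("chr1", 4000, 6000)
        ts = TagSet({"chr1": [4001, 5000, 5999, 6000]})
        # 6000 excluded by the half-open convention
        assert count_center_tags(iv, ts) == 3

    def test_boundary_differs_from_inclusive_oracle(self):
        iv = GenomicInterval("chr1", 4000, 6000)
        ts = TagSet({"chr1": [6000]})
        inclusive = 1  # an inclusive-right convention would count it
        assert count_center_tags(iv, ts) == inclusive - 1


class TestKMeansClassify:
    def test_matches_brute_force_partition(self):
        counts = [2, 3, 4, 100, 120, 130]
        model = kmeans_classify(counts)
        mask = brute_force_two_means(counts)
        # identify brute-force high cluster by mean
        x = np.log2(np.asarray(counts) + 1.0)
        high = mask if x[mask].mean() > x[~mask].mean() else ~mask
        assert list(model.labels == "eRNA") == list(high)
        assert model.threshold_tags == 4

    def test_two_point_threshold(self):
        model = kmeans_classify([0, 1000])
        assert model.threshold_tags == 0

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 300, size=10)
            if np.unique(counts).size < 2:
                continue
            model = kmeans_classify(counts)
            mask = brute_force_two_means(counts)
            x = np.log2(counts + 1.0)
            high = mask if x[mask].mean() > x[~mask].mean() else ~mask
            assert list(model.labels == "eRNA") == list(high)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.cluster import KMeans
        counts = np.concatenate([
            rng.integers(0, 30, size=150), rng.integers(60, 400, size=80)])
        model = kmeans_classify(counts)
        x = np.log2(counts + 1.0).reshape(-1, 1)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x)
        high_label = int(np.argmax(km.cluster_centers_.ravel()))
        assert np.array_equal(model.labels == "eRNA", km.labels_ == high_label)

    def test_threshold_below_min_erna_count(self, rng):
        counts = rng.integers(0, 500, size=200)
        model = kmeans_classify(counts)
        erna_counts = np.asarray(counts)[model.labels == "eRNA"]
        assert model.threshold_tags < erna_counts.min()

    def test_degenerate_identical_counts(self):
        with pytest.raises(DegenerateClusteringError):
            kmeans_classify([7, 7, 7, 7])


def test_classification_table_round_trips_labels(rng):
    from ernatlas.classify import classification_table
    counts = np.concatenate([rng.integers(0, 10, 50), rng.integers(80, 300, 30)])
    model = kmeans_classify(counts)
    df = classification_table([f"c{i}" for i in range(80)], counts, model,
                              threshold=model.threshold_tags)
    assert (df.label == model.labels).all()
    assert (df.n_i > df.threshold).equals(df.label == "eRNA")


class TestDepthCorrectedThreshold:
    def test_reference_identity(self):
        assert depth_corrected_threshold(REFERENCE_TOTAL_TAGS) == 30.0

    def test_zero_library(self):
        assert depth_corrected_threshold(0) == 0.0

    def test_doubling_scales_linearly(self):
        assert depth_corrected_threshold(2 * REFERENCE_TOTAL_TAGS) == 60.0

    def test_negative_signalled(self):
        with pytest.raises(ValueError):
            depth_corrected_threshold(-1)


class TestAssignOrientation:
    def make(self, plus, minus):
        pos = list(range(1000, 1000 + plus)) + list(range(1500, 1500 + minus))
        strands = ["+"] * plus + ["-"] * minus
        return TagSet({"chr1": pos}, strands={"chr1": np.array(strands)})

    def test_majority_plus(self):
        region = GenomicInterval("chr1", 500, 2500)
        assert assign_orientation(region, self.make(10, 3)) == "+"

    def test_tie_is_unstranded(self):
        region = GenomicInterval("chr1", 500, 2500)
        assert assign_orientation(region, self.make(5, 5)) == "."

    def test_no_tags_is_unstranded(self):
        region = GenomicInterval("chr1", 500, 2500)
        assert assign_orientation(region, TagSet({})) == "."
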