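import numpy as np
import pytest

from ernatlas import simulate
from ernatlas.catalog import (
    MasterList,
    build_master_list,
    cell_specificity,
    consensus_calls,
    dedup_hits,
    fit_weibull,
    saturation_curve,
    weibull_curve,
)
from ernatlas.intervals import GenomicInterval


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestBuildMasterList:
    def test_overlap_merges_with_shared_membership(self):
        ml = build_master_list({"a": [iv(0, 3000)], "b": [iv(2000, 5000)]})
        assert ml.elements == [iv(0, 5000)]
        assert ml.membership == [{"a", "b"}]

    def test_long_span_split_into_equal_chunks(self):
        ml = build_master_list({"a": [iv(0, 6000)]})
        assert ml.elements == [iv(0, 3000), iv(3000, 6000)]

    def test_disjoint_inputs_unchanged(self):
        ml = build_master_list({"a": [iv(0, 100)], "b": [iv(500, 900)]})
        assert ml.elements == [iv(0, 100), iv(500, 900)]
        assert ml.membership == [{"a"}, {"b"}]

    def test_elements_capped_and_disjoint(self, rng):
        cats = {
            f"c{k}": [iv(int(s), int(s) + int(rng.integers(1000, 9000)))
                      for s in rng.integers(0, 100_000, size=20)]
            for k in range(4)
        }
        ml = build_master_list(cats)
        assert all(e.length <= 5000 for e in ml.elements)
        for a, b in zip(ml.elements[:-1], ml.elements[1:]):
            assert a.end <= b.start
        assert all(len(m) >= 1 for m in ml.membership)

    def test_coverage_invariant_to_input_order(self, rng):
        cats = {
            f"c{k}": [iv(int(s), int(s) + 2000) for s in rng.integers(0, 50_000, size=10)]
            for k in range(3)
        }
        fwd = build_master_list(cats)
        rev = build_master_list(dict(reversed(list(cats.items()))))
        assert fwd.coverage_bp() == rev.coverage_bp()


class TestCellSpecificity:
    def test_counts_match_brute_force_recount(self, rng):
        cats = {
            f"c{k}": [iv(int(s) * 100, int(s) * 100 + 80)
                      for s in rng.integers(0, 500, size=40)]
            for k in range(5)
        }
        ml = build_master_list(cats)
        df = cell_specificity(ml)
        for el, n in zip(ml.elements, df["n_cell_types"]):
            brute = sum(
                1 for c, ivs in cats.items() if any(el.overlaps(v) for v in ivs)
            )
            assert n == brute


class TestSaturationCurve:
    def make_catalogs(self, seed=0, n_cells=8):
        cfg = simulate.SimConfig(seed=seed, n_cell_types=n_cells, weibull_A=200.0)
        cats, _ = simulate.generate_catalog_series(cfg)
        return cats

    def test_full_subset_equals_master_list_exactly(self, rng):
        cats = self.make_catalogs()
        ml = build_master_list(cats)
        curve = saturation_curve(cats, n_samples=50, rng=rng)
        last = curve.iloc[-1]
        assert last["mean_count"] == ml.element_count()
        assert last["mean_coverage_bp"] == ml.coverage_bp()

    def test_single_cell_mean_matches_closed_form(self):
        cats = self.make_catalogs()
        curve = saturation_curve(cats, n_samples=4000, rng=np.random.default_rng(1))
        exact = np.mean([len(v) for v in cats.values()])
        assert abs(curve.iloc[0]["mean_count"] - exact) / exact < 0.05

    def test_monotone_in_expectation_and_deterministic(self):
        cats = self.make_catalogs()
        c1 = saturation_curve(cats, n_samples=500, rng=np.random.default_rng(3))
        c2 = saturation_curve(cats, n_samples=500, rng=np.random.default_rng(3))
        assert c1.equals(c2)
        assert (np.diff(c1["mean_count"]) >= 0).all()

    def test_bad_sample_count(self):
        with pytest.raises(ValueError):
            saturation_curve(self.make_catalogs(), n_samples=0)


class TestFitWeibull:
    def test_recovers_noiseless_parameters(self):
        x = np.arange(1, 51, dtype=float)
        y = weibull_curve(x, 1000.0, 20.0, 1.2)
        fit = fit_weibull(x, y)
        assert abs(fit.A - 1000.0) / 1000.0 < 0.01
        assert fit.r2 > 0.999
        assert fit.A_sd >= 0.0 and np.isfinite(fit.A_sd)

    def test_constant_curve_flagged_degenerate(self):
        fit = fit_weibull(np.arange(1, 10.0), np.full(9, 42.0))
        assert fit.degenerate
        assert fit.A == pytest.approx(42.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_weibull([1, 2, 3], [1, 2, 3])


class TestConsensusAndDedup:
    def test_two_set_support_kept(self):
        sets = [[iv(100, 200)], [], [iv(100, 200)]]
        assert consensus_calls(sets) == [iv(100, 200)]

    def test_single_set_support_dropped(self):
        sets = [[iv(100, 200)], [iv(5000, 6000)]]
        assert consensus_calls(sets) == []

    def test_partial_overlap_keeps_shared_bases(self):
        sets = [[iv(0, 150)], [iv(100, 300)]]
        assert consensus_calls(sets) == [iv(100, 150)]

    def test_dedup_small_shift_collapses(self):
        hits = [("RF0001", iv(100, 200)), ("RF0001", iv(104, 204))]
        out = dedup_hits(hits, shift_tol=10)
        assert len(out) == 1 and out[0][2] == 2

    def test_dedup_large_shift_kept_separate(self):
        hits = [("RF0001", iv(100, 200)), ("RF0001", iv(150, 250))]
        assert len(dedup_hits(hits, shift_tol=10)) == 2

    def test_dedup_respects_model_label(self):
        hits = [("RF0001", iv(100, 200)), ("RF0002", iv(100, 200))]
        assert len(dedup_hits(hits, shift_tol=10)) == 2
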