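import numpy as np
import pytest
from scipy import stats

from ernatlas import io, simulate
from ernatlas.intervals import GenomicInterval
from ernatlas.simulate import DECOY_CLASSES, SimConfig


class TestConfigValidation:
    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            SimConfig(high_fraction=0.0)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_true_enhancers=0)

    def test_capacity_error_when_genome_too_small(self):
        cfg = SimConfig(n_chroms=1, chrom_len=100_000, n_true_enhancers=500)
        with pytest.raises(simulate.CapacityError):
            simulate.generate_genome_bundle(cfg)


class TestGenomeBundle:
    def test_deterministic_given_seed(self):
        a = simulate.generate_genome_bundle(SimConfig(seed=7))
        b = simulate.generate_genome_bundle(SimConfig(seed=7))
        assert a[1]["H3K27ac"] == b[1]["H3K27ac"]
        for chrom in a[2]["H3K4me1"].positions:
            assert np.array_equal(a[2]["H3K4me1"].positions[chrom],
                                  b[2]["H3K4me1"].positions[chrom])

    def test_every_entity_has_a_truth_label(self, genome_bundle, sim_cfg):
        _, peaks, _, truth = genome_bundle
        n_classes = len(DECOY_CLASSES)
        assert len(truth.planted_enhancers) == sim_cfg.n_true_enhancers
        assert len(truth.decoys) == n_classes * sim_cfg.n_decoys_per_class
        # each decoy labelled exactly once with a known class
        assert all(d["class"] in DECOY_CLASSES for d in truth.decoys)

    def test_planted_enhancers_clear_of_tss_and_genes(self, genome_bundle):
        ann, _, _, truth = genome_bundle
        from ernatlas.intervals import distance_to_nearest_tss
        for iv in truth.planted_enhancers:
            assert distance_to_nearest_tss(iv, ann) >= 1_000
            assert not any(iv.overlaps(g) for g in ann.gene_bodies)
            assert not any(iv.overlaps(r) for r in ann.rrna_genes)

    def test_round_trip_through_writers(self, genome_bundle, sim_cfg, tmp_path):
        ann, peaks, _, truth = genome_bundle
        simulate.export_bundle(tmp_path, ann, peaks, truth, sim_cfg.seed)
        back = io.read_bed(tmp_path / "H3K27ac_rep0.bed")
        want = [GenomicInterval(p.chrom, p.start, p.end) for p in peaks["H3K27ac"][0]]
        assert back == want


class TestTagCounts:
    def test_high_component_median_calibrated(self):
        cfg = SimConfig(seed=1)
        ivs = [GenomicInterval("chr1", i * 3000, i * 3000 + 1000) for i in range(10_000)]
        _, counts, high = simulate.generate_tag_counts(ivs, cfg)
        assert 100 <= np.median(counts[high]) <= 150
        assert 2 <= np.median(counts[~high]) <= 7

    def test_high_fraction_zero_gives_all_low(self):
        cfg = SimConfig(seed=1, high_fraction=1e-12)
        ivs = [GenomicInterval("chr1", i * 3000, i * 3000 + 1000) for i in range(200)]
        _, counts, high = simulate.generate_tag_counts(ivs, cfg)
        assert not high.any()
        assert np.median(counts) < 20

    def test_deterministic(self):
        cfg = SimConfig(seed=9)
        ivs = [GenomicInterval("chr1", i * 3000, i * 3000 + 1000) for i in range(50)]
        _, c1, _ = simulate.generate_tag_counts(ivs, cfg)
        _, c2, _ = simulate.generate_tag_counts(ivs, cfg)
        assert np.array_equal(c1, c2)

    def test_counts_recoverable_from_tag_positions(self):
        from ernatlas.classify import count_center_tags
        cfg = SimConfig(seed=3)
        ivs = [GenomicInterval("chr1", i * 5000, i * 5000 + 1000) for i in range(100)]
        tags, counts, _ = simulate.generate_tag_counts(ivs, cfg)
        for iv, c in zip(ivs, counts):
            assert count_center_tags(iv, tags) == c


class TestCatalogSeries:
    def test_mean_curve_matches_weibull_truth(self):
        """Sampled discovery at x=30 within 5% of A(1-exp(-(30/b)^c)), 200 reps."""
        cfg = SimConfig(seed=0, n_cell_types=30, weibull_A=500.0)
        found = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            cats, truth = simulate.generate_catalog_series(cfg, rng=rng)
            distinct = set()
            for ivs in cats.values():
                distinct.update((v.chrom, v.start) for v in ivs)
            found.append(len(distinct))
        A, b, c = 500.0, cfg.weibull_b, cfg.weibull_c
        expect = A * (1.0 - np.exp(-((30.0 / b) ** c)))
        assert abs(np.mean(found) - expect) / expect < 0.05

    def test_single_cell_type_is_single_point(self):
        cfg = SimConfig(seed=2, n_cell_types=1)
        cats, _ = simulate.generate_catalog_series(cfg)
        (ivs,) = cats.values()
        assert len(ivs) >= 0  # a single catalogue; curve would be one point

    def test_deterministic(self):
        cfg = SimConfig(seed=5)
        a, _ = simulate.generate_catalog_series(cfg)
        b, _ = simulate.generate_catalog_series(cfg)
        assert a == b

    def test_capacity_error(self):
        cfg = SimConfig(seed=0, n_chroms=1, chrom_len=50_000, weibull_A=10_000)
        with pytest.raises(simulate.CapacityError):
            simulate.generate_catalog_series(cfg)


class TestSnpPanel:
    def locate(self, cfg):
        cats, truth = simulate.generate_catalog_series(cfg)
        elements = truth.catalog_elements
        return elements[::20], elements

    def test_no_enrichment_at_fold_one(self):
        cfg = SimConfig(seed=4, planted_enrichment_fold=1.0, n_disease_snps=4000)
        loci, domain = self.locate(cfg)
        disease, background, _, _ = simulate.generate_snp_panel(cfg, loci, domain)
        rho = sum(v.length for v in loci) / sum(v.length for v in domain)

        def in_locus_frac(snps):
            starts = {(v.chrom): [] for v in loci}
            n_in = 0
            for _, chrom, pos in snps:
                n_in += any(v.chrom == chrom and v.start <= pos < v.end for v in loci)
            return n_in / len(snps)

        assert abs(in_locus_frac(disease) - rho) < 0.02

    def test_planted_fold_within_binomial_ci(self):
        cfg = SimConfig(seed=4, planted_enrichment_fold=8.0, n_disease_snps=500)
        loci, domain = self.locate(cfg)
        disease, _, _, truth = simulate.generate_snp_panel(cfg, loci, domain)
        rho = sum(v.length for v in loci) / sum(v.length for v in domain)
        k = int(truth.true_enriched_snps.sum())
        lo, hi = stats.binom.interval(0.99, 500, 8.0 * rho)
        assert lo <= k <= hi

    def test_deterministic_and_r2_in_range(self):
        cfg = SimConfig(seed=6)
        loci, domain = self.locate(cfg)
        a = simulate.generate_snp_panel(cfg, loci, domain)
        b = simulate.generate_snp_panel(cfg, loci, domain)
        assert a[0] == b[0] and a[2] == b[2]
        assert all(0.0 <= p[4] <= 1.0 for p in a[2])

    def test_empty_loci_signalled(self):
        cfg = SimConfig(seed=6)
        with pytest.raises(simulate.EmptyDomainError):
            simulate.generate_snp_panel(cfg, [], [GenomicInterval("chr1", 0, 100)])


class TestStructureCases:
    def test_alt_never_equals_ref_and_flags_cover_all(self):
        seqs, snvs, truth = simulate.generate_structure_cases(SimConfig(seed=8))
        assert len(snvs) == len(truth.true_disruptive_snvs)
        for sid, pos, ref, alt in snvs:
            assert seqs[sid][pos] == ref
            assert alt != ref

    def test_disruptive_snv_breaks_a_stem_pair(self):
        cfg = SimConfig(seed=8, stem_len=6, loop_len=4, n_structure_cases=4)
        seqs, snvs, truth = simulate.generate_structure_cases(cfg)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for (sid, pos, ref, alt), disruptive in zip(snvs, truth.true_disruptive_snvs):
            seq = seqs[sid]
            if disruptive:
                partner = seq[len(seq) - 1 - pos]
                assert comp[ref] == partner           # WC pair in the hairpin
                assert comp.get(alt) != partner       # broken by the alt
                assert not (alt, partner) in {("G", "U"), ("U", "G")}
            else:
                assert ref == "A" and cfg.stem_len <= pos < cfg.stem_len + cfg.loop_len

    def test_hairpin_constraint_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(stem_len=2)
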