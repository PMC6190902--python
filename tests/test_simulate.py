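import numpy as np
import pandas as pd
import pytest

from mantelqtl.distance import genotype_distance, phenotype_distance
from mantelqtl.mantel import mantel_statistic, single_marker_scan
from mantelqtl.simulate import (ArchitectureSpec, condition_architectures,
                                default_conditions, simulate_dataset,
                                simulate_founder_panel, simulate_hs_genomes,
                                simulate_phenotypes)

from conftest import planted


class TestFounderPanel:
    def test_deterministic_given_seed(self):
        a = simulate_founder_panel(8, 500, seed=1)
        b = simulate_founder_panel(8, 500, seed=1)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        pd.testing.assert_frame_equal(a.marker_map, b.marker_map)
        assert np.array_equal(a.target_maf, b.target_maf)

    def test_single_founder_is_monomorphic(self):
        panel = simulate_founder_panel(1, 50, seed=2)
        assert (panel.haplotypes == panel.haplotypes[0]).all()
        assert (panel.target_maf == 0).all()

    def test_equal_mixing_frequency_equals_target(self):
        panel = simulate_founder_panel(8, 300, seed=3)
        np.testing.assert_allclose(panel.haplotypes.mean(axis=0),
                                   panel.target_maf)
        assert (panel.target_maf >= 0.05).all()
        assert (panel.target_maf <= 0.5).all()

    def test_positions_strictly_increasing_per_chromosome(self):
        panel = simulate_founder_panel(8, 400, seed=4)
        for _, grp in panel.marker_map.groupby("chrom"):
            assert (np.diff(grp["bp"]) > 0).all()

    def test_empirical_maf_tracks_target(self):
        # binomial sampling of 1000 haplotypes: sd <= 0.0158, so nearly all
        # markers land within +/-0.05 of target and none far outside
        panel = simulate_founder_panel(8, 1000, seed=5)
        g = simulate_hs_genomes(panel, 500, 20, seed=6)
        dev = np.abs(g.allele_frequency() - panel.target_maf)
        assert (dev <= 0.05).mean() >= 0.99
        assert dev.max() <= 0.08

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_founder_panel(0, 10)
        with pytest.raises(ValueError):
            simulate_founder_panel(8, 10, maf_low=0.0)
        with pytest.raises(ValueError):
            simulate_founder_panel(8, 10, maf_low=0.3, maf_high=0.2)
        with pytest.raises(ValueError, match="sum"):
            simulate_founder_panel(8, 10, chrom_layout={"chr1": 5})


class TestHsGenomes:
    def test_deterministic_given_seed(self):
        panel = simulate_founder_panel(8, 200, seed=1)
        a = simulate_hs_genomes(panel, 50, 20, seed=2)
        b = simulate_hs_genomes(panel, 50, 20, seed=2)
        assert np.array_equal(a.dosages, b.dosages)

    def test_single_founder_gives_zero_distances(self):
        panel = simulate_founder_panel(1, 60, seed=3)
        g = simulate_hs_genomes(panel, 20, 10, seed=4)
        assert (genotype_distance(g).values == 0).all()

    def test_dosage_conservation(self):
        panel = simulate_founder_panel(8, 100, seed=5)
        g = simulate_hs_genomes(panel, 40, 15, seed=6)
        counts = g.dosages.sum(axis=0)
        np.testing.assert_allclose(g.allele_frequency(),
                                   counts / (2 * g.n_samples))

    def test_block_length_controls_linkage(self):
        # long blocks -> adjacent markers share founder origin -> higher
        # squared dosage correlation than the single-marker-block setting
        panel = simulate_founder_panel(8, 300, seed=7,
                                       chrom_layout={"chr1": 300})
        def mean_r2(block):
            g = simulate_hs_genomes(panel, 300, block, seed=8)
            d = g.dosages.astype(float)
            keep = d.std(axis=0) > 0
            d = d[:, keep]
            r = np.array([np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
                          for j in range(d.shape[1] - 1)])
            return np.nanmean(r ** 2)
        assert mean_r2(1_000_000) > mean_r2(1) + 0.05

    def test_argument_validation(self):
        panel = simulate_founder_panel(2, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_hs_genomes(panel, 0)
        with pytest.raises(ValueError):
            simulate_hs_genomes(panel, 5, mean_block_markers=0.5)


class TestPhenotypes:
    def test_zero_heritability_gives_null_mantel(self):
        g, pheno, _, _ = planted(seed=8, n_samples=200, n_markers=200,
                                 heritability=0.0)
        d_g = genotype_distance(g)
        d_p = phenotype_distance(pheno, "context_avgmot")
        assert abs(mantel_statistic(d_g, d_p)) < 0.05

    def test_noise_free_single_locus_is_affine_in_dosage(self):
        panel = simulate_founder_panel(8, 30, seed=9)
        g = simulate_hs_genomes(panel, 60, 10, seed=10)
        cond = pd.DataFrame({"cohort": ["c"] * 60, "condition": ["sham"] * 60},
                            index=pd.Index(g.samples, name="sample"))
        causal = g.markers[3]
        spec = ArchitectureSpec(effects={"sham": [(causal, 2.0)]},
                                heritability=1.0,
                                categories={"y": "context_avgmot"}, seed=0)
        pheno, _ = simulate_phenotypes(g, spec, cond)
        dosage = g.dosages[:, 3].astype(float)
        slope, intercept = np.polyfit(dosage, pheno.values["y"], 1)
        resid = pheno.values["y"] - (slope * dosage + intercept)
        assert np.abs(resid).max() < 1e-10

    def test_category_correlation_structure_matches_study_ranges(self):
        g, pheno, cond, _ = simulate_dataset(
            n_samples=400, n_markers=300, seed=11,
            cohort_shift={"cohort1": (0.0, 1.0), "cohort2": (0.0, 1.0)})
        corr = pheno.values.corr().to_numpy()
        cats = np.array([pheno.categories[m] for m in pheno.values.columns])
        same = cats[:, None] == cats[None, :]
        off_diag = ~np.eye(len(cats), dtype=bool)
        within = corr[same & off_diag]
        between = corr[~same]
        assert 0.5 <= within.mean() <= 0.9
        assert abs(between).mean() < 0.6

    def test_unknown_condition_label_rejected(self):
        g, pheno, cond, _ = planted(seed=12, n_samples=30, n_markers=20)
        bad = cond.copy()
        bad.iloc[0, bad.columns.get_loc("condition")] = "mystery"
        spec = ArchitectureSpec(effects={"sham": [(g.markers[0], 1.0)]},
                                heritability=0.5, seed=0)
        with pytest.raises(ValueError, match="mystery"):
            simulate_phenotypes(g, spec, bad)

    def test_effect_marker_must_exist(self):
        g, _, cond, _ = planted(seed=13, n_samples=20, n_markers=10)
        spec = ArchitectureSpec(effects={"sham": [("ghost", 1.0)]},
                                heritability=0.5, seed=0)
        with pytest.raises(ValueError, match="ghost"):
            simulate_phenotypes(g, spec, cond)

    def test_heritability_range_validated(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(effects={}, heritability=1.2)
        with pytest.raises(ValueError):
            ArchitectureSpec(effects={}, cohort_shift={"c": (0.0, 0.0)})


class TestArchitectures:
    def test_overlap_knob_extremes(self):
        markers = [f"m{i}" for i in range(100)]
        same = condition_architectures(markers, ["a", "b"], n_causal=10,
                                       overlap=1.0, seed=1)
        loci_a = {m for m, _ in same["a"]}
        loci_b = {m for m, _ in same["b"]}
        assert loci_a == loci_b
        assert same["a"] == same["b"]  # shared loci share effects
        disjoint = condition_architectures(markers, ["a", "b"], n_causal=10,
                                           overlap=0.0, seed=2)
        assert not ({m for m, _ in disjoint["a"]}
                    & {m for m, _ in disjoint["b"]})

    def test_overlap_range_validated(self):
        with pytest.raises(ValueError):
            condition_architectures(["m0"], ["a"], n_causal=1, overlap=1.5)

    def test_insufficient_markers_rejected(self):
        with pytest.raises(ValueError, match="distinct causal"):
            condition_architectures(["m0", "m1"], ["a", "b"], n_causal=3,
                                    overlap=0.0)


class TestRecoverability:
    def test_top_scan_rank_recovers_planted_locus(self):
        # strong, sparse architecture at n >= 200 samples: the top-ranked
        # marker should be causal or inside one mosaic block of a causal
        hits = 0
        for rep in range(20):
            g, pheno, _, truth = planted(seed=400 + rep, n_samples=250,
                                         n_markers=600, n_causal=3,
                                         heritability=0.5)
            d = phenotype_distance(pheno, "context_avgmot")
            top = single_marker_scan(g, d, B=0).table["marker"].iloc[0]
            midx = {m: i for i, m in enumerate(g.markers)}
            chrom = g.marker_map["chrom"].to_dict()
            hits += any(abs(midx[top] - midx[cm]) <= 20
                        and chrom[top] == chrom[cm]
                        for cm in truth.causal["sham"])
        assert hits >= 16


class TestDataset:
    def test_deterministic_and_schema_stable(self):
        a = simulate_dataset(n_samples=60, n_markers=80, seed=3)
        b = simulate_dataset(n_samples=60, n_markers=80, seed=3)
        c = simulate_dataset(n_samples=60, n_markers=80, seed=4)
        assert np.array_equal(a[0].dosages, b[0].dosages)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        assert not np.array_equal(a[0].dosages, c[0].dosages)
        assert list(a[1].values.columns) == list(c[1].values.columns)

    def test_default_conditions_proportions(self):
        cond = default_conditions(4000, seed=0)
        frac = (cond["cohort"] == "cohort2").mean()
        assert 0.6 < frac < 0.73
        assert set(cond["condition"]) == {"sham", "fe", "si", "gamma"}
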