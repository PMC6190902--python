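import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from mantelqtl.distance import DistanceMatrix, genotype_distance, phenotype_distance
from mantelqtl.mantel import (DegenerateDistanceError, EmptyScanError,
                              mantel_statistic, mantel_test,
                              single_marker_scan)
from mantelqtl.selection import eligible_markers

from conftest import make_genotypes, planted


def random_distance(rng, n, ids=None):
    x = rng.standard_normal((n, 3))
    return DistanceMatrix(ids if ids is not None else [f"s{i}" for i in range(n)],
                          squareform(pdist(x, "cityblock")))


class TestMantelStatistic:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        d1 = random_distance(rng, 8)
        assert mantel_statistic(d1, d1) == pytest.approx(1.0)
        v = 2.0 * d1.values + 3.0
        np.fill_diagonal(v, 0.0)
        d2 = DistanceMatrix(d1.ids, v)
        assert mantel_statistic(d1, d2) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_brute_force_pearson_over_pairs(self, n):
        rng = np.random.default_rng(n)
        d1, d2 = random_distance(rng, n), random_distance(rng, n)
        iu = np.triu_indices(n, 1)
        expected = np.corrcoef(d1.values[iu], d2.values[iu])[0, 1]
        assert mantel_statistic(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_library_oracle(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        d1, d2 = random_distance(rng, 10), random_distance(rng, 10)
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values),
            skbio_distance.DistanceMatrix(d2.values),
            method="pearson", permutations=0)
        assert mantel_statistic(d1, d2) == pytest.approx(r_skbio, abs=1e-12)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        d1, d2 = random_distance(rng, 9), random_distance(rng, 9)
        assert mantel_statistic(d1, d2) == pytest.approx(
            mantel_statistic(d2, d1), abs=1e-14)

    def test_constant_matrix_rejected(self):
        v = np.full((4, 4), 2.0)
        np.fill_diagonal(v, 0.0)
        d1 = DistanceMatrix(list("abcd"), v)
        d2 = random_distance(np.random.default_rng(0), 4, ids=list("abcd"))
        with pytest.raises(DegenerateDistanceError):
            mantel_statistic(d1, d2)

    def test_misaligned_ids_rejected(self):
        rng = np.random.default_rng(1)
        d1 = random_distance(rng, 5)
        d2 = random_distance(rng, 5, ids=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError, match="ids"):
            mantel_statistic(d1, d2)


class TestMantelTest:
    def test_add_one_estimator_when_no_permutation_exceeds(self):
        # d2 == d1 gives r_obs = 1; with continuous data no relabeling ties it
        rng = np.random.default_rng(0)
        d1 = random_distance(rng, 12)
        res = mantel_test(d1, d1, B=99, seed=1)
        assert res.exceed == 0
        assert res.p == pytest.approx(1 / 100)

    def test_agrees_with_exhaustive_enumeration_at_n4(self):
        rng = np.random.default_rng(7)
        d1, d2 = random_distance(rng, 4), random_distance(rng, 4)
        r_obs = mantel_statistic(d1, d2)
        iu = np.triu_indices(4, 1)
        exceed = total = 0
        for perm in itertools.permutations(range(4)):
            yp = d2.values[np.ix_(perm, perm)]
            r = np.corrcoef(d1.values[iu], yp[iu])[0, 1]
            exceed += r >= r_obs - 1e-12
            total += 1
        exact = exceed / total  # includes the identity relabeling
        res = mantel_test(d1, d2, B=4999, seed=3)
        tol = 4 * np.sqrt(exact * (1 - exact) / 4999) + 1e-3
        assert res.p == pytest.approx(exact, abs=tol)

    def test_seed_reproduces_exceed_count_exactly(self):
        rng = np.random.default_rng(4)
        d1, d2 = random_distance(rng, 15), random_distance(rng, 15)
        a = mantel_test(d1, d2, B=199, seed=11)
        b = mantel_test(d1, d2, B=199, seed=11)
        assert (a.exceed, a.p) == (b.exceed, b.p)

    def test_two_sided_alternative(self):
        rng = np.random.default_rng(8)
        d1, d2 = random_distance(rng, 10), random_distance(rng, 10)
        res = mantel_test(d1, d2, B=99, seed=0, alternative="two-sided")
        assert 1 / 100 <= res.p <= 1.0


class TestSingleMarkerScan:
    def test_scan_r_matches_pairwise_mantel(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        scan = single_marker_scan(g, d, B=0)
        tab = scan.table.set_index("marker")
        for mk in tab.index[:5]:
            r_direct = mantel_statistic(genotype_distance(g, [mk]), d)
            assert tab.loc[mk, "r"] == pytest.approx(r_direct, abs=1e-12)

    def test_ibs_metric_matches_pairwise_mantel(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        scan = single_marker_scan(g, d, B=0, metric="ibs_mismatch")
        tab = scan.table.set_index("marker")
        mk = tab.index[0]
        r_direct = mantel_statistic(
            genotype_distance(g, [mk], metric="ibs_mismatch"), d)
        assert tab.loc[mk, "r"] == pytest.approx(r_direct, abs=1e-12)

    def test_monomorphic_markers_skipped(self):
        d = np.array([[0, 1, 1], [0, 1, 2], [0, 1, 0], [0, 1, 1]], dtype=np.int8)
        g = make_genotypes(d)
        rng = np.random.default_rng(0)
        pheno_d = random_distance(rng, 4, ids=list(g.samples))
        scan = single_marker_scan(g, pheno_d, B=9, seed=0)
        assert set(scan.skipped) == {"m0", "m1"}
        assert set(scan.table["marker"]) == {"m2"}

    def test_all_monomorphic_raises(self):
        g = make_genotypes(np.ones((4, 3), dtype=np.int8))
        pheno_d = random_distance(np.random.default_rng(0), 4, ids=list(g.samples))
        with pytest.raises(EmptyScanError):
            single_marker_scan(g, pheno_d, B=9)

    def test_seed_determinism(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        a = single_marker_scan(g, d, B=49, seed=5)
        b = single_marker_scan(g, d, B=49, seed=5)
        assert a.table.equals(b.table)

    def test_gate_mode_matches_exact_eligibility(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        gate = single_marker_scan(g, d, B=199, seed=9, mode="gate", p_gate=0.01)
        exact = single_marker_scan(g, d, B=199, seed=9, mode="exact")
        assert eligible_markers(gate, 0.01) == eligible_markers(exact, 0.01)
        # truncated markers never report a p on the eligible side of the gate
        failed = gate.table[gate.table["n_perm"] < 199]
        assert (failed["p"] >= 0.01).all()

    def test_planted_single_locus_attains_top_rank(self):
        # one strong locus (half the phenotypic variance) at n=200
        hits = 0
        for rep in range(20):
            g, pheno, _, truth = planted(seed=1000 + rep, n_samples=200,
                                         n_markers=400, n_causal=1,
                                         heritability=0.5)
            d = phenotype_distance(pheno, "context_avgmot")
            scan = single_marker_scan(g, d, B=0)
            causal = truth.causal["sham"][0]
            top = scan.table["marker"].iloc[0]
            ci = list(g.markers).index(causal)
            ti = list(g.markers).index(top)
            same_chrom = (g.marker_map.iloc[ci]["chrom"]
                          == g.marker_map.iloc[ti]["chrom"])
            hits += (top == causal) or (same_chrom and abs(ci - ti) <= 20)
        assert hits >= 16
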