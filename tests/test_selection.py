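import numpy as np
import pandas as pd
import pytest

from mantelqtl.distance import genotype_distance, phenotype_distance
from mantelqtl.mantel import ScanResult, mantel_statistic, single_marker_scan
from mantelqtl.selection import (SelectionCurve, cumulative_curve,
                                 eligible_markers, marker_set_analysis,
                                 select_peak)

from conftest import planted


def scan_from(p_values, r_values=None):
    m = len(p_values)
    r = r_values if r_values is not None else np.linspace(0.5, 0.1, m)
    table = pd.DataFrame({
        "marker": [f"m{j}" for j in range(m)],
        "chrom": ["chr1"] * m, "bp": np.arange(m) + 1,
        "r": r, "p": p_values,
        "exceed": 0, "n_perm": 999,
    })
    return ScanResult(table, B=999, seed=0, mode="exact", p_gate=None, skipped=[])


class TestEligibleMarkers:
    def test_none_pass(self):
        assert eligible_markers(scan_from([0.02, 0.5, 0.011]), 0.01) == []

    def test_gate_is_strict_and_preserves_rank_order(self):
        scan = scan_from([0.005, 0.02, 0.009, 0.01])
        assert eligible_markers(scan, 0.01) == ["m0", "m2"]


class TestCumulativeCurve:
    def test_k1_is_bit_identical_to_scan_r(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        scan = single_marker_scan(g, d, B=199, seed=3, mode="gate")
        elig = eligible_markers(scan, 0.01)
        assert elig, "planted fixture should yield eligible markers"
        curve = cumulative_curve(g, d, elig)
        r_lookup = scan.table.set_index("marker")["r"]
        assert curve.c[0] == r_lookup[elig[0]]

    @pytest.mark.parametrize("metric", ["manhattan_dosage", "ibs_mismatch"])
    def test_incremental_equals_full_recomputation(self, metric):
        g, pheno, _, _ = planted(seed=5, n_samples=40, n_markers=50)
        d = phenotype_distance(pheno, "context_avgmot")
        order = list(g.markers)
        curve = cumulative_curve(g, d, order, metric=metric)
        for k in range(1, 51):
            full = mantel_statistic(
                genotype_distance(g, order[:k], metric=metric), d)
            assert curve.c[k - 1] == pytest.approx(full, abs=1e-10)

    def test_invariant_to_sample_ordering(self):
        g, pheno, _, _ = planted(seed=6, n_samples=30, n_markers=20)
        d = phenotype_distance(pheno, "context_avgmot")
        order = list(g.markers)[:10]
        c1 = cumulative_curve(g, d, order).c
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_samples)
        ids = [g.samples[i] for i in perm]
        g2 = g.subset_samples(ids)
        d2 = phenotype_distance(pheno.subset_samples(ids), "context_avgmot")
        np.testing.assert_allclose(cumulative_curve(g2, d2, order).c, c1,
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", [9, 12, 15])
    def test_planted_multilocus_set_beats_best_single_marker(self, seed):
        # balanced 5-locus architecture: the combined true set carries more
        # signal than any one locus, so the cumulative correlation at k=5
        # over the true loci must exceed the best single-marker correlation
        import pandas as pd
        from mantelqtl.simulate import (ArchitectureSpec, simulate_founder_panel,
                                        simulate_hs_genomes, simulate_phenotypes)
        ss = np.random.SeedSequence(seed).spawn(4)
        panel = simulate_founder_panel(8, 200, seed=ss[0])
        g = simulate_hs_genomes(panel, 250, 20, seed=ss[1])
        cond = pd.DataFrame({"cohort": ["c"] * 250, "condition": ["sham"] * 250},
                            index=pd.Index(g.samples, name="sample"))
        rng = np.random.default_rng(ss[2])
        causal = list(rng.choice(g.markers, 5, replace=False))
        spec = ArchitectureSpec(effects={"sham": [(m, 1.0) for m in causal]},
                                heritability=0.7,
                                seed=int(ss[3].generate_state(1)[0] % 2**31))
        pheno, _ = simulate_phenotypes(g, spec, cond)
        d = phenotype_distance(pheno, "context_avgmot")
        scan = single_marker_scan(g, d, B=0)
        curve = cumulative_curve(g, d, causal)
        assert curve.c[4] > scan.table["r"].max()

    def test_empty_marker_list_rejected(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        with pytest.raises(ValueError, match="nonempty"):
            cumulative_curve(g, d, [])


class TestSelectPeak:
    def make(self, c):
        m = np.array([f"m{j}" for j in range(len(c))], dtype=object)
        return SelectionCurve(m, np.array(c), p_gate=0.01)

    def test_strictly_increasing_curve_selects_all(self):
        k, markers = select_peak(self.make([0.1, 0.2, 0.3, 0.4]), plateau_tol=0.0)
        assert k == 4 and len(markers) == 4

    def test_interior_peak(self):
        k, markers = select_peak(self.make([0.10, 0.30, 0.25, 0.20]), plateau_tol=0.0)
        assert k == 2 and markers == ["m0", "m1"]

    def test_plateau_tolerance_takes_earliest_entry(self):
        k, _ = select_peak(self.make([0.10, 0.29, 0.30, 0.30]), plateau_tol=0.05)
        assert k == 2  # 0.29 >= 0.95 * 0.30

    def test_zero_tolerance_hits_exact_maximum(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(30)
        curve = self.make(c)
        k, _ = select_peak(curve, plateau_tol=0.0)
        assert curve.c[k - 1] == c.max()


class TestMarkerSetAnalysis:
    def test_no_eligible_markers_yields_empty_analysis(self):
        g, pheno, _, _ = planted(seed=13, n_samples=60, n_markers=40,
                                 heritability=0.0)
        d = phenotype_distance(pheno, "context_avgmot")
        res = marker_set_analysis(g, d, B=999, seed=1, p_gate=0.002)
        assert res.eligible == []
        assert res.curve is None and res.peak_markers == []
        assert res.k_star is None and res.peak_value is None

    def test_unattainable_gate_rejected(self, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        with pytest.raises(ValueError, match="unattainable"):
            marker_set_analysis(g, d, B=199, seed=1, p_gate=0.001)

    def test_curve_tsv_round_trip(self, tmp_path, small_planted):
        g, pheno = small_planted[0], small_planted[1]
        d = phenotype_distance(pheno, "context_avgmot")
        res = marker_set_analysis(g, d, B=199, seed=3)
        res.curve.to_tsv(tmp_path / "curve.tsv")
        back = pd.read_csv(tmp_path / "curve.tsv", sep="\t")
        assert list(back["marker"]) == list(res.curve.markers)
        np.testing.assert_allclose(back["c_k"], res.curve.c, rtol=1e-9)
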