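"""QTL engine: marker QC, scan-vs-OLS oracle equivalence, permutation
machinery, cofactor selection, support intervals, effect tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatscan.core import CrossDesign, GenotypeMatrix
from heatscan.qtl import (Cofactor, QTLScanner, compact_letter_display,
                          combined_effect, crossing_components,
                          filter_markers_qc, lod_drop_ci, permutation_threshold,
                          posthoc_tests, scan, select_cofactors,
                          simultaneous_fit)
from heatscan.simulate import default_cross_design, simulate_cross_genotypes
from tests.conftest import small_map


def geno_with_counts(n_aa, n_ab, n_bb):
    codes = np.array([0] * n_aa + [1] * n_ab + [2] * n_bb, dtype=np.int8)
    return GenotypeMatrix([f"i{k}" for k in range(len(codes))], ["m1"],
                          codes[:, None], np.ones(len(codes), int),
                          CrossDesign({1: ("P", "Q")}))


class TestMarkerQc:
    def test_balanced_marker_kept(self):
        kept, removed = filter_markers_qc(geno_with_counts(25, 50, 25))
        assert kept.markers == ["m1"]
        assert removed.empty

    def test_strong_distortion_removed(self):
        # 45 AA + 5 BB from 50 individuals: allele counts 90 vs 10,
        # chi-square (90-10)^2/100 = 64
        kept, removed = filter_markers_qc(geno_with_counts(45, 0, 5))
        assert kept.markers == []
        assert removed.iloc[0]["reason"] == "segregation distortion"
        assert removed.iloc[0]["chi2"] == pytest.approx(64.0)
        assert removed.iloc[0]["p"] == pytest.approx(
            stats.chi2.sf(64.0, 1), rel=1e-6)

    def test_mild_distortion_survives_strict_alpha(self):
        # allele counts 60 vs 40: chi-square 4.0, P ~ 0.046 > 0.001
        kept, removed = filter_markers_qc(geno_with_counts(30, 0, 20))
        assert kept.markers == ["m1"]

    def test_monomorphic_marker_flagged(self):
        kept, removed = filter_markers_qc(geno_with_counts(50, 0, 0))
        assert kept.markers == []
        assert "monomorphic" in removed.iloc[0]["reason"]


@pytest.fixture(scope="module")
def small_scanner():
    gmap = small_map(n_chrom=3, n_markers=9, length=100.0)
    rng = np.random.default_rng(77)
    geno = simulate_cross_genotypes(gmap, default_cross_design(),
                                    pop_sizes=[60] * 6, rng=rng)
    return QTLScanner(geno, gmap, step=5.0)


def planted_phenotype(scanner, marker_idx, effects, noise_sd, seed=0,
                      dominance=None):
    geno = scanner.geno
    rng = np.random.default_rng(seed)
    codes = geno.codes[:, marker_idx]
    g = np.zeros(geno.n_individuals)
    for pop in geno.cross_design.populations:
        a, b = geno.cross_design.parents_of(pop)
        sel = geno.population == pop
        g[sel] = ((2 - codes[sel]) * effects.get(a, 0.0)
                  + codes[sel] * effects.get(b, 0.0))
        if dominance and pop in dominance:
            g[sel & (codes == 1)] += dominance[pop]
    y = g + rng.normal(0, noise_sd, len(g))
    return pd.Series(y, index=geno.individuals), g


class TestScan:
    def test_f_matches_brute_force_ols_at_markers(self, small_scanner):
        """At fully informative marker positions the expected-design scan
        reduces to plain two-model OLS; F must agree to 1e-8."""
        sc = small_scanner
        y, _ = planted_phenotype(sc, 4, {"S067": -0.4, "P040": 0.4}, 1.0)
        prof = scan(y.to_numpy(), sc.sd_markers)
        geno = sc.geno
        for i in [0, 4, 13]:
            codes = geno.codes[:, i].astype(float)
            # oracle: population dummies vs + additive doses + dominance
            X0 = pd.get_dummies(geno.population).to_numpy(float)
            dose = {p: np.zeros(len(codes)) for p in geno.cross_design.all_parents}
            het = np.zeros((len(codes), 6))
            for k, pop in enumerate(geno.cross_design.populations):
                a, b = geno.cross_design.parents_of(pop)
                sel = geno.population == pop
                dose[a][sel] += 2 - codes[sel]
                dose[b][sel] += codes[sel]
                het[sel, k] = codes[sel] == 1
            X1 = np.hstack([X0] + [v[:, None] for v in dose.values()] + [het])
            yv = y.to_numpy()

            def rss(X):
                b, *_ = np.linalg.lstsq(X, yv, rcond=None)
                r = yv - X @ b
                return r @ r, np.linalg.matrix_rank(X)

            r0, p0 = rss(X0)
            r1, p1 = rss(X1)
            q = p1 - p0
            f_oracle = ((r0 - r1) / q) / (r1 / (len(yv) - p1))
            assert prof.iloc[i]["F"] == pytest.approx(f_oracle, abs=1e-8)

    def test_null_f_profile_near_one(self, small_scanner):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(0, 1, small_scanner.geno.n_individuals),
                      index=small_scanner.geno.individuals)
        prof = scan(y.to_numpy(), small_scanner.sd_grid)
        assert 0.5 < prof["F"].mean() < 1.6

    def test_peak_lands_near_planted_locus(self, small_scanner):
        sc = small_scanner
        y, g = planted_phenotype(sc, 13, {"S070": 0.6, "L043": -0.6}, 0.8,
                                 seed=1)
        prof = scan(y.to_numpy(), sc.sd_grid)
        best = prof.iloc[prof["F"].idxmax()]
        true_cm = 50.0  # marker 13 = chr 2, 5th of 9 markers on 0-100
        assert best["chromosome"] == 2
        assert abs(best["cm"] - true_cm) <= 5.0

    def test_lod_and_f_are_consistent_transforms(self, small_scanner):
        sc = small_scanner
        y, _ = planted_phenotype(sc, 4, {"S067": -0.5, "P040": 0.5}, 1.0)
        prof = scan(y.to_numpy(), sc.sd_grid)
        n = sc.geno.n_individuals
        # same RSS ratio underlies both columns
        ratio = 10 ** (2 * prof["lod"] / n)
        q, dfe = prof["df"], n - sc.sd_grid.pop_dummies.shape[1] - prof["df"]
        f_back = (ratio - 1) * (n - sc.sd_grid.pop_dummies.shape[1] - q) / q
        np.testing.assert_allclose(f_back, prof["F"], rtol=1e-6)

    def test_connected_effect_pooled_across_populations(self, small_scanner):
        """An allele effect shared by two populations of one parent is
        recovered as a single pooled estimate."""
        sc = small_scanner
        y, _ = planted_phenotype(sc, 4, {"S067": 1.0, "P040": -0.5,
                                         "L012": -0.5}, 0.05, seed=2)
        fit = simultaneous_fit(y.to_numpy(), sc.sd_markers, [(1, 50.0)])
        add = fit["additive"][0]
        eff = dict(zip(add["parents"], add["effect"]))
        assert eff["S067"] == pytest.approx(1.0, abs=0.05)


class TestPermutation:
    def test_alpha_one_gives_min_of_max_f(self, small_scanner):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, small_scanner.geno.n_individuals)
        out = permutation_threshold(y, small_scanner.sd_grid,
                                    small_scanner.population, n_perm=100,
                                    alpha=1.0, rng=rng)
        assert out["threshold"] == pytest.approx(out["max_f"].min())

    def test_small_n_perm_warns(self, small_scanner):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, small_scanner.geno.n_individuals)
        with pytest.warns(UserWarning, match="small"):
            permutation_threshold(y, small_scanner.sd_grid,
                                  small_scanner.population, n_perm=50, rng=rng)

    def test_threshold_tracks_null_f_scale(self, small_scanner):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, small_scanner.geno.n_individuals)
        out = permutation_threshold(y, small_scanner.sd_grid,
                                    small_scanner.population, n_perm=300,
                                    alpha=0.05, rng=rng)
        assert 2.0 < out["threshold"] < 6.0


class TestCofactors:
    def test_no_signal_gives_empty_set(self, small_scanner):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, small_scanner.geno.n_individuals)
        assert select_cofactors(y, small_scanner.sd_markers, 8.0) == []

    def test_two_distant_signals_both_selected(self, small_scanner):
        sc = small_scanner
        y1, _ = planted_phenotype(sc, 1, {"S067": 0.7, "P040": -0.7}, 0.0)
        y2, _ = planted_phenotype(sc, 7, {"S070": 0.7, "L023": -0.7}, 0.0)
        y = (y1 + y2 + np.random.default_rng(3).normal(0, 0.7, len(y1)))
        cof = select_cofactors(y.to_numpy(), sc.sd_markers, 5.0,
                               min_spacing=10.0)
        cms = sorted((c.chromosome, c.cm) for c in cof)
        assert (1, 12.5) in cms and (1, 87.5) in cms

    def test_spacing_rule_keeps_only_stronger_neighbor(self, small_scanner):
        """Markers 12.5 cM apart carry correlated signal; the greedy rule
        must never select two cofactors closer than the spacing."""
        sc = small_scanner
        y, _ = planted_phenotype(sc, 4, {"S067": 1.0, "P040": -1.0}, 0.3)
        cof = select_cofactors(y.to_numpy(), sc.sd_markers, 5.0,
                               min_spacing=20.0)
        cms = [(c.chromosome, c.cm) for c in cof]
        for i, (c1, p1) in enumerate(cms):
            for c2, p2 in cms[i + 1:]:
                assert c1 != c2 or abs(p1 - p2) >= 20.0


class TestLodDropCi:
    def test_triangular_profile_geometry(self):
        cm = np.arange(0, 101, 5.0)
        lod = 10.0 - 0.3 * np.abs(cm - 50.0)
        prof = pd.DataFrame({"cm": cm, "lod": lod})
        lo, hi = lod_drop_ci(prof, 50.0, drop=1.5)
        assert lo == pytest.approx(45.0)
        assert hi == pytest.approx(55.0)

    def test_clipped_at_chromosome_end(self):
        cm = np.arange(0, 51, 5.0)
        prof = pd.DataFrame({"cm": cm, "lod": np.full(len(cm), 5.0)})
        lo, hi = lod_drop_ci(prof, 25.0, drop=1.5)
        assert (lo, hi) == (0.0, 50.0)

    def test_monotone_profile_peak_at_origin(self):
        cm = np.arange(0, 51, 5.0)
        prof = pd.DataFrame({"cm": cm, "lod": 8.0 - 0.2 * cm})
        lo, hi = lod_drop_ci(prof, 0.0, drop=1.5)
        assert lo == 0.0
        assert hi == pytest.approx(7.5)

    def test_interpolation_between_grid_points(self):
        prof = pd.DataFrame({"cm": [0.0, 10.0, 20.0], "lod": [1.0, 5.0, 1.0]})
        lo, hi = lod_drop_ci(prof, 10.0, drop=1.5)
        assert lo == pytest.approx(10 - 1.5 / 0.4)
        assert hi == pytest.approx(10 + 1.5 / 0.4)


class TestSimultaneousFit:
    def test_single_locus_equals_sequential_r2(self, small_scanner):
        sc = small_scanner
        y, _ = planted_phenotype(sc, 4, {"S067": -0.6, "P040": 0.6}, 1.0)
        fit = simultaneous_fit(y.to_numpy(), sc.sd_markers, [(1, 50.0)])
        assert fit["r2_single"][0] == pytest.approx(fit["r2_total"], abs=1e-12)

    def test_r2_matches_rss_oracle(self, small_scanner):
        sc = small_scanner
        y, _ = planted_phenotype(sc, 4, {"S067": -0.6, "P040": 0.6}, 1.0)
        yv = y.to_numpy()
        fit = simultaneous_fit(yv, sc.sd_markers, [(1, 50.0)])
        X0 = sc.sd_markers.pop_dummies
        X1 = np.hstack([X0, sc.sd_markers.blocks[4]])
        def rss(X):
            b, *_ = np.linalg.lstsq(X, yv, rcond=None)
            r = yv - X @ b
            return float(r @ r)
        assert fit["r2_total"] == pytest.approx(1 - rss(X1) / rss(X0),
                                                abs=1e-10)

    def test_independent_loci_explain_additively(self, small_scanner):
        sc = small_scanner
        r2_tot = []
        for seed in range(5):
            y1, g1 = planted_phenotype(sc, 2, {"S067": 0.5, "P040": -0.5},
                                       0.0, seed=seed)
            y2, g2 = planted_phenotype(sc, 22, {"S058": 0.5, "S070": -0.5},
                                       0.0, seed=seed)
            noise_sd = np.sqrt((np.var(g1) + np.var(g2)) * 8 / 2)
            rng = np.random.default_rng(seed)
            y = g1 + g2 + rng.normal(0, noise_sd, len(g1))
            f1 = simultaneous_fit(y, sc.sd_markers, [(1, 25.0)])
            f2 = simultaneous_fit(y, sc.sd_markers, [(3, 50.0)])
            fj = simultaneous_fit(y, sc.sd_markers, [(1, 25.0), (3, 50.0)])
            r2_tot.append(fj["r2_total"] - (f1["r2_total"] + f2["r2_total"]))
        assert abs(np.mean(r2_tot)) < 0.05


class TestPosthoc:
    def _fit(self, scanner, dominance=None):
        y, _ = planted_phenotype(scanner, 4, {"S067": -0.8, "P040": 0.8},
                                 0.3, seed=4, dominance=dominance)
        fit = simultaneous_fit(y.to_numpy(), scanner.sd_markers, [(1, 50.0)])
        return posthoc_tests(fit["additive"][0], fit["dominance"][0],
                             fit["ddf"])

    def test_separated_parents_get_distinct_letters(self, small_scanner):
        add, dom = self._fit(small_scanner)
        letters = dict(zip(add["parent"], add["letters"]))
        assert set(letters["S067"]).isdisjoint(set(letters["P040"]))

    def test_dominance_stars_follow_normal_test(self, small_scanner):
        add, dom = self._fit(small_scanner, dominance={1: 1.5})
        row = dom[dom["population"] == 1].iloc[0]
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(row["z"])),
                                         rel=1e-9)
        assert row["stars"] in ("*", "**", "***")

    def test_normal_two_sided_p_for_z_3_5(self):
        # d/SE = 3.5 -> p = 2*Phi(-3.5) ~ 4.65e-4 -> three stars
        from heatscan.hsi import significance_stars
        p = 2 * stats.norm.sf(3.5)
        assert p == pytest.approx(4.65e-4, rel=0.01)
        assert significance_stars(p) == "***"


class TestCompactLetters:
    def test_textbook_example(self):
        # A differs from C; B overlaps both
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 2] = sig[2, 0] = True
        letters = compact_letter_display(["A", "B", "C"], sig)
        assert set(letters["A"]).isdisjoint(letters["C"])
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])

    @pytest.mark.parametrize("seed", range(6))
    def test_display_consistency_random_graphs(self, seed):
        """Shared letter iff pair not significant, for random patterns."""
        rng = np.random.default_rng(seed)
        k = 7
        sig = rng.random((k, k)) < 0.3
        sig = np.triu(sig, 1)
        sig = sig | sig.T
        names = [f"p{i}" for i in range(k)]
        letters = compact_letter_display(names, sig)
        for i in range(k):
            for j in range(i + 1, k):
                shared = set(letters[names[i]]) & set(letters[names[j]])
                if sig[i, j]:
                    assert not shared
                else:
                    assert shared

    def test_combined_effect_reads_table(self):
        tab = pd.DataFrame({
            "qtl": ["Qa", "Qa", "Qb"], "level": ["S067", "P040", "P040"],
            "effect": [0.53, -1.03, 0.33]})
        total = combined_effect(tab, [("Qa", "S067"), ("Qb", "P040")])
        assert total == pytest.approx(0.86)


class TestCrossingGraph:
    def test_two_components_in_default_design(self):
        comps = crossing_components(default_cross_design())
        assert sorted(map(len, comps)) == [4, 4]
        flat = {p for c in comps for p in c}
        assert len(flat) == 8
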