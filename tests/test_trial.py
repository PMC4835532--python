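"""Adjustment cascade: thermal time, trait derivations, subexperiment
effects, entry means, and the condition-effect test."""

import numpy as np
import pandas as pd
import pytest

from heatscan.simulate import TrialDesign, simulate_trial
from heatscan.trial import (adjust_fieldbook, adjust_observations,
                            aem_per_condition, aem_per_location, compute_gdd,
                            condition_effect_test, derive_traits,
                            fit_standards_model)


def wx(rows):
    return pd.DataFrame([{"location": "L", "date": pd.Timestamp("2012-06-01")
                          + pd.Timedelta(days=i), "tmin": lo, "tmax": hi}
                         for i, (lo, hi) in enumerate(rows)])


class TestGdd:
    @pytest.mark.parametrize("tmin,tmax,expected", [
        (10.0, 10.0, 0.0),     # exactly at base temperature
        (20.0, 30.0, 15.0),    # (30+20)/2 - 10
        (4.0, 12.0, 0.0),      # negative degree day clamps to zero
    ])
    def test_single_day(self, tmin, tmax, expected):
        assert compute_gdd(wx([(tmin, tmax)]))["L"] == pytest.approx(expected)

    def test_missing_day_is_hard_error(self):
        frame = wx([(10, 20), (10, 20), (10, 20)])
        frame = frame.drop(index=1)
        with pytest.raises(ValueError, match="missing days"):
            compute_gdd(frame)


class TestDeriveTraits:
    def test_closed_forms_and_missing_propagation(self):
        fb = pd.DataFrame({"MF": [70.0, 70.0], "FF": [72.0, 72.0],
                           "FY": [100.0, np.nan], "GM": [32.5, 30.0]})
        out = derive_traits(fb)
        assert out["ASI"].iloc[0] == pytest.approx(2.0)
        assert out["DY"].iloc[0] == pytest.approx(100 * 0.675 / 0.85)
        assert np.isnan(out["DY"].iloc[1])

    def test_full_moisture_rejected(self):
        fb = pd.DataFrame({"FY": [10.0], "GM": [100.0]})
        with pytest.raises(ValueError, match="moisture"):
            derive_traits(fb)


def standards_toy(delta=0.0, delta_sub=3, n_sub=6):
    """Noise-free standards layout: 8 parents once per subexperiment,
    2 replications, one block per subexperiment; one subexperiment
    optionally shifted by delta in replication 1."""
    rows = []
    for rep in (1, 2):
        for sub in range(1, n_sub + 1):
            for k in range(8):
                val = 100.0 + (delta if rep == 1 and sub == delta_sub else 0.0)
                rows.append({"genotype": f"P{k}", "is_standard": True,
                             "population": pd.NA, "location": "Einbeck",
                             "condition": "standard", "replication": rep,
                             "subexperiment": sub, "block": 1, "MF": val})
    return pd.DataFrame(rows)


class TestStandardsModel:
    def test_identical_standards_give_zero_effects(self):
        fit = fit_standards_model(standards_toy(), "Einbeck", "MF")
        assert all(abs(v) < 1e-8 for v in fit.effects.values())

    def test_delta_injection_recovered_by_ols_algebra(self):
        """Shifting one of k subexperiments by delta gives effects
        delta*(k-1)/k for it and -delta/k for the others (sum-to-zero
        least squares on the toy layout)."""
        delta, k = 6.0, 6
        fit = fit_standards_model(standards_toy(delta=delta), "Einbeck", "MF")
        assert fit.effects[(1, 3)] == pytest.approx(delta * (k - 1) / k, abs=1e-8)
        for s in [1, 2, 4, 5, 6]:
            assert fit.effects[(1, s)] == pytest.approx(-delta / k, abs=1e-8)
        for s in range(1, 7):
            assert fit.effects[(2, s)] == pytest.approx(0.0, abs=1e-8)

    def test_adjustment_equalizes_standards_and_is_idempotent(self):
        fb = standards_toy(delta=6.0)
        fit = fit_standards_model(fb, "Einbeck", "MF")
        adj = adjust_observations(fb, {"MF": {"Einbeck": fit.effects}})
        per_sub = adj.groupby(["replication", "subexperiment"])["MF"].mean()
        for rep in (1, 2):  # equal within replication (rep effect remains)
            assert per_sub[rep].std() == pytest.approx(0.0, abs=1e-8)
        refit = fit_standards_model(adj, "Einbeck", "MF")
        assert all(abs(v) < 1e-8 for v in refit.effects.values())

    def test_simulation_recovery_of_subexperiment_effects(self, small_trial):
        """With only subexperiment noise, the estimated effects match the
        realized subexperiment means."""
        from tests.test_simulate import flat_architecture
        arch = flat_architecture(sigma_subexp=2.0)
        fb, _ = simulate_trial(small_trial["geno"], arch, TrialDesign(),
                               np.random.default_rng(5), small_trial["gmap"])
        fit = fit_standards_model(fb, "Einbeck", "MF")
        d = fb[fb["location"] == "Einbeck"]
        for rep in (1, 2):
            sub_means = d[d["replication"] == rep].groupby("subexperiment")[
                "MF"].mean()
            centered = sub_means - sub_means.mean()
            for s, v in centered.items():
                assert fit.effects[(rep, s)] == pytest.approx(v, abs=1e-6)


def aem_toy():
    """3 genotypes, 2 reps; g3 only observed in rep 2; rep 2 shifted."""
    rho = 4.0
    rows = []
    vals = {"g1": 10.0, "g2": 14.0, "g3": 12.0}
    for rep in (1, 2):
        for g, v in vals.items():
            if g == "g3" and rep == 1:
                continue
            rows.append({"genotype": g, "is_standard": False, "population": 1,
                         "location": "Einbeck", "condition": "standard",
                         "replication": rep, "subexperiment": 1, "block": 1,
                         "MF": v + (rho if rep == 2 else 0.0)})
    return pd.DataFrame(rows), vals, rho


class TestEntryMeans:
    def test_balanced_noise_free_equals_plot_means(self, small_trial):
        from tests.test_simulate import flat_architecture
        arch = flat_architecture(sigma_g=1.0)
        fb, truth = simulate_trial(small_trial["geno"], arch, TrialDesign(),
                                   np.random.default_rng(6),
                                   small_trial["gmap"])
        aem = aem_per_location(fb, "Einbeck", "MF")
        plot_means = fb[fb["location"] == "Einbeck"].groupby("genotype")[
            "MF"].mean()
        np.testing.assert_allclose(aem.sort_index(), plot_means.sort_index(),
                                   atol=1e-7)
        # and the plot means equal the generating values exactly (no noise)
        np.testing.assert_allclose(
            aem.sort_index(),
            truth.true_aem["MF"]["Einbeck"].sort_index(), atol=1e-7)

    def test_unbalanced_rep_effect_corrected_via_hand_gls(self):
        """A genotype seen only in the shifted replication is corrected by
        the replication effect identified from the balanced genotypes."""
        fb, vals, rho = aem_toy()
        aem = aem_per_location(fb, "Einbeck", "MF")
        # hand OLS oracle: y = mu + G (sum-zero) + R (sum-zero)
        X = []
        y = []
        gl = ["g1", "g2", "g3"]
        for _, r in fb.iterrows():
            g = gl.index(r["genotype"])
            grow = [1.0, 0.0] if g == 0 else ([0.0, 1.0] if g == 1 else [-1.0, -1.0])
            rrow = [1.0] if r["replication"] == 1 else [-1.0]
            X.append([1.0] + grow + rrow)
            y.append(r["MF"])
        beta, *_ = np.linalg.lstsq(np.array(X), np.array(y), rcond=None)
        expect = {"g1": beta[0] + beta[1], "g2": beta[0] + beta[2],
                  "g3": beta[0] - beta[1] - beta[2]}
        for g in gl:
            assert aem[g] == pytest.approx(expect[g], abs=1e-7)
        # correction moves g3 toward its true value
        naive = fb[fb["genotype"] == "g3"]["MF"].mean()
        assert abs(aem["g3"] - vals["g3"]) < abs(naive - vals["g3"])

    def test_condition_means_balanced_identity(self, small_trial):
        from tests.test_simulate import flat_architecture
        arch = flat_architecture(sigma_g=1.0)
        fb, _ = simulate_trial(small_trial["geno"], arch, TrialDesign(),
                               np.random.default_rng(7), small_trial["gmap"])
        aem = aem_per_condition(fb, "standard", "MF")
        means = fb[fb["condition"] == "standard"].groupby("genotype")["MF"].mean()
        np.testing.assert_allclose(aem.sort_index(), means.sort_index(),
                                   atol=1e-7)

    def test_aem_recovery_improves_with_less_noise(self, small_trial):
        from tests.test_simulate import flat_architecture
        truth_cors = []
        for s_e in (4.0, 0.5):
            arch = flat_architecture(sigma_g=1.0,
                                     sigma_e={"standard": s_e, "heat": s_e})
            fb, truth = simulate_trial(small_trial["geno"], arch,
                                       TrialDesign(),
                                       np.random.default_rng(8),
                                       small_trial["gmap"])
            aem = aem_per_location(fb, "Einbeck", "MF")
            t = truth.true_aem["MF"]["Einbeck"].reindex(aem.index)
            truth_cors.append(np.corrcoef(aem, t)[0, 1])
        assert truth_cors[1] > truth_cors[0]
        assert truth_cors[1] > 0.95


class TestConditionEffect:
    def test_huge_injected_effect_detected(self, small_trial):
        fb = small_trial["fieldbook"]
        ct = condition_effect_test(fb, "GM")
        assert ct.p_value < 1e-6
        assert ct.heat_dependent
        # location means reflect the generating stress multipliers
        assert ct.location_means["Monselice"] < 0.6 * ct.location_means["Einbeck"]

    def test_null_rejection_rate_near_alpha(self):
        """Type-I: no condition effect in the generating model."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 60
        genos = [f"g{i}" for i in range(15)]
        locs = [("A", "standard"), ("B", "standard"),
                ("C", "heat"), ("D", "heat")]
        for _ in range(n_sim):
            g_eff = rng.normal(0, 1.0, len(genos))
            cg = rng.normal(0, 0.5, (2, len(genos)))
            gl = rng.normal(0, 0.5, (4, len(genos)))
            rows = []
            for j, (loc, cond) in enumerate(locs):
                for rep in (1, 2):
                    for i, g in enumerate(genos):
                        c = 0 if cond == "standard" else 1
                        rows.append({
                            "genotype": g, "is_standard": False,
                            "population": 1, "location": loc,
                            "condition": cond, "replication": rep,
                            "subexperiment": 1, "block": 1,
                            "MF": g_eff[i] + cg[c, i] + gl[j, i]
                            + rng.normal(0, 1.0)})
            ct = condition_effect_test(pd.DataFrame(rows), "MF")
            rejections += ct.heat_dependent
        rate = rejections / n_sim
        assert rate <= 0.15

    def test_single_condition_rejected(self):
        fb, *_ = aem_toy()
        with pytest.raises(ValueError, match="both conditions"):
            condition_effect_test(fb, "MF")
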