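"""Imputation, bivariate fitting, Rubin pooling, INB, CEAC and subgroups."""

import numpy as np
import pandas as pd
import pytest

from periopcea.cea import (CEAC, CEEstimate, ceac, ceac_monte_carlo, fit_bivariate,
                           impute, inb, pool, sixmonth_cea, subgroup_cea,
                           utilities_to_index)
from periopcea.synthetic import TrialDesign, generate_trial


def make_est(dc, dq, vc=1.0, vq=1.0, cov=0.0):
    return CEEstimate(dc, dq, np.array([[vc, cov], [cov, vq]]))


class TestPool:
    def test_closed_form_m2(self):
        ests = [make_est(1.0, 1.0), make_est(3.0, 3.0)]
        pooled = pool(ests)
        assert pooled.delta_cost == 2.0
        # within 1 + (1+1/2)*2 = 4
        assert pooled.cov[0, 0] == pytest.approx(4.0)

    def test_identical_estimates_total_equals_within(self):
        ests = [make_est(2.0, 0.5, vc=3.0, vq=0.2, cov=0.1)] * 5
        pooled = pool(ests)
        assert np.allclose(pooled.cov, ests[0].cov)

    def test_random_inputs_match_rubin_formulas(self):
        rng = np.random.default_rng(2)
        m = 7
        pts = rng.normal(size=(m, 2))
        covs = []
        ests = []
        for i in range(m):
            a = rng.uniform(0.5, 2, size=2)
            c = np.diag(a)
            covs.append(c)
            ests.append(CEEstimate(pts[i, 0], pts[i, 1], c))
        pooled = pool(ests)
        mean = pts.mean(axis=0)
        within = np.mean(covs, axis=0)
        between = np.cov(pts.T, ddof=1)
        expected = within + (1 + 1 / m) * between
        assert np.allclose([pooled.delta_cost, pooled.delta_qaly], mean)
        assert np.allclose(pooled.cov, expected)


class TestINB:
    def test_arithmetic(self):
        assert inb(make_est(0.0, 0.2), 20000)[0] == pytest.approx(4000)

    def test_lambda_zero_identity(self):
        est = make_est(-350.0, 0.01)
        assert inb(est, 0.0)[0] == pytest.approx(350.0)

    def test_linearity_in_lambda(self):
        est = make_est(-404.0, 0.013)
        i1, i2 = inb(est, 10000)[0], inb(est, 30000)[0]
        assert i2 - i1 == pytest.approx(20000 * est.delta_qaly)

    def test_rounded_table_inputs_reproduce_printed_scale(self):
        # ΔQALY 0.01 and Δcost −404 at £20,000/QALY give £604 on rounded
        # inputs (a published analysis reports 580 from unrounded ΔQALY)
        assert inb(make_est(-404.0, 0.01), 20000)[0] == pytest.approx(604.0)

    def test_variance_formula(self):
        est = make_est(0.0, 0.0, vc=4.0, vq=9.0, cov=1.5)
        lam = 2.0
        _, se, _ = inb(est, lam)
        assert se ** 2 == pytest.approx(lam ** 2 * 9 + 4 - 2 * lam * 1.5)


class TestCEAC:
    def test_half_at_break_even_lambda(self):
        est = make_est(200.0, 0.01, vc=100.0 ** 2, vq=0.004 ** 2)
        lam = 200.0 / 0.01
        curve = ceac(est, [lam])
        assert curve.prob_ce[0] == pytest.approx(0.5)

    def test_dominance_probability_one(self):
        est = make_est(-500.0, 0.05, vc=1e-6, vq=1e-12)
        curve = ceac(est, np.linspace(0, 50000, 11))
        assert np.allclose(curve.prob_ce, 1.0)

    def test_limits(self):
        from scipy import stats
        est = make_est(-100.0, 0.004, vc=300.0 ** 2, vq=0.006 ** 2, cov=0.2 * 300 * 0.006)
        assert ceac(est, [0.0]).prob_ce[0] == pytest.approx(stats.norm.cdf(100 / 300))
        big = ceac(est, [1e12]).prob_ce[0]
        assert big == pytest.approx(stats.norm.cdf(0.004 / 0.006), abs=1e-6)

    def test_normal_vs_monte_carlo(self):
        est = make_est(-404.0, 0.01, vc=460 ** 2, vq=0.005 ** 2, cov=0.25 * 460 * 0.005)
        grid = np.arange(0, 50001, 2500.0)
        mc = ceac_monte_carlo(est, grid, n_draws=200_000, seed=5)
        assert np.max(np.abs(ceac(est, grid).prob_ce - mc.prob_ce)) < 0.005

    def test_zero_variance_warns_step(self):
        est = CEEstimate(-10.0, 0.0, np.zeros((2, 2)))
        with pytest.warns(UserWarning):
            curve = ceac(est, [0.0, 1000.0])
        assert list(curve.prob_ce) == [1.0, 1.0]


class TestImpute:
    def test_complete_data_returns_identical_copies(self, complete_trial, uk_vs):
        out = impute(complete_trial, m=3, seed=1, vs=uk_vs)
        assert len(out) == 3
        for t in out[1:]:
            pd.testing.assert_frame_equal(out[0], t)

    def test_deterministic_given_seed(self, small_trial, uk_vs):
        a = impute(small_trial, m=2, seed=9, vs=uk_vs)
        b = impute(small_trial, m=2, seed=9, vs=uk_vs)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = impute(small_trial, m=2, seed=10, vs=uk_vs)
        assert not a[0]["eq5d_6m"].equals(c[0]["eq5d_6m"])

    def test_death_structural_missing_not_imputed(self, small_trial, uk_vs):
        out = impute(small_trial, m=2, seed=1, vs=uk_vs)[0]
        dead = out["death_time_days"].notna()
        assert out.loc[dead, "eq5d_6m"].isna().all()

    def test_mcar_masked_pooled_close_to_complete(self):
        d = TrialDesign(n_per_arm=250, n_sites=5, seed=77,
                        missing_prob_30d=0.0, missing_prob_6m=0.0)
        full = generate_trial(d)
        est_full, _ = sixmonth_cea(full, m=2, seed=1)
        rng = np.random.default_rng(3)
        masked = full.copy()
        alive = masked["death_time_days"].isna()
        drop = alive & (rng.random(len(masked)) < 0.2)
        masked.loc[drop, "eq5d_6m"] = np.nan
        est_m, _ = sixmonth_cea(masked, m=10, seed=1)
        assert abs(est_m.delta_qaly - est_full.delta_qaly) < 2 * np.sqrt(est_full.cov[1, 1])

    def test_fully_missing_variable_fails_informatively(self, small_trial, uk_vs):
        broken = utilities_to_index(small_trial, uk_vs)
        broken["eq5d_30d"] = np.nan
        with pytest.raises(ValueError, match="eq5d_30d"):
            impute(broken, m=2, seed=0)


class TestFitBivariate:
    def test_null_cross_equation_correlation(self, complete_trial):
        # costs and utilities are generated independently, so the residual
        # cross-correlation should be near zero
        est, _ = sixmonth_cea(complete_trial, m=2, seed=0)
        n = len(complete_trial)
        assert abs(est.correlation) < 3 / np.sqrt(n)

    def test_rank_deficiency_reported(self, complete_trial):
        df = utilities_to_index(complete_trial).copy()
        df["dup"] = df["age"]
        df["qaly_6m"] = 0.3
        with pytest.raises(ValueError, match="collinear"):
            fit_bivariate(df, covariates=("age", "dup"))

    def test_site_modes_agree_on_point_estimates(self, complete_trial):
        est_a, _ = sixmonth_cea(complete_trial, m=2, seed=0, site_mode="random_intercept")
        est_b, _ = sixmonth_cea(complete_trial, m=2, seed=0, site_mode="fixed")
        assert est_a.delta_cost == pytest.approx(est_b.delta_cost, rel=0.25, abs=150)
        assert est_a.delta_qaly == pytest.approx(est_b.delta_qaly, abs=0.01)


class TestSubgroups:
    def test_level_sizes_partition_total(self, complete_trial):
        df = complete_trial
        for factor in ("urgency", "surgery_category", "recruitment_timing"):
            if factor == "recruitment_timing":
                sizes = [(df["recruitment_order_in_site"] <= 10).sum(),
                         (df["recruitment_order_in_site"] > 10).sum()]
            else:
                sizes = df[factor].value_counts().to_list()
            assert sum(sizes) == len(df)

    def test_single_level_factor_equals_overall(self, complete_trial):
        df = complete_trial.copy()
        df["urgency"] = "elective"
        est, completed = sixmonth_cea(df, m=2, seed=4)
        subs = subgroup_cea(df, "urgency", completed=completed)
        assert list(subs) == ["elective"]
        assert subs["elective"].delta_cost == pytest.approx(est.delta_cost)
        assert subs["elective"].delta_qaly == pytest.approx(est.delta_qaly)

    def test_tiny_level_skipped_with_warning(self, complete_trial):
        df = complete_trial.copy()
        df.loc[df.index[:-3], "urgency"] = "elective"
        df.loc[df.index[-3:], "urgency"] = "non_elective"
        _, completed = sixmonth_cea(df, m=2, seed=4)
        with pytest.warns(UserWarning, match="skipped"):
            subs = subgroup_cea(df, "urgency", completed=completed)
        assert "non_elective" not in subs
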