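"""Parametric survival fitting, life-table projection and lifetime QALYs."""

import numpy as np
import pandas as pd
import pytest

from periopcea.lifetime import (FAMILIES, LifeTable, ProjectionConfig, SurvivalFit,
                                UtilityNorms, add_lifetime_qalys, fit_all_families,
                                fit_parametric, lifetime_cea, project_qaly,
                                project_survival, select_model, synthetic_uk_lifetable,
                                synthetic_utility_norms)
from periopcea.cea import sixmonth_cea


def small_lifetable(qx_const, terminal=90, start=60):
    rows = []
    for sex in ("M", "F"):
        for age in range(start, terminal + 1):
            rows.append({"age": age, "sex": sex,
                         "qx": 1.0 if age == terminal else qx_const})
    return LifeTable(pd.DataFrame(rows))


class TestFitParametric:
    def test_exponential_closed_form(self):
        # 10 deaths at 1y plus censoring adding to 100 person-years:
        # MLE rate 0.1, log-likelihood 10 ln(0.1) - 10
        times = np.concatenate([np.ones(10), np.full(90, 1.0)])
        events = np.concatenate([np.ones(10, int), np.zeros(90, int)])
        fit = fit_parametric(times, events, "exponential")
        assert 1.0 / fit.params["scale"] == pytest.approx(0.1, rel=1e-4)
        assert fit.log_likelihood == pytest.approx(10 * np.log(0.1) - 10, rel=1e-4)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.log_likelihood)

    def test_weibull_parameter_recovery(self):
        rng = np.random.default_rng(12)
        t = rng.weibull(1.5, size=500) * 5.0
        cens = np.minimum(t, 8.0)
        events = (t <= 8.0).astype(int)
        fit = fit_parametric(cens, events, "weibull")
        assert fit.params["shape"] == pytest.approx(1.5, rel=0.10)
        assert fit.params["scale"] == pytest.approx(5.0, rel=0.10)

    def test_gompertz_recovery_and_exponential_limit(self):
        rng = np.random.default_rng(5)
        a, b = 0.05, 0.4
        u = rng.random(2000)
        t = np.log(1.0 - (b / a) * np.log(u)) / b  # inverse Gompertz CDF
        fit = fit_parametric(t, np.ones_like(t, dtype=int), "gompertz")
        assert fit.params["rate"] == pytest.approx(a, rel=0.15)
        assert fit.params["shape"] == pytest.approx(b, rel=0.25)
        # b -> 0 reduces to the exponential survival function
        flat = SurvivalFit("gompertz", {"rate": 0.1, "shape": 0.0}, 0.0, 1)
        assert flat.sf(3.0) == pytest.approx(np.exp(-0.3))

    def test_requires_at_least_one_event(self):
        with pytest.raises(ValueError):
            fit_parametric([1.0, 2.0], [0, 0], "weibull")

    def test_aic_orders_nested_families_sanely(self):
        rng = np.random.default_rng(30)
        t = rng.exponential(2.0, size=400)
        fits = {f.family: f for f in fit_all_families(t, np.ones_like(t, dtype=int))}
        # Weibull nests the exponential: its AIC exceeds by at most ~2
        assert fits["weibull"].aic <= fits["exponential"].aic + 2.5


class TestSelectModel:
    def test_single_fit_returned(self):
        f = SurvivalFit("exponential", {"scale": 5.0}, -10.0, 3)
        best, report = select_model([f])
        assert best is f

    def test_equal_aic_tie_broken_by_family_order(self):
        f1 = SurvivalFit("weibull", {"scale": 5.0, "shape": 1.0}, -10.0, 3)
        f2 = SurvivalFit("gompertz", {"rate": 0.2, "shape": 0.0}, -10.0, 3)
        best, report = select_model([f2, f1])
        assert best.family == "weibull"  # earlier in the fixed family order
        assert report["tied_best"].sum() == 2

    def test_report_rates_equal_direct_hazard_evaluation(self):
        f = SurvivalFit("exponential", {"scale": 4.0}, -1.0, 2)
        _, report = select_model([f], landmark=0.5)
        for k in range(1, 6):
            expected = 1.0 - np.exp(-0.25)  # constant hazard 1/4 per year
            assert report.loc[0, f"model_rate_year{k}"] == pytest.approx(expected)


class TestProjectSurvival:
    def test_certain_death(self):
        lt = small_lifetable(1.0)
        S = project_survival(70, "M", lt, ProjectionConfig())
        assert np.allclose(S, 0.0)

    def test_no_mortality_until_terminal(self):
        lt = small_lifetable(0.0)
        S = project_survival(70, "F", lt, ProjectionConfig())
        assert np.all(S[:-2] == 1.0)

    def test_constant_hazard_hand_computation(self):
        lt = small_lifetable(0.1)
        S = project_survival(70, "M", lt, ProjectionConfig())
        assert S[:3] == pytest.approx([0.9, 0.81, 0.729])

    def test_row_order_invariance(self):
        lt1 = synthetic_uk_lifetable()
        shuffled = LifeTable(lt1.table.sample(frac=1.0, random_state=1))
        cfg = ProjectionConfig()
        assert np.allclose(project_survival(72, "F", lt1, cfg),
                           project_survival(72, "F", shuffled, cfg))

    def test_age_beyond_table_named_in_error(self):
        lt = small_lifetable(0.1, terminal=80)
        with pytest.raises(KeyError, match="10"):
            project_survival(105, "M", lt, ProjectionConfig())

    def test_smr_accelerates_mortality(self):
        lt = synthetic_uk_lifetable()
        S1 = project_survival(72, "M", lt, ProjectionConfig(smr=1.0))
        S2 = project_survival(72, "M", lt, ProjectionConfig(smr=2.0))
        assert np.all(S2 <= S1 + 1e-12)

    def test_parametric_mode_conditional_ratio(self):
        fit = SurvivalFit("exponential", {"scale": 5.0}, -1.0, 2)
        lt = small_lifetable(0.0, terminal=80)
        cfg = ProjectionConfig(extrapolation_mode="parametric")
        S = project_survival(70, "M", lt, cfg, fit=fit)
        assert S[0] == pytest.approx(np.exp(-1.0 / 5.0))


class TestProjectQaly:
    NORMS = synthetic_utility_norms()

    def test_zero_survival_adds_nothing_without_half_cycle(self):
        cfg = ProjectionConfig(half_cycle_correction=False)
        q = project_qaly(72, "M", 0.35, 0.7, self.NORMS, np.zeros(5), cfg)
        assert q == 0.35

    def test_two_full_cycles_undiscounted(self):
        cfg = ProjectionConfig(discount_rate=0.0, qol_mode="frozen_6m")
        q = project_qaly(72, "M", 0.0, 1.0, self.NORMS, np.ones(2), cfg)
        assert q == pytest.approx(2.0)

    def test_half_cycle_value_on_immediate_death(self):
        cfg = ProjectionConfig(discount_rate=0.0, qol_mode="frozen_6m")
        q = project_qaly(72, "M", 0.0, 1.0, self.NORMS, np.zeros(3), cfg)
        assert q == pytest.approx(0.5)

    def test_discounting_strictly_reduces(self):
        S = project_survival(72, "M", synthetic_uk_lifetable(), ProjectionConfig())
        q0 = project_qaly(72, "M", 0.35, 0.7, self.NORMS, S, ProjectionConfig(discount_rate=0.0))
        q35 = project_qaly(72, "M", 0.35, 0.7, self.NORMS, S, ProjectionConfig(discount_rate=0.035))
        assert q35 < q0

    def test_norms_equal_to_u6m_make_modes_identical(self):
        flat = UtilityNorms(pd.DataFrame({"age": np.arange(50, 101), "utility": 0.7}))
        S = np.full(10, 0.9) ** np.arange(1, 11)
        qa = project_qaly(72, "M", 0.3, 0.7, flat, S, ProjectionConfig())
        qb = project_qaly(72, "M", 0.3, 0.7, flat, S,
                          ProjectionConfig(qol_mode="frozen_6m"))
        assert qa == pytest.approx(qb)

    def test_fine_grid_integration_oracle(self):
        lt = synthetic_uk_lifetable()
        cfg = ProjectionConfig()
        S = project_survival(72, "F", lt, cfg)
        q = project_qaly(72, "F", 0.0, 0.75, self.NORMS, S, cfg)
        # continuous-time oracle on the piecewise curves
        from periopcea.lifetime import _utility_at
        knots_t = cfg.landmark + np.arange(0, len(S) + 1) * cfg.cycle_years
        knots_S = np.concatenate([[1.0], S])
        grid = np.linspace(knots_t[0], knots_t[-1], 200_001)
        Sg = np.interp(grid, knots_t, knots_S)
        ug = np.array([_utility_at(t, 72, 0.75, self.NORMS, cfg) for t in grid])
        dg = (1 + cfg.discount_rate) ** (-(grid - cfg.landmark))
        oracle = np.trapezoid(Sg * ug * dg, grid)
        assert q == pytest.approx(oracle, rel=0.02)


class TestLifetimeCEA:
    def test_degenerate_horizon_reproduces_sixmonth(self, complete_trial):
        est6, completed = sixmonth_cea(complete_trial, m=2, seed=0)
        cfg = ProjectionConfig(smr=1e9, half_cycle_correction=False)
        est_lt, curve, _ = lifetime_cea(complete_trial, cfg=cfg, completed=completed)
        assert est_lt.delta_cost == pytest.approx(est6.delta_cost)
        assert est_lt.delta_qaly == pytest.approx(est6.delta_qaly)

    def test_lifetime_qalys_exceed_sixmonth_for_survivors(self, complete_trial):
        _, completed = sixmonth_cea(complete_trial, m=2, seed=0)
        aug = add_lifetime_qalys(completed[0], synthetic_uk_lifetable(),
                                 synthetic_utility_norms(), ProjectionConfig())
        alive = aug["death_time_days"].isna()
        assert (aug.loc[alive, "qaly_lifetime"] > aug.loc[alive, "qaly_6m"]).all()
        assert np.allclose(aug.loc[~alive, "qaly_lifetime"], aug.loc[~alive, "qaly_6m"])

    def test_parametric_mode_runs_and_differs(self, complete_trial):
        _, completed = sixmonth_cea(complete_trial, m=2, seed=0)
        base, _, _ = lifetime_cea(complete_trial, completed=completed)
        par, _, report = lifetime_cea(complete_trial,
                                      cfg=ProjectionConfig(extrapolation_mode="parametric"),
                                      completed=completed)
        assert report is not None and set(report["family"]) <= set(FAMILIES)
        assert par.delta_qaly != pytest.approx(base.delta_qaly, abs=1e-9)
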