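"""End-to-end orchestration: run the whole evaluation and write its report bundle.

``run_all`` chains simulation (or a user-supplied trial CSV) through QALY
construction, costing, the 6-month bivariate analysis, subgroups, lifetime
extrapolation, value of information and the six pre-specified sensitivity
scenarios, writing CSV/JSON outputs.  All randomness flows from one master
seed through named substreams (simulation, imputation, bootstrap), so re-runs
with the same configuration reproduce every number exactly, and all scenarios
share the same imputations so differences isolate the toggled assumption.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

import periopcea
from periopcea.cea import CEEstimate, ceac, inb, sixmonth_cea, subgroup_cea, utilities_to_index
from periopcea.costing import UnitCostTable, cost_table
from periopcea.eq5d import ValueSet, load_value_set, uk_value_set, qaly_table
from periopcea.lifetime import (LifeTable, ProjectionConfig, UtilityNorms, lifetime_cea,
                                synthetic_uk_lifetable, synthetic_utility_norms)
from periopcea.synthetic import TrialDesign, design_from_dict, generate_trial
from periopcea.voi import evpi

logger = logging.getLogger(__name__)

SENSITIVITY_KEYS = ("s1", "s2", "s3", "s4", "s5", "s6")


@dataclass
class AnalysisConfig:
    trial_path: Optional[str] = None  # None -> simulate from `design`
    design: TrialDesign = field(default_factory=TrialDesign)
    value_set_path: Optional[str] = None
    unit_costs_path: Optional[str] = None
    lifetable_path: Optional[str] = None
    norms_path: Optional[str] = None
    lam: float = 20000.0
    lambda_grid: tuple[float, float, float] = (0.0, 50000.0, 500.0)
    m_imputations: int = 20
    seed: int = 0
    sensitivity: Sequence[str] = SENSITIVITY_KEYS
    subgroup_factors: Sequence[str] = ("urgency", "surgery_category", "recruitment_timing")
    site_mode: str = "random_intercept"
    cost_source: str = "generated"  # "generated" (simulated totals) or "costing"
    outdir: str = "outputs"

    def validate(self) -> None:
        lo, hi, step = self.lambda_grid
        if not (0 <= lo < hi <= 5e5 and step > 0):
            raise ValueError("lambda_grid must satisfy 0 <= lo < hi <= 5e5, step > 0")
        bad = set(self.sensitivity) - set(SENSITIVITY_KEYS)
        if bad:
            raise ValueError(f"unknown sensitivity toggles: {sorted(bad)}")
        for p in (self.trial_path, self.value_set_path, self.unit_costs_path,
                  self.lifetable_path, self.norms_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def arm_summary(trial: pd.DataFrame, qalys: pd.Series, costs: pd.Series) -> pd.DataFrame:
    """Arm-level analogue of the trial's outcome tables: mortality, EQ-5D for
    survivors, QALYs and costs as mean (SD) or n (%)."""
    df = utilities_to_index(trial)
    df = df.assign(qaly_6m=qalys.to_numpy(), total_cost=costs.to_numpy())
    rows = []
    for arm, g in df.groupby("arm"):
        died = g["death_time_days"].notna()
        surv = ~died
        rows.append({
            "arm": arm,
            "n": len(g),
            "deaths_6m": int(died.sum()),
            "mortality_6m_pct": 100.0 * died.mean(),
            "eq5d_30d_survivors_mean": g.loc[surv, "eq5d_30d"].mean(),
            "eq5d_30d_survivors_sd": g.loc[surv, "eq5d_30d"].std(),
            "eq5d_6m_survivors_mean": g.loc[surv, "eq5d_6m"].mean(),
            "eq5d_6m_survivors_sd": g.loc[surv, "eq5d_6m"].std(),
            "qaly_6m_mean": g["qaly_6m"].mean(),
            "qaly_6m_sd": g["qaly_6m"].std(),
            "cost_mean_gbp": g["total_cost"].mean(),
            "cost_sd_gbp": g["total_cost"].std(),
            "ward_days_mean": g["ward_days"].mean(),
            "cc_level2_days_mean": g["cc_level2_days"].mean(),
            "cc_level3_days_mean": g["cc_level3_days"].mean(),
            "monitor_used_pct": 100.0 * g["monitor_used"].mean(),
        })
    return pd.DataFrame(rows)


def _est_row(label: str, est: CEEstimate, lam: float) -> dict:
    mean, se, (lo, hi) = inb(est, lam)
    return {"analysis": label,
            "delta_cost_gbp": round(est.delta_cost),
            "delta_qaly": round(est.delta_qaly, 3),
            "inb_gbp": round(mean), "inb_se_gbp": round(se),
            "inb_ci_low_gbp": round(lo), "inb_ci_high_gbp": round(hi)}


def _resolve_inputs(cfg: AnalysisConfig):
    vs = load_value_set(cfg.value_set_path) if cfg.value_set_path else uk_value_set()
    uc = UnitCostTable.from_yaml(cfg.unit_costs_path) if cfg.unit_costs_path else UnitCostTable.default()
    lt = LifeTable.from_csv(cfg.lifetable_path) if cfg.lifetable_path else synthetic_uk_lifetable()
    norms = UtilityNorms.from_csv(cfg.norms_path) if cfg.norms_path else synthetic_utility_norms()
    return vs, uc, lt, norms


def run_all(cfg: AnalysisConfig) -> dict:
    """Run the full evaluation; write the report bundle; return the key results.

    Any stage failure aborts with the stage name and cause.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    seed_sim, seed_imp, seed_boot = (int(s.generate_state(1)[0] % 2 ** 31) for s in seeds)
    grid = np.arange(cfg.lambda_grid[0], cfg.lambda_grid[1] + cfg.lambda_grid[2] / 2,
                     cfg.lambda_grid[2])
    results: dict = {}
    stage = "setup"
    try:
        vs, uc, lt, norms = _resolve_inputs(cfg)

        stage = "trial data"
        if cfg.trial_path:
            trial = pd.read_csv(cfg.trial_path)
        else:
            design = cfg.design
            design.seed = seed_sim
            trial = generate_trial(design)
        trial = utilities_to_index(trial, vs)

        stage = "costing"
        costs = cost_table(trial, uc)
        if cfg.cost_source == "costing" or "total_cost_gbp" not in trial.columns:
            trial = trial.assign(total_cost_gbp=costs["total"].to_numpy())
        costs.to_csv(outdir / "costs.csv", index=False)

        stage = "six-month analysis"
        est6, completed = sixmonth_cea(trial, m=cfg.m_imputations, seed=seed_imp,
                                       site_mode=cfg.site_mode)
        qalys = completed[0]["qaly_6m"]
        arm_summary(trial, qalys, trial["total_cost_gbp"]).to_csv(
            outdir / "arm_summary.csv", index=False)
        curve6 = ceac(est6, grid)
        curve6.to_frame().to_csv(outdir / "ceac_6m.csv", index=False)
        results["sixmonth"] = est6

        stage = "subgroups"
        sub_rows = []
        for factor in cfg.subgroup_factors:
            for level, est in subgroup_cea(trial, factor, completed=completed,
                                           site_mode=cfg.site_mode).items():
                row = _est_row(f"{factor}={level}", est, cfg.lam)
                sub_rows.append(row)
        pd.DataFrame(sub_rows).to_csv(outdir / "subgroup_table.csv", index=False)

        stage = "lifetime analysis"
        est_lt, curve_lt, model_report = lifetime_cea(
            trial, lt, norms, ProjectionConfig(), completed=completed,
            site_mode=cfg.site_mode, lambdas=grid)
        curve_lt.to_frame().to_csv(outdir / "ceac_lifetime.csv", index=False)
        if model_report is not None:
            model_report.to_csv(outdir / "model_comparison.csv", index=False)
        results["lifetime"] = est_lt

        stage = "value of information"
        mean_lt, se_lt, _ = inb(est_lt, cfg.lam)
        voi = evpi(mean_lt, inb_sd=se_lt, lam=cfg.lam, population=270503)
        with open(outdir / "evpi.json", "w") as fh:
            json.dump(voi.to_dict(), fh, indent=2)
        results["evpi"] = voi

        stage = "sensitivity analyses"
        sens_rows = [_est_row("base_case_6m", est6, cfg.lam),
                     _est_row("base_case_lifetime", est_lt, cfg.lam)]
        for key in cfg.sensitivity:
            est_s = _run_sensitivity(key, trial, completed, uc, lt, norms, cfg, grid)
            sens_rows.append(_est_row(key, est_s, cfg.lam))
            results[key] = est_s
        pd.DataFrame(sens_rows).to_csv(outdir / "sensitivity_table.csv", index=False)

        stage = "estimates"
        mean6, se6, ci6 = inb(est6, cfg.lam)
        payload = {
            "sixmonth": {"delta_cost": est6.delta_cost, "delta_qaly": est6.delta_qaly,
                         "cov": est6.cov.tolist(), "inb": mean6, "inb_ci": ci6},
            "lifetime": {"delta_cost": est_lt.delta_cost, "delta_qaly": est_lt.delta_qaly,
                         "cov": est_lt.cov.tolist(), "inb": mean_lt,
                         "inb_ci": inb(est_lt, cfg.lam)[2]},
            "lambda": cfg.lam,
        }
        with open(outdir / "ce_estimate.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({"version": periopcea.__version__, "master_seed": cfg.seed,
                       "substream_seeds": {"simulate": seed_sim, "impute": seed_imp,
                                           "bootstrap": seed_boot},
                       "m_imputations": cfg.m_imputations, "site_mode": cfg.site_mode},
                      fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return results


def _run_sensitivity(key: str, trial: pd.DataFrame, completed, uc, lt, norms,
                     cfg: AnalysisConfig, grid) -> CEEstimate:
    """One lifetime-scale sensitivity scenario, sharing the base imputations."""
    pcfg = ProjectionConfig()
    if key in ("s1", "s2"):
        addons = cost_table(trial, uc, [key])["sensitivity_addons"].to_numpy()
        shifted = [t.assign(total_cost_gbp=t["total_cost_gbp"].to_numpy() + addons)
                   for t in _unique(completed)]
        est, _, _ = lifetime_cea(trial, lt, norms, pcfg, completed=shifted,
                                 site_mode=cfg.site_mode, lambdas=grid)
        return est
    if key in ("s3", "s4"):
        baseline = "randomisation_anchor" if key == "s3" else "day30_anchor"
        decedent = "interpolate_to_death" if key == "s4" else "zero_at_timepoints"
        redone = []
        for t in _unique(completed):
            t = t.copy()
            t["qaly_6m"] = qaly_table(t, None, baseline, decedent)
            redone.append(t)
        est, _, _ = lifetime_cea(trial, lt, norms, pcfg, completed=redone,
                                 site_mode=cfg.site_mode, lambdas=grid)
        return est
    if key == "s5":
        pcfg.qol_mode = "frozen_6m"
    elif key == "s6":
        pcfg.extrapolation_mode = "parametric"
    est, _, _ = lifetime_cea(trial, lt, norms, pcfg, completed=completed,
                             site_mode=cfg.site_mode, lambdas=grid)
    return est


def _unique(tables):
    seen, out = set(), []
    for t in tables:
        if id(t) not in seen:
            seen.add(id(t))
            out.append(t)
    return out


def design_from_yaml(path) -> TrialDesign:
    import yaml
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh) or {})
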