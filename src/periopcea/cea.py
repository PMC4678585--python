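"""Six-month cost-effectiveness analysis: imputation, bivariate regression,
net monetary benefit, acceptability curves and subgroups.

The estimand is the joint incremental effect of the intervention on 6-month
costs and QALYs.  Costs and QALYs are regressed on the same covariate list
(age, sex, urgency, surgical procedure, post-operative location, ASA grade,
renal impairment, diabetes, cardio-respiratory risk and the randomisation
EQ-5D score) with a random intercept for site.  With identical regressors the
seemingly-unrelated-regression point estimates coincide with per-equation
least squares; the cross-equation covariance of the two treatment
coefficients is recovered from the residual cross-correlation,
``cov = r * se_cost * se_qaly``.

Missing EQ-5D observations are completed by chained-equation multiple
imputation under the missing-at-random assumption, and per-imputation
estimates are combined by Rubin's rules: the pooled point estimate is the
mean, and the total covariance is the mean within-imputation covariance plus
``(1 + 1/m)`` times the between-imputation covariance.

Incremental net monetary benefit at willingness-to-pay ``λ`` is
``INB(λ) = λ·ΔQALY − ΔCost`` with variance
``λ²·var(ΔQALY) + var(ΔCost) − 2λ·cov``; the cost-effectiveness acceptability
curve reports ``P(INB(λ) > 0)`` over a grid of thresholds, by default under a
bivariate-normal approximation (``Φ(mean/SE)``), with a within-site patient
bootstrap available as a skew check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from periopcea.eq5d import ValueSet, qaly_table, to_index

DEFAULT_COVARIATES = ("age", "sex", "urgency", "surgery_category", "postop_location",
                      "asa_grade", "renal_impairment", "diabetes", "cardioresp_risk",
                      "eq5d_random")
_CATEGORICAL = {"sex", "urgency", "surgery_category", "postop_location", "asa_grade"}
_EQ5D_COLS = ("eq5d_random", "eq5d_30d", "eq5d_6m")
UTILITY_FLOOR = -0.594


@dataclass
class CEEstimate:
    """Joint estimate of (incremental cost, incremental QALY) with 2x2 covariance."""

    delta_cost: float
    delta_qaly: float
    cov: np.ndarray  # order: (cost, qaly)
    n_imputations: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2):
            raise ValueError("cov must be 2x2")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-8 * max(1.0, np.trace(self.cov))):
            raise ValueError("cov must be positive semi-definite")

    @property
    def correlation(self) -> float:
        denom = np.sqrt(self.cov[0, 0] * self.cov[1, 1])
        return float(self.cov[0, 1] / denom) if denom > 0 else 0.0


@dataclass
class CEAC:
    lambdas: np.ndarray
    prob_ce: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.prob_ce = np.asarray(self.prob_ce, dtype=float)
        if np.any((self.prob_ce < 0) | (self.prob_ce > 1)):
            raise ValueError("CEAC probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "prob_cost_effective": self.prob_ce})


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def utilities_to_index(trial: pd.DataFrame, vs: Optional[ValueSet] = None) -> pd.DataFrame:
    """Copy of the trial table with EQ-5D columns coerced to utility-index floats."""
    out = trial.copy()
    for col in _EQ5D_COLS:
        if col in out.columns and not pd.api.types.is_float_dtype(out[col]):
            out[col] = [to_index(v, vs) for v in out[col]]
    return out


def impute(trial: pd.DataFrame, m: int = 20, seed: int = 0,
           vs: Optional[ValueSet] = None) -> list[pd.DataFrame]:
    """Chained-equation multiple imputation of missing EQ-5D indices.

    Predictors: arm, covariates, total cost and the observed utilities.
    Utilities structurally absent because of death are *not* imputed (the QALY
    rules assign them zero); only survivor-missing values are completed.
    Imputed utilities are clipped to the tariff range.  Per-imputation seeds
    are derived from the master seed, so results are reproducible.

    A table with no missing values returns ``m`` identical copies.
    """
    if m < 2:
        raise ValueError("m must be >= 2 for multiple imputation")
    df = utilities_to_index(trial, vs)

    dead30 = df["death_time_days"].notna() & (df["death_time_days"] <= 30.4375)
    dead6m = df["death_time_days"].notna()
    needs = {
        "eq5d_random": df["eq5d_random"].isna(),
        "eq5d_30d": df["eq5d_30d"].isna() & ~dead30,
        "eq5d_6m": df["eq5d_6m"].isna() & ~dead6m,
    }
    for col, mask in needs.items():
        alive = {"eq5d_random": np.ones(len(df), bool), "eq5d_30d": ~dead30, "eq5d_6m": ~dead6m}[col]
        if alive.sum() > 0 and df.loc[alive, col].isna().all():
            raise ValueError(f"{col} is missing for every patient at risk; cannot impute")

    if not any(mask.any() for mask in needs.values()):
        return [df.copy() for _ in range(m)]

    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    # numeric predictor matrix
    X = pd.DataFrame(index=df.index)
    X["arm01"] = (df["arm"] == "intervention").astype(float)
    X["age"] = df["age"].astype(float)
    X["male"] = (df["sex"] == "M").astype(float)
    X["non_elective"] = (df["urgency"] == "non_elective").astype(float)
    X["asa"] = df["asa_grade"].astype(float)
    for b in ("renal_impairment", "diabetes", "cardioresp_risk"):
        X[b] = df[b].astype(float)
    if "total_cost_gbp" in df.columns:
        X["cost"] = df["total_cost_gbp"].astype(float)
    for col in _EQ5D_COLS:
        X[col] = df[col].astype(float)
        X.loc[~needs[col] & df[col].isna(), col] = 0.0  # structural (death) NaNs: placeholder

    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(seed).spawn(m)]
    completed: list[pd.DataFrame] = []
    for sd in seeds:
        imp = IterativeImputer(sample_posterior=True, random_state=sd, max_iter=10,
                               skip_complete=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = pd.DataFrame(imp.fit_transform(X), index=X.index, columns=X.columns)
        out = df.copy()
        for col in _EQ5D_COLS:
            vals = filled[col].clip(UTILITY_FLOOR, 1.0)
            out.loc[needs[col], col] = vals[needs[col]]
        completed.append(out)
    return completed


# ---------------------------------------------------------------------------
# bivariate regression
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["arm01"] = (df["arm"] == "intervention").astype(float)
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in table")
        if cov in _CATEGORICAL:
            dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = df[cov].astype(float)
    # drop constant columns (e.g. a subgroup where urgency does not vary)
    keep = [c for c in X.columns if c in ("intercept", "arm01") or X[c].nunique() > 1]
    X = X[keep]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify collinear columns by QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j] if j < r.shape[0] else 0) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    return X


def _fit_one(y: np.ndarray, X: pd.DataFrame, groups, site_mode: str):
    """Arm coefficient, its SE, and level-1 residuals for one outcome."""
    if site_mode == "random_intercept":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            try:
                res = model.fit(reml=True, method="lbfgs")
            except Exception:
                res = model.fit(reml=True)
        j = list(X.columns).index("arm01")
        beta = float(res.fe_params.iloc[j])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se = float(res.bse_fe.iloc[j])
        if not np.isfinite(se):
            # site variance estimated on the zero boundary; absorb sites as
            # fixed intercepts instead
            return _fit_one(y, X, groups, "_fixed_ols")
        # marginal residuals; robust to a site variance estimated at zero
        resid = np.asarray(y) - X.to_numpy() @ np.asarray(res.fe_params)
        return beta, se, resid
    if site_mode in ("fixed", "none", "_fixed_ols"):
        Xf = X.copy()
        if site_mode in ("fixed", "_fixed_ols"):
            dummies = pd.get_dummies(pd.Series(groups, index=X.index).astype(str),
                                     prefix="site", drop_first=True, dtype=float)
            Xf = pd.concat([Xf, dummies], axis=1)
        ols = sm.OLS(y, Xf)
        if site_mode == "fixed":
            res = ols.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
        else:
            res = ols.fit()
        j = list(Xf.columns).index("arm01")
        return float(res.params.iloc[j]), float(res.bse.iloc[j]), np.asarray(res.resid)
    raise ValueError(f"unknown site_mode {site_mode!r}")


def fit_bivariate(completed: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES,
                  site_mode: str = "random_intercept", cost_col: str = "total_cost_gbp",
                  qaly_col: str = "qaly_6m", label: str = "") -> CEEstimate:
    """Treatment effects on cost and QALY from one completed dataset.

    Both equations share the same regressors, so the point estimates equal
    per-equation least squares and the cross-equation covariance of the two
    treatment coefficients is ``r_resid * se_cost * se_qaly``.
    """
    for col in (cost_col, qaly_col):
        if col not in completed.columns or completed[col].isna().any():
            raise ValueError(f"outcome column {col!r} missing or incomplete")
    covariates = [c for c in covariates if c in completed.columns]
    X = _design_matrix(completed, covariates)
    groups = completed["site_id"].to_numpy()
    b_c, se_c, r_c = _fit_one(completed[cost_col].to_numpy(float), X, groups, site_mode)
    b_q, se_q, r_q = _fit_one(completed[qaly_col].to_numpy(float), X, groups, site_mode)
    r = float(np.corrcoef(r_c, r_q)[0, 1]) if np.std(r_c) > 0 and np.std(r_q) > 0 else 0.0
    cov = np.array([[se_c ** 2, r * se_c * se_q], [r * se_c * se_q, se_q ** 2]])
    return CEEstimate(b_c, b_q, cov, n_imputations=1, label=label)


def pool(estimates: Sequence[CEEstimate], label: str = "") -> CEEstimate:
    """Rubin's rules across imputations, element-wise on the 2x2 covariance."""
    if len(estimates) < 1:
        raise ValueError("no estimates to pool")
    m = len(estimates)
    points = np.array([[e.delta_cost, e.delta_qaly] for e in estimates])
    mean = points.mean(axis=0)
    within = np.mean([e.cov for e in estimates], axis=0)
    if m == 1:
        total = within
    else:
        centred = points - mean
        between = centred.T @ centred / (m - 1)
        total = within + (1.0 + 1.0 / m) * between
    return CEEstimate(float(mean[0]), float(mean[1]), total, n_imputations=m, label=label)


# ---------------------------------------------------------------------------
# decision measures
# ---------------------------------------------------------------------------

def inb(est: CEEstimate, lam: float = 20000.0) -> tuple[float, float, tuple[float, float]]:
    """Incremental net monetary benefit at threshold ``lam``: (mean, SE, 95% CI)."""
    if lam < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    mean = lam * est.delta_qaly - est.delta_cost
    var = (lam ** 2 * est.cov[1, 1] + est.cov[0, 0] - 2.0 * lam * est.cov[0, 1])
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    return float(mean), se, (float(mean - z * se), float(mean + z * se))


def ceac(est: CEEstimate, lambdas: Sequence[float] | None = None) -> CEAC:
    """P(cost-effective) over a threshold grid under the normal approximation."""
    if lambdas is None:
        lambdas = np.arange(0.0, 50001.0, 500.0)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0):
        raise ValueError("lambda grid must be non-negative")
    means = lambdas * est.delta_qaly - est.delta_cost
    var = lambdas ** 2 * est.cov[1, 1] + est.cov[0, 0] - 2.0 * lambdas * est.cov[0, 1]
    se = np.sqrt(np.maximum(var, 0.0))
    prob = np.empty_like(means)
    ok = se > 0
    prob[ok] = stats.norm.cdf(means[ok] / se[ok])
    prob[~ok] = (means[~ok] > 0).astype(float)
    if np.any(~ok):
        warnings.warn("zero INB variance on part of the grid; returning a 0/1 step there")
    return CEAC(lambdas, prob)


def ceac_monte_carlo(est: CEEstimate, lambdas: Sequence[float], n_draws: int = 100_000,
                     seed: int = 0) -> CEAC:
    """Monte-Carlo CEAC from the fitted bivariate-normal (sampling oracle for the
    closed form; also usable directly)."""
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal([est.delta_cost, est.delta_qaly], est.cov, size=n_draws)
    lambdas = np.asarray(lambdas, dtype=float)
    inb_draws = draws[:, 1][None, :] * lambdas[:, None] - draws[:, 0][None, :]
    return CEAC(lambdas, (inb_draws > 0).mean(axis=1))


def bootstrap_ceac(trial: pd.DataFrame, lambdas: Sequence[float], n_boot: int = 200,
                   seed: int = 0, **fit_kwargs) -> CEAC:
    """Nonparametric CEAC: resample patients within site, refit, count INB > 0."""
    rng = np.random.default_rng(seed)
    lambdas = np.asarray(lambdas, dtype=float)
    wins = np.zeros(len(lambdas))
    groups = [g for _, g in trial.groupby("site_id")]
    done = 0
    for _ in range(n_boot):
        parts = [g.iloc[rng.integers(0, len(g), size=len(g))] for g in groups]
        boot = pd.concat(parts, ignore_index=True)
        try:
            est = fit_bivariate(boot, **fit_kwargs)
        except Exception:
            continue
        wins += (lambdas * est.delta_qaly - est.delta_cost) > 0
        done += 1
    if done == 0:
        raise RuntimeError("all bootstrap refits failed")
    return CEAC(lambdas, wins / done)


# ---------------------------------------------------------------------------
# pipeline and subgroups
# ---------------------------------------------------------------------------

def _complete_with_qalys(tables: list[pd.DataFrame], baseline_rule: str,
                         decedent_rule: str) -> list[pd.DataFrame]:
    out = []
    for t in tables:
        t = t.copy()
        t["qaly_6m"] = qaly_table(t, None, baseline_rule, decedent_rule)
        out.append(t)
    return out


def sixmonth_cea(trial: pd.DataFrame, m: int = 20, seed: int = 0,
                 vs: Optional[ValueSet] = None,
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 site_mode: str = "random_intercept",
                 baseline_rule: str = "day30_anchor",
                 decedent_rule: str = "zero_at_timepoints",
                 cost_col: str = "total_cost_gbp",
                 label: str = "6m") -> tuple[CEEstimate, list[pd.DataFrame]]:
    """Impute → QALY construction → bivariate fit → Rubin pooling.

    Returns the pooled estimate and the completed tables (with ``qaly_6m``),
    which downstream stages (lifetime extrapolation, subgroups) reuse so the
    same imputations underlie every scenario.

    With no missing utilities the ``m`` chained-equation copies are identical,
    so pooling reduces exactly to the single complete-data fit; that shortcut
    is taken to avoid redundant refits.
    """
    df = utilities_to_index(trial, vs)
    has_missing = _any_survivor_missing(df)
    if has_missing:
        tables = impute(df, m=m, seed=seed)
    else:
        tables = [df]
    tables = _complete_with_qalys(tables, baseline_rule, decedent_rule)
    fits = [fit_bivariate(t, covariates, site_mode, cost_col=cost_col) for t in tables]
    pooled = pool(fits, label=label)
    if not has_missing:
        pooled.n_imputations = m
        tables = tables * m if m > 1 else tables
    return pooled, tables


def _any_survivor_missing(df: pd.DataFrame) -> bool:
    dead30 = df["death_time_days"].notna() & (df["death_time_days"] <= 30.4375)
    dead6m = df["death_time_days"].notna()
    return bool(df["eq5d_random"].isna().any()
                or (df["eq5d_30d"].isna() & ~dead30).any()
                or (df["eq5d_6m"].isna() & ~dead6m).any())


def subgroup_cea(trial: pd.DataFrame, factor: str, m: int = 20, seed: int = 0,
                 vs: Optional[ValueSet] = None, completed: Optional[list[pd.DataFrame]] = None,
                 **fit_kwargs) -> dict[str, CEEstimate]:
    """Pre-specified subgroup analyses.

    ``factor`` is ``urgency``, ``surgery_category`` or ``recruitment_timing``
    (the latter splits on the first ten patients recruited at each site versus
    all subsequent patients).  Imputation is performed once on the full table
    and subgroups are subset from the completed datasets, so every level
    shares the same imputations.  Levels with fewer than 2 patients per arm
    are skipped with a warning.
    """
    if factor not in ("urgency", "surgery_category", "recruitment_timing"):
        raise ValueError(f"unknown subgroup factor {factor!r}")
    if completed is None:
        _, completed = sixmonth_cea(trial, m=m, seed=seed, vs=vs, **fit_kwargs)
    base = completed[0]
    if factor == "recruitment_timing":
        levels = {"first_10_per_site": base["recruitment_order_in_site"] <= 10,
                  "after_first_10": base["recruitment_order_in_site"] > 10}
    else:
        levels = {str(v): base[factor] == v for v in sorted(base[factor].unique())}

    fit_keys = {k: v for k, v in fit_kwargs.items()
                if k in ("covariates", "site_mode", "cost_col")}
    # subgroup models drop the factor itself from the covariate list
    covs = list(fit_keys.get("covariates", DEFAULT_COVARIATES))
    if factor in covs:
        covs.remove(factor)
    fit_keys["covariates"] = covs

    out: dict[str, CEEstimate] = {}
    for name, mask in levels.items():
        counts = base.loc[mask, "arm"].value_counts()
        if mask.sum() == 0 or counts.min() < 2 or len(counts) < 2:
            warnings.warn(f"subgroup {factor}={name}: fewer than 2 patients per arm; skipped")
            continue
        # completed tables may be the same object repeated (complete-data case);
        # fit each distinct table once
        cache: dict[int, CEEstimate] = {}
        fits = []
        for t in completed:
            key = id(t)
            if key not in cache:
                cache[key] = fit_bivariate(t.loc[mask], label=name, **fit_keys)
            fits.append(cache[key])
        out[name] = pool(fits, label=f"{factor}={name}")
    return out
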