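"""EQ-5D-3L scoring and QALY construction by the area-under-the-curve method.

An EQ-5D-3L health profile records five dimensions (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression) each at level 1 (no problems),
2 (some problems) or 3 (extreme problems).  A country value set converts a
profile into a utility index anchored at 1 (full health) and 0 (dead); states
worse than dead are negative.  The bundled UK tariff is the general-population
time-trade-off value set (MVH study); its worst state 33333 scores -0.594.

Per-patient QALYs over the 6-month trial window are the trapezoidal area under
the utility-time curve with assessments at randomisation, 30 days and 6 months.
The base case anchors the curve at the day-30 index (the randomisation score
reflects the acute surgical episode and enters the regression as a covariate
instead); patients who die between assessments contribute zero utility at
every post-death time point, or, under the decedent-interpolation sensitivity
rule, decline linearly from the last observed value to zero at the death date.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25
T_30D_YEARS = DAYS_PER_MONTH / DAYS_PER_YEAR  # exactly 1/12
T_6M_YEARS = 0.5
SIX_MONTHS_DAYS = 182.625

_DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")
_TERM_PREFIX = {"mobility": "MO", "self_care": "SC", "usual_activities": "UA",
                "pain_discomfort": "PD", "anxiety_depression": "AD"}


@dataclass(frozen=True)
class EQ5DProfile:
    """One EQ-5D-3L health state, e.g. ``EQ5DProfile.from_string("21123")``."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in _DIMENSIONS:
            lvl = getattr(self, dim)
            if lvl not in (1, 2, 3):
                raise ValueError(f"EQ-5D-3L level for {dim} must be 1, 2 or 3; got {lvl!r}")

    @classmethod
    def from_string(cls, s: str) -> "EQ5DProfile":
        s = str(s).strip()
        if len(s) != 5 or not s.isdigit():
            raise ValueError(f"EQ-5D-3L profile must be a 5-digit string; got {s!r}")
        return cls(*(int(c) for c in s))

    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, d) for d in _DIMENSIONS)

    def __str__(self) -> str:
        return "".join(str(l) for l in self.levels())


@dataclass(frozen=True)
class ValueSet:
    """Decrement-based EQ-5D-3L scoring tariff.

    ``index = 1 - constant·1{any level > 1} - Σ level decrements - n3·1{any level = 3}``.

    Coefficients are loaded from a CSV with columns (term, decrement); terms are
    ``constant``, ``MO2``..``AD3`` and ``N3``.  The engine never hard-codes them.
    """

    constant: float
    decrements: dict[str, float]  # keys MO2, MO3, SC2, SC3, UA2, UA3, PD2, PD3, AD2, AD3
    n3: float
    name: str = "custom"

    def index(self, profile: EQ5DProfile | str) -> float:
        if not isinstance(profile, EQ5DProfile):
            profile = EQ5DProfile.from_string(profile)
        levels = profile.levels()
        if all(l == 1 for l in levels):
            return 1.0
        value = 1.0 - self.constant
        for dim, lvl in zip(_DIMENSIONS, levels):
            if lvl > 1:
                value -= self.decrements[f"{_TERM_PREFIX[dim]}{lvl}"]
        if any(l == 3 for l in levels):
            value -= self.n3
        return value

    @property
    def floor(self) -> float:
        """Minimum attainable index over all 243 profiles (worst state)."""
        return min(self.index(EQ5DProfile(*lv)) for lv in itertools.product((1, 2, 3), repeat=5))


def load_value_set(path, name: Optional[str] = None) -> ValueSet:
    """Read a (term, decrement) CSV into a :class:`ValueSet`."""
    tab = pd.read_csv(path)
    missing = {"term", "decrement"} - set(tab.columns)
    if missing:
        raise ValueError(f"value-set CSV missing columns: {sorted(missing)}")
    coef = dict(zip(tab["term"].astype(str), tab["decrement"].astype(float)))
    required = {"constant", "N3"} | {f"{p}{l}" for p in _TERM_PREFIX.values() for l in (2, 3)}
    absent = required - set(coef)
    if absent:
        raise ValueError(f"value-set CSV missing terms: {sorted(absent)}")
    return ValueSet(
        constant=coef["constant"],
        decrements={k: v for k, v in coef.items() if k not in ("constant", "N3")},
        n3=coef["N3"],
        name=name or str(path),
    )


def uk_value_set() -> ValueSet:
    """The bundled UK general-population EQ-5D-3L tariff (MVH time-trade-off)."""
    with resources.as_file(resources.files("periopcea.data") / "uk_eq5d3l_tariff.csv") as p:
        vs = load_value_set(p, name="UK MVH")
    return vs


def to_index(value, vs: Optional[ValueSet] = None) -> float:
    """Coerce a stored EQ-5D observation (profile string or index float) to a float index."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return np.nan
        if len(s) == 5 and s.isdigit() and set(s) <= set("123"):
            if vs is None:
                raise ValueError("profile string supplied but no value set given")
            return vs.index(s)
        return float(s)
    return float(value)


@dataclass
class UtilityTrajectory:
    """Piecewise-linear utility curve over the 6-month window (times in years)."""

    times: Sequence[float]
    utilities: Sequence[float]
    death_time: Optional[float] = None  # years; None = alive at 6 months
    baseline_rule: str = "day30_anchor"
    decedent_rule: str = "zero_at_timepoints"
    missing: bool = field(default=False)  # needs imputation; QALY not computable

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) != len(self.utilities):
            raise ValueError("times and utilities must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")


def qaly_auc(traj: UtilityTrajectory) -> float:
    """Trapezoidal area under the utility-time curve, in QALYs.

    Negative (worse-than-dead) utilities integrate negatively; the result is
    reported, not clipped.
    """
    if traj.missing:
        return np.nan
    t = np.asarray(traj.times, dtype=float)
    u = np.asarray(traj.utilities, dtype=float)
    if len(t) == 0:
        return 0.0
    if len(t) == 1:
        return 0.0
    if np.any(np.isnan(u)):
        return np.nan
    return float(np.trapezoid(u, t))


def build_trajectory(
    rec,
    vs: Optional[ValueSet] = None,
    baseline_rule: str = "day30_anchor",
    decedent_rule: str = "zero_at_timepoints",
) -> UtilityTrajectory:
    """Assemble one patient's utility trajectory from a trial-table row.

    ``rec`` is a mapping (pandas row) with fields ``eq5d_random``, ``eq5d_30d``,
    ``eq5d_6m`` (profile strings or index floats; empty = missing) and
    ``death_time_days`` (NaN if alive at 6 months).

    Base case (``day30_anchor``): the curve starts at the day-30 index value;
    the randomisation score is not part of the AUC.  ``randomisation_anchor``
    starts at the randomisation score instead.  Decedents: under
    ``zero_at_timepoints`` every assessment after death scores 0; under
    ``interpolate_to_death`` utility declines linearly from the last observed
    value to 0 at the death date.

    Missing needed utilities (for a patient alive at that assessment) yield a
    trajectory flagged ``missing=True`` for the imputation stage — never a
    silent substitution.
    """
    if baseline_rule not in ("day30_anchor", "randomisation_anchor"):
        raise ValueError(f"unknown baseline_rule {baseline_rule!r}")
    if decedent_rule not in ("zero_at_timepoints", "interpolate_to_death"):
        raise ValueError(f"unknown decedent_rule {decedent_rule!r}")

    u_rand = to_index(rec.get("eq5d_random"), vs)
    u_30 = to_index(rec.get("eq5d_30d"), vs)
    u_6m = to_index(rec.get("eq5d_6m"), vs)
    death_days = rec.get("death_time_days")
    death_days = float(death_days) if death_days is not None and not pd.isna(death_days) else None
    death_years = death_days / DAYS_PER_YEAR if death_days is not None else None

    died_before_30d = death_days is not None and death_days <= DAYS_PER_MONTH
    died_before_6m = death_days is not None and death_days <= SIX_MONTHS_DAYS

    kw = dict(death_time=death_years, baseline_rule=baseline_rule, decedent_rule=decedent_rule)

    if decedent_rule == "zero_at_timepoints" or death_days is None:
        # assessments after death are zero; alive patients use observed values
        v30 = 0.0 if died_before_30d else u_30
        v6m = 0.0 if died_before_6m else u_6m
        anchor = v30 if baseline_rule == "day30_anchor" else u_rand
        vals = [anchor, v30, v6m]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            return UtilityTrajectory([0.0, T_30D_YEARS, T_6M_YEARS], [np.nan] * 3, missing=True, **kw)
        return UtilityTrajectory([0.0, T_30D_YEARS, T_6M_YEARS], vals, **kw)

    # interpolate_to_death for a decedent: nodes at pre-death assessments, then 0 at death
    if died_before_30d:
        # no day-30 value exists; the interpolation anchors on the randomisation score
        anchor = u_rand
        if np.isnan(anchor):
            return UtilityTrajectory([0.0, death_years], [np.nan, 0.0], missing=True, **kw)
        times = [0.0, death_years]
        vals = [anchor, 0.0]
    else:
        anchor = u_30 if baseline_rule == "day30_anchor" else u_rand
        if np.isnan(anchor) or np.isnan(u_30):
            return UtilityTrajectory([0.0, death_years], [np.nan, 0.0], missing=True, **kw)
        times = [0.0, T_30D_YEARS, death_years]
        vals = [anchor, u_30, 0.0]
    # pad with zeros at remaining assessment times so the horizon is covered
    for t_pad in (T_30D_YEARS, T_6M_YEARS):
        if t_pad > death_years:
            times.append(t_pad)
            vals.append(0.0)
    return UtilityTrajectory(times, vals, **kw)


def qaly_table(
    trial: pd.DataFrame,
    vs: Optional[ValueSet] = None,
    baseline_rule: str = "day30_anchor",
    decedent_rule: str = "zero_at_timepoints",
) -> pd.Series:
    """Per-patient 6-month QALYs for a whole trial table (NaN where utilities are missing)."""
    out = np.empty(len(trial), dtype=float)
    for i, (_, row) in enumerate(trial.iterrows()):
        out[i] = qaly_auc(build_trajectory(row, vs, baseline_rule, decedent_rule))
    return pd.Series(out, index=trial.index, name="qaly_6m")
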