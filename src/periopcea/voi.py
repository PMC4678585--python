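"""Expected value of perfect information (EVPI) under a normal incremental
net monetary benefit.

With INB ~ N(mean, sd²), the expected opportunity loss of deciding now —
adopt if mean > 0, reject otherwise — is the unit-normal loss integral

    EVPI = sd * [phi(z) - z * Phi(-z)],   z = |mean| / sd,

where phi and Phi are the standard-normal density and CDF.  The population
EVPI multiplies the per-patient value by the effective population: the
(discounted) number of future patients whose treatment the decision governs
over the decision horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

Z_95 = 1.959964  # normal 97.5% quantile used for CI <-> SD conversion


def sd_from_ci(lower: float, upper: float) -> float:
    """SD of a normal estimate from its 95% confidence interval."""
    if upper < lower:
        raise ValueError("upper CI bound below lower bound")
    return (upper - lower) / (2.0 * Z_95)


def evpi_per_patient(mean: float, sd: float) -> float:
    """Per-patient EVPI from the normal INB mean and SD (unit-normal loss)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return 0.0
    z = abs(mean) / sd
    return float(sd * (stats.norm.pdf(z) - z * stats.norm.cdf(-z)))


def effective_population(annual_incidence: float, horizon_years: int,
                         discount_rate: float = 0.035) -> float:
    """Discounted patient count over the decision horizon:
    ``sum_{t=1..H} incidence / (1+r)^(t-1)``.

    A directly known total (e.g. from hospital-episode statistics) can be
    passed straight to :func:`population_evpi` instead.
    """
    if annual_incidence < 0 or horizon_years < 0 or discount_rate < 0:
        raise ValueError("all inputs must be >= 0")
    t = np.arange(1, horizon_years + 1)
    return float(np.sum(annual_incidence / (1.0 + discount_rate) ** (t - 1)))


def population_evpi(per_patient: float, population: float) -> float:
    if per_patient < 0 or population < 0:
        raise ValueError("inputs must be >= 0")
    return per_patient * population


@dataclass
class EVPIResult:
    lam: float
    inb_mean: float
    inb_sd: float
    evpi_per_patient: float
    effective_population: float
    population_evpi: float
    horizon_years: int = 5
    discount_rate: float = 0.035

    def to_dict(self) -> dict:
        return asdict(self)


def evpi(inb_mean: float, inb_sd: float | None = None, ci: tuple[float, float] | None = None,
         lam: float = 20000.0, population: float | None = None,
         annual_incidence: float | None = None, horizon_years: int = 5,
         discount_rate: float = 0.035) -> EVPIResult:
    """One-call EVPI: accepts either the INB SD or its 95% CI, and either a
    directly supplied effective population or an annual incidence to discount."""
    if inb_sd is None:
        if ci is None:
            raise ValueError("supply inb_sd or ci")
        inb_sd = sd_from_ci(*ci)
    if population is None:
        if annual_incidence is None:
            raise ValueError("supply population or annual_incidence")
        population = effective_population(annual_incidence, horizon_years, discount_rate)
    per = evpi_per_patient(inb_mean, inb_sd)
    return EVPIResult(lam, inb_mean, inb_sd, per, population, population_evpi(per, population),
                      horizon_years, discount_rate)


def evpi_monte_carlo(mean: float, sd: float, n_draws: int = 1_000_000, seed: int = 0) -> float:
    """Sampling estimate of the expected opportunity loss, for cross-checking
    the closed form: E[max(0, -INB)] if adopting (mean > 0), else E[max(0, INB)]."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, n_draws)
    loss = np.maximum(0.0, -draws) if mean > 0 else np.maximum(0.0, draws)
    return float(loss.mean())
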