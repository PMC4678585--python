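"""Per-patient 6-month NHS cost construction from resource use and unit costs.

National reference costs for a surgical procedure bundle the operation *and*
an average hospital stay.  Because ward and critical-care days are costed
separately from the observed resource use, the stay embedded in the reference
cost would be double counted; the adjusted surgery cost therefore subtracts
the average length of stay (at the ward-day rate) and one post-anaesthetic
recovery day from the national average unit cost.

Two cost-side sensitivity scenarios are supported as options:

* ``s1`` — adds one level-2 critical-care day plus one hour of recovery-nurse
  time for patients not transferred directly to critical care after surgery;
* ``s2`` — adds 4.5 hours of nurse time for every intervention-arm patient
  (the staff time to deliver the haemodynamic algorithm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_SCALAR_RATES = ("ward_day", "cc_level2_day", "cc_level3_day", "recovery_day",
                 "monitor_per_patient", "dopexamine_per_mg", "crystalloid_per_ml",
                 "colloid_per_ml", "blood_per_ml", "nurse_hour")


class UnknownProcedureError(KeyError):
    pass


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs (GBP, one price year) keyed as in the bundled YAML layout."""

    reference_cost: dict[str, float]
    avg_los_days: dict[str, float]
    ward_day: float
    cc_level2_day: float
    cc_level3_day: float
    recovery_day: float
    monitor_per_patient: float
    dopexamine_per_mg: float
    crystalloid_per_ml: float
    colloid_per_ml: float
    blood_per_ml: float
    nurse_hour: float
    price_year: str = "unspecified"

    def __post_init__(self) -> None:
        for name in _SCALAR_RATES:
            if getattr(self, name) < 0:
                raise ValueError(f"unit cost {name} must be >= 0")
        for code, v in self.reference_cost.items():
            if v < 0:
                raise ValueError(f"reference_cost[{code}] must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: raw[k] for k in cls.__dataclass_fields__ if k in raw})

    @classmethod
    def default(cls) -> "UnitCostTable":
        """Bundled synthetic placeholder table (see data/unit_costs_default.yaml)."""
        with resources.as_file(resources.files("periopcea.data") / "unit_costs_default.yaml") as p:
            return cls.from_yaml(p)


@dataclass
class CostBreakdown:
    surgery_adjusted: float
    critical_care: float
    ward: float
    intervention_equipment_drugs: float
    fluids_blood: float
    sensitivity_addons: float = 0.0

    @property
    def total(self) -> float:
        return (self.surgery_adjusted + self.critical_care + self.ward
                + self.intervention_equipment_drugs + self.fluids_blood
                + self.sensitivity_addons)


def adjusted_surgery_cost(code: str, uc: UnitCostTable) -> float:
    """Reference cost net of the embedded average stay and one recovery day.

    Floored at zero (with a warning) if the subtraction overshoots.
    """
    if code not in uc.reference_cost:
        raise UnknownProcedureError(f"no reference cost for procedure code {code!r}")
    value = (uc.reference_cost[code]
             - uc.avg_los_days.get(code, 0.0) * uc.ward_day
             - 1.0 * uc.recovery_day)
    if value < 0 and uc.reference_cost[code] > 0:
        logger.warning("adjusted surgery cost for %s negative (%.2f); floored at 0", code, value)
        return 0.0
    return max(value, 0.0)


def patient_cost(rec, uc: UnitCostTable, sensitivity: Iterable[str] = ()) -> CostBreakdown:
    """Assemble one patient's 6-month cost breakdown.

    ``rec`` is a trial-table row; ``sensitivity`` may contain ``"s1"`` and/or
    ``"s2"`` (see module docstring).  Monitor use is costed per patient
    whenever the monitor was used, in either arm (intention-to-treat costing
    of actual resource use).
    """
    sens = set(sensitivity)
    bad = sens - {"s1", "s2"}
    if bad:
        raise ValueError(f"unknown sensitivity options: {sorted(bad)}")
    quantities = ("cc_level2_days", "cc_level3_days", "ward_days", "dopexamine_mg",
                  "crystalloid_ml_intraop", "crystalloid_ml_postop",
                  "colloid_ml_intraop", "colloid_ml_postop",
                  "blood_ml_intraop", "blood_ml_postop")
    for q in quantities:
        if float(rec[q]) < 0:
            raise ValueError(f"negative resource quantity {q}={rec[q]}")

    critical = (float(rec["cc_level2_days"]) * uc.cc_level2_day
                + float(rec["cc_level3_days"]) * uc.cc_level3_day)
    ward = float(rec["ward_days"]) * uc.ward_day
    equip = (uc.monitor_per_patient if bool(rec["monitor_used"]) else 0.0) \
        + float(rec["dopexamine_mg"]) * uc.dopexamine_per_mg
    fluids = ((float(rec["crystalloid_ml_intraop"]) + float(rec["crystalloid_ml_postop"])) * uc.crystalloid_per_ml
              + (float(rec["colloid_ml_intraop"]) + float(rec["colloid_ml_postop"])) * uc.colloid_per_ml
              + (float(rec["blood_ml_intraop"]) + float(rec["blood_ml_postop"])) * uc.blood_per_ml)

    addons = 0.0
    if "s1" in sens and rec["postop_location"] in ("recovery", "ward"):
        addons += uc.cc_level2_day + 1.0 * uc.nurse_hour
    if "s2" in sens and rec["arm"] == "intervention":
        addons += 4.5 * uc.nurse_hour

    return CostBreakdown(
        surgery_adjusted=adjusted_surgery_cost(str(rec["procedure_code"]), uc),
        critical_care=critical,
        ward=ward,
        intervention_equipment_drugs=equip,
        fluids_blood=fluids,
        sensitivity_addons=addons,
    )


def cost_table(trial: pd.DataFrame, uc: Optional[UnitCostTable] = None,
               sensitivity: Iterable[str] = ()) -> pd.DataFrame:
    """Per-patient cost components and totals for a whole trial table."""
    uc = uc or UnitCostTable.default()
    rows = []
    for _, rec in trial.iterrows():
        b = patient_cost(rec, uc, sensitivity)
        rows.append({"patient_id": rec["patient_id"],
                     "surgery_adjusted": b.surgery_adjusted,
                     "critical_care": b.critical_care,
                     "ward": b.ward,
                     "intervention_equipment_drugs": b.intervention_equipment_drugs,
                     "fluids_blood": b.fluids_blood,
                     "sensitivity_addons": b.sensitivity_addons,
                     "total": b.total})
    return pd.DataFrame(rows, index=trial.index)
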