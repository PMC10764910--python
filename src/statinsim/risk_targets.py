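"""Cardiovascular risk categorisation and LDL-C treatment targets.

Implements the two-category (high / very-high) risk stratification of the
2019 ESC/EAS dyslipidaemia guidelines with the category-specific LDL-C
targets of < 70 and < 55 mg/dL, driven by a configurable rule table over
normalised diagnosis categories with category-specific look-back windows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .config import SelectionConfig
from .emr_model import DiagnosisCategory, PatientRecord
from .errors import ConfigurationError, ValidationError


class RiskCategory(str, Enum):
    high = "high"
    very_high = "very_high"


LDL_TARGETS_MG_DL: dict[RiskCategory, float] = {
    RiskCategory.very_high: 55.0,
    RiskCategory.high: 70.0,
}


@dataclass(frozen=True)
class RiskProfile:
    category: RiskCategory
    ldl_target_mg_dl: float
    qualifying_conditions: tuple[DiagnosisCategory, ...]


@dataclass(frozen=True)
class RiskRules:
    """Configurable mapping from diagnosis categories to the risk decision.

    ``ascvd`` categories (secondary prevention) and ``ckd`` are very-high on
    their own; diabetes is very-high with at least ``diabetes_very_high_min_factors``
    of the ``risk_factors``, otherwise high; ``risk_factors`` alone are high
    only when all of them co-occur (hypertension with current smoking).
    """

    ascvd: tuple[DiagnosisCategory, ...] = (
        DiagnosisCategory.coronary_artery_disease,
        DiagnosisCategory.cerebrovascular_disease,
        DiagnosisCategory.peripheral_artery_disease,
    )
    ckd: DiagnosisCategory = DiagnosisCategory.chronic_kidney_disease
    diabetes: DiagnosisCategory = DiagnosisCategory.diabetes
    risk_factors: tuple[DiagnosisCategory, ...] = (
        DiagnosisCategory.hypertension,
        DiagnosisCategory.smoking,
    )
    diabetes_very_high_min_factors: int = 2

    def to_dict(self) -> dict:
        return {
            "ascvd": [c.value for c in self.ascvd],
            "ckd": self.ckd.value,
            "diabetes": self.diabetes.value,
            "risk_factors": [c.value for c in self.risk_factors],
            "diabetes_very_high_min_factors": self.diabetes_very_high_min_factors,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskRules":
        try:
            return cls(
                ascvd=tuple(DiagnosisCategory(c) for c in d["ascvd"]),
                ckd=DiagnosisCategory(d["ckd"]),
                diabetes=DiagnosisCategory(d["diabetes"]),
                risk_factors=tuple(DiagnosisCategory(c) for c in d["risk_factors"]),
                diabetes_very_high_min_factors=int(d["diabetes_very_high_min_factors"]),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"malformed risk rules: {exc}") from exc


def assign_risk(
    patient: PatientRecord,
    index_date: dt.date,
    config: SelectionConfig,
    rules: RiskRules | None = None,
) -> RiskProfile | None:
    """Assign high / very-high risk at the index date, or ``None`` (excluded).

    Look-backs are category-specific: unrestricted for atherosclerotic
    cardiovascular disease and diabetes, 60 months for chronic kidney
    disease, 12 months for hypertension and current smoking. Patients
    qualifying for neither category fall outside the study population.
    """
    if rules is None:
        rules = RiskRules()

    ckd_start = index_date - dt.timedelta(days=config.ckd_lookback_days)
    rf_start = index_date - dt.timedelta(days=config.risk_lookback_days)

    present: set[DiagnosisCategory] = set()
    for d in patient.diagnoses:
        if d.date > index_date:
            continue
        if d.category == rules.ckd:
            if d.date >= ckd_start:
                present.add(d.category)
        elif d.category in rules.risk_factors:
            if d.date >= rf_start:
                present.add(d.category)
        else:
            present.add(d.category)

    ascvd = [c for c in rules.ascvd if c in present]
    factors = [c for c in rules.risk_factors if c in present]
    has_diabetes = rules.diabetes in present
    has_ckd = rules.ckd in present

    if ascvd:
        qualifying = tuple(ascvd)
        category = RiskCategory.very_high
    elif has_ckd:
        qualifying = (rules.ckd,)
        category = RiskCategory.very_high
    elif has_diabetes and len(factors) >= rules.diabetes_very_high_min_factors:
        qualifying = (rules.diabetes, *factors)
        category = RiskCategory.very_high
    elif has_diabetes:
        qualifying = (rules.diabetes, *factors)
        category = RiskCategory.high
    elif len(factors) == len(rules.risk_factors) and factors:
        qualifying = tuple(factors)
        category = RiskCategory.high
    else:
        return None
    return RiskProfile(
        category=category,
        ldl_target_mg_dl=LDL_TARGETS_MG_DL[category],
        qualifying_conditions=qualifying,
    )


def ldl_target(category: RiskCategory | str) -> float:
    """LDL-C goal in mg/dL: very-high risk → 55, high risk → 70."""
    try:
        return LDL_TARGETS_MG_DL[RiskCategory(category)]
    except ValueError as exc:
        raise ValidationError(f"unknown risk category: {category!r}") from exc


def at_target(ldl_mg_dl: float, category: RiskCategory | str) -> bool:
    """Strict target attainment: LDL-C strictly below the category goal."""
    if ldl_mg_dl <= 0:
        raise ValidationError(f"LDL-C must be positive, got {ldl_mg_dl}")
    return ldl_mg_dl < ldl_target(category)
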