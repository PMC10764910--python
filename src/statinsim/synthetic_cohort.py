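"""Synthetic EMR cohort generator with planted ground truth.

Emulates the statistical structure of a German outpatient hypercholesterolaemia
cohort: per-patient statin/ezetimibe/other lipid-lowering prescription
histories over a three-year look-back, LDL-C sampled per treatment stratum
from log-normal distributions calibrated to target arithmetic moments
(no LLT: mean 152.1 SD 43.5 mg/dL; on LLT: mean 92.1 SD 31.5 mg/dL), a
66.1/33.9 very-high/high risk mix (73.7/26.3 within statin intolerance), the
observed lipid-lowering-therapy mix, and statin-intolerance prescription
patterns planted from the canonical template of one classifier rule each, so
that label recovery is an exact oracle rather than a statistical hope.

Every quantity is drawn from one seeded generator; identical specs and seeds
yield byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .config import SelectionConfig
from .emr_model import (
    DiagnosisCategory,
    DiagnosisEvent,
    DrugClass,
    LabMeasurement,
    PatientRecord,
    PrescriptionEvent,
    Sex,
    write_cohort,
)
from .errors import SpecificationError, ValidationError
from .risk_targets import RiskCategory
from .si_classifier import SICategory

DAY = dt.timedelta(days=1)

#: lipid-lowering-therapy mix of the full cohort (fractions of all patients)
DEFAULT_LLT_MIX: dict[str, float] = {
    "none": 0.193,
    "statin_mono_low": 0.109,
    "statin_mono_moderate": 0.422,
    "statin_mono_high": 0.181,
    "ezetimibe_mono": 0.012,
    "statin_plus_ezetimibe": 0.080,
    "other": 0.003,
}

DEFAULT_LDL_MEAN_SD: dict[str, tuple[float, float]] = {
    "no_llt": (152.1, 43.5),
    "on_llt": (92.1, 31.5),
}

#: decorative diagnosis prevalences that never interact with risk assignment
DEFAULT_DIAGNOSIS_PREVALENCES: dict[str, float] = {
    "liver_disease": 0.0020,
    "gout": 0.0047,
    "hyperuricaemia": 0.0012,
}

ABSOLUTE_TEMPLATES: dict[str, float] = {
    "abs_documented_si": 0.25,
    "abs_sams": 0.20,
    "abs_down_titration": 0.15,
    "abs_statin_switch": 0.10,
    "abs_intermittent_dosing": 0.10,
    "abs_low_dose_latest": 0.20,
}

PARTIAL_TEMPLATES: dict[str, float] = {
    "part_specific_switch_to_low": 0.20,
    "part_down_titration_different": 0.20,
    "part_documented_si": 0.25,
    "part_down_same_with_switch": 0.10,
    "part_low_dose_plus_nonstatin": 0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; defaults reproduce the study population mix."""

    n_patients: int = 1000
    seed: int = 0
    fraction_absolute_si: float = 0.018
    fraction_partial_si: float = 0.068
    risk_very_high_overall: float = 0.661
    risk_very_high_within_si: float = 0.737
    llt_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LLT_MIX))
    ldl_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LDL_MEAN_SD)
    )
    age_mean: float = 69.5
    age_sd: float = 11.9
    fraction_female: float = 0.45
    diagnosis_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_PREVALENCES)
    )
    #: share of SI patients already on bempedoic acid / a PCSK9 inhibitor at
    #: baseline (these are excluded from the simulation downstream)
    fraction_si_on_advanced_llt: float = 0.013

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecificationError("n_patients must be >= 1")
        for name in (
            "fraction_absolute_si",
            "fraction_partial_si",
            "risk_very_high_overall",
            "risk_very_high_within_si",
            "fraction_female",
            "fraction_si_on_advanced_llt",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecificationError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_absolute_si + self.fraction_partial_si >= 1.0:
            raise SpecificationError("SI fractions must sum to < 1")
        total = sum(self.llt_mix.values())
        if any(w < 0 for w in self.llt_mix.values()) or total <= 0:
            raise SpecificationError("llt_mix weights must be non-negative with positive sum")
        if abs(total - 1.0) > 1e-9:
            # printed mixes carry rounding; normalise once at construction
            object.__setattr__(
                self, "llt_mix", {k: w / total for k, w in self.llt_mix.items()}
            )
        unknown = set(self.llt_mix) - set(DEFAULT_LLT_MIX)
        if unknown:
            raise SpecificationError(f"unknown llt_mix strata: {sorted(unknown)}")
        for stratum, (mean, sd) in self.ldl_mean_sd.items():
            if mean <= 0 or sd <= 0:
                raise SpecificationError(f"LDL moments for {stratum!r} must be positive")


def si_cohort_spec(n_patients: int = 1000, seed: int = 0) -> CohortSpec:
    """Spec for a pure statin-intolerance cohort calibrated to the SI stratum.

    Absolute/partial shares follow the observed 2336/8950 split, risk mix is
    the within-SI 73.7/26.3, and baseline LDL-C is drawn for every treatment
    stratum from the SI-stratum moments (mean 105.6, SD 39.8 mg/dL).
    """
    return CohortSpec(
        n_patients=n_patients,
        seed=seed,
        fraction_absolute_si=0.2070,
        fraction_partial_si=0.7929,
        risk_very_high_overall=0.737,
        risk_very_high_within_si=0.737,
        ldl_mean_sd={"no_llt": (105.6, 39.8), "on_llt": (105.6, 39.8)},
    )


@dataclass(frozen=True)
class PlantedLabel:
    patient_id: str
    true_si_category: SICategory
    generating_rule: str  # classifier rule name or LLT stratum for non-SI
    true_risk_category: RiskCategory


def apportion(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` units over named fractions."""
    total = sum(fractions.values())
    if total <= 0:
        raise SpecificationError("fractions must have positive sum")
    quotas = {k: n * v / total for k, v in fractions.items()}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    shortfall = n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda k: (quotas[k] - counts[k], k), reverse=True)
    for k in by_remainder[:shortfall]:
        counts[k] += 1
    return counts


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def sample_ldl(stratum: str, spec: CohortSpec, rng: np.random.Generator, size=None):
    """Log-normal LDL-C draw(s) matching the stratum's arithmetic mean and SD."""
    if stratum not in spec.ldl_mean_sd:
        raise ValidationError(f"unknown LDL stratum: {stratum!r}")
    mu, sigma = _lognormal_params(*spec.ldl_mean_sd[stratum])
    return rng.lognormal(mu, sigma, size=size)


# ---------------------------------------------------------------------------
# Prescription-history templates
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, days: int = 15) -> dt.timedelta:
    return dt.timedelta(days=int(rng.integers(-days, days + 1)))


def _scripts(
    pid: str,
    regimen: tuple[DrugClass, str, float],
    dates: list[dt.date],
    supply: int = 90,
) -> list[PrescriptionEvent]:
    cls, molecule, dose = regimen
    return [PrescriptionEvent(pid, d, cls, molecule, dose, supply) for d in dates]


def _run_dates(
    index: dt.date, first_offset: int, last_offset: int, rng: np.random.Generator
) -> list[dt.date]:
    """Quarterly prescription dates at index − first_offset … index − last_offset,
    jittered ±15 d; 90-day steps keep every supply hole ≤ 30 d (refill noise)."""
    return [
        index - dt.timedelta(days=off) + _jitter(rng)
        for off in range(first_offset, last_offset - 1, -90)
    ]


_STATIN = DrugClass.statin
_EZE = (DrugClass.ezetimibe, "ezetimibe", 10.0)
_OTHER = (DrugClass.other_llt, "fenofibrate", 145.0)


def _continuous(pid, index, rng, regimen) -> list[PrescriptionEvent]:
    # covers index: last script ~30 d before index, 90-day supply
    return _scripts(pid, regimen, _run_dates(index, 1020, 30, rng))


def _ended_run(pid, index, rng, regimen, last_offset=350) -> list[PrescriptionEvent]:
    # last supply ends ~260 d before index → permanent discontinuation
    return _scripts(pid, regimen, _run_dates(index, 980, last_offset, rng))


def _si_note(pid, index, rng, category) -> DiagnosisEvent:
    return DiagnosisEvent(
        pid, index - dt.timedelta(days=int(rng.integers(30, 900))), category
    )


def _tmpl_abs_documented_si(pid, index, rng):
    return (
        _ended_run(pid, index, rng, (_STATIN, "simvastatin", 40.0)),
        [_si_note(pid, index, rng, DiagnosisCategory.documented_si_note)],
    )


def _tmpl_abs_sams(pid, index, rng):
    return (
        _ended_run(pid, index, rng, (_STATIN, "simvastatin", 40.0)),
        [_si_note(pid, index, rng, DiagnosisCategory.sams)],
    )


def _tmpl_abs_down_titration(pid, index, rng):
    first = _scripts(pid, (_STATIN, "atorvastatin", 40.0), _run_dates(index, 980, 800, rng))
    second = _scripts(pid, (_STATIN, "pravastatin", 20.0), _run_dates(index, 710, 350, rng))
    return first + second, []


def _tmpl_abs_statin_switch(pid, index, rng):
    first = _scripts(pid, (_STATIN, "simvastatin", 20.0), _run_dates(index, 980, 800, rng))
    second = _scripts(pid, (_STATIN, "atorvastatin", 20.0), _run_dates(index, 710, 350, rng))
    return first + second, []


def _tmpl_abs_intermittent_dosing(pid, index, rng):
    regimen = (_STATIN, "simvastatin", 40.0)
    dates = [
        index - dt.timedelta(days=off) + _jitter(rng)
        for off in (880, 790, 600, 390)  # holes of ~100 and ~120 d, then >180 d to index
    ]
    return _scripts(pid, regimen, dates), []


def _tmpl_abs_low_dose_latest(pid, index, rng):
    return _ended_run(pid, index, rng, (_STATIN, "simvastatin", 10.0)), []


def _tmpl_part_specific_switch_to_low(pid, index, rng):
    first = _scripts(pid, (_STATIN, "atorvastatin", 40.0), _run_dates(index, 930, 750, rng))
    second = _scripts(pid, (_STATIN, "pravastatin", 20.0), _run_dates(index, 660, 30, rng))
    return first + second, []


def _tmpl_part_down_titration_different(pid, index, rng):
    first = _scripts(pid, (_STATIN, "rosuvastatin", 20.0), _run_dates(index, 930, 750, rng))
    second = _scripts(pid, (_STATIN, "atorvastatin", 10.0), _run_dates(index, 660, 30, rng))
    return first + second, []


def _tmpl_part_documented_si(pid, index, rng):
    return (
        _continuous(pid, index, rng, (_STATIN, "atorvastatin", 20.0)),
        [_si_note(pid, index, rng, DiagnosisCategory.documented_si_note)],
    )


def _tmpl_part_down_same_with_switch(pid, index, rng):
    a = _scripts(pid, (_STATIN, "simvastatin", 40.0), _run_dates(index, 930, 750, rng))
    b = _scripts(pid, (_STATIN, "simvastatin", 10.0), _run_dates(index, 660, 480, rng))
    c = _scripts(pid, (_STATIN, "lovastatin", 20.0), _run_dates(index, 390, 30, rng))
    return a + b + c, []


def _tmpl_part_low_dose_plus_nonstatin(pid, index, rng):
    statin = _continuous(pid, index, rng, (_STATIN, "simvastatin", 10.0))
    eze = _continuous(pid, index, rng, _EZE)
    return statin + eze, []


SI_TEMPLATE_BUILDERS: dict[str, Callable] = {
    "abs_documented_si": _tmpl_abs_documented_si,
    "abs_sams": _tmpl_abs_sams,
    "abs_down_titration": _tmpl_abs_down_titration,
    "abs_statin_switch": _tmpl_abs_statin_switch,
    "abs_intermittent_dosing": _tmpl_abs_intermittent_dosing,
    "abs_low_dose_latest": _tmpl_abs_low_dose_latest,
    "part_specific_switch_to_low": _tmpl_part_specific_switch_to_low,
    "part_down_titration_different": _tmpl_part_down_titration_different,
    "part_documented_si": _tmpl_part_documented_si,
    "part_down_same_with_switch": _tmpl_part_down_same_with_switch,
    "part_low_dose_plus_nonstatin": _tmpl_part_low_dose_plus_nonstatin,
}

_NONSI_REGIMENS: dict[str, list[tuple[DrugClass, str, float]]] = {
    "none": [],
    "statin_mono_low": [(_STATIN, "simvastatin", 10.0)],
    "statin_mono_moderate": [(_STATIN, "simvastatin", 40.0)],
    "statin_mono_high": [(_STATIN, "atorvastatin", 40.0)],
    "ezetimibe_mono": [_EZE],
    "statin_plus_ezetimibe": [(_STATIN, "atorvastatin", 20.0), _EZE],
    "other": [_OTHER],
}


# ---------------------------------------------------------------------------
# Risk planting
# ---------------------------------------------------------------------------

def _plant_risk(
    pid: str, index: dt.date, category: RiskCategory, rng: np.random.Generator
) -> list[DiagnosisEvent]:
    """Diagnoses that make assign_risk recover exactly the planted category.

    Very-high patients qualify via documented atherosclerotic disease (95%)
    or chronic kidney disease (5%) and may carry any decorating risk factors;
    high patients qualify via diabetes (85%, with at most one of
    hypertension/smoking so the diabetes escalation rule cannot fire) or via
    hypertension plus current smoking without diabetes (15%).
    """
    events: list[DiagnosisEvent] = []

    def add(category: DiagnosisCategory, max_back: int, min_back: int = 10) -> None:
        events.append(
            DiagnosisEvent(
                pid, index - dt.timedelta(days=int(rng.integers(min_back, max_back))), category
            )
        )

    if category is RiskCategory.very_high:
        if rng.random() < 0.05:
            add(DiagnosisCategory.chronic_kidney_disease, 1500)
        else:
            subtypes = [
                (DiagnosisCategory.coronary_artery_disease, 0.62),
                (DiagnosisCategory.cerebrovascular_disease, 0.17),
                (DiagnosisCategory.peripheral_artery_disease, 0.31),
            ]
            drawn = [c for c, p in subtypes if rng.random() < p]
            if not drawn:
                drawn = [DiagnosisCategory.coronary_artery_disease]
            for c in drawn:
                add(c, 2000)
        # decorations cannot escalate beyond very-high or demote
        if rng.random() < 0.83:
            add(DiagnosisCategory.hypertension, 300)
        if rng.random() < 0.50:
            add(DiagnosisCategory.smoking, 300)
        if rng.random() < 0.50:
            add(DiagnosisCategory.diabetes, 2000)
    else:
        if rng.random() < 0.85:
            add(DiagnosisCategory.diabetes, 2000)
            # at most one modifiable factor, else the patient becomes very-high
            if rng.random() < 0.80:
                add(
                    DiagnosisCategory.hypertension
                    if rng.random() < 0.62
                    else DiagnosisCategory.smoking,
                    300,
                )
        else:
            add(DiagnosisCategory.hypertension, 300)
            add(DiagnosisCategory.smoking, 300)
    return events


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: CohortSpec, config: SelectionConfig | None = None
) -> tuple[dict[str, PatientRecord], list[PlantedLabel]]:
    """Generate patient records plus planted ground-truth labels.

    Category counts (SI mix, risk mix, LLT mix) are apportioned by largest
    remainder, so realised integer mixes are exact and reproducible; within
    categories, assignment order is randomised by the seeded generator.
    """
    if config is None:
        config = SelectionConfig()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_patients
    si_counts = apportion(
        {
            "absolute": spec.fraction_absolute_si,
            "partial": spec.fraction_partial_si,
            "none": 1.0 - spec.fraction_absolute_si - spec.fraction_partial_si,
        },
        n,
    )
    categories = (
        [SICategory.absolute] * si_counts["absolute"]
        + [SICategory.partial] * si_counts["partial"]
        + [SICategory.none] * si_counts["none"]
    )
    rng.shuffle(categories)  # type: ignore[arg-type]

    # risk planting: within-SI mix for SI patients; the non-SI share is set so
    # the overall very-high fraction comes out at the configured overall mix
    n_si = si_counts["absolute"] + si_counts["partial"]
    vh_si = apportion({"vh": spec.risk_very_high_within_si, "h": 1 - spec.risk_very_high_within_si}, n_si)["vh"]
    n_nonsi = n - n_si
    vh_overall = apportion(
        {"vh": spec.risk_very_high_overall, "h": 1 - spec.risk_very_high_overall}, n
    )["vh"]
    vh_nonsi = min(max(vh_overall - vh_si, 0), n_nonsi)

    si_risk = [RiskCategory.very_high] * vh_si + [RiskCategory.high] * (n_si - vh_si)
    nonsi_risk = [RiskCategory.very_high] * vh_nonsi + [RiskCategory.high] * (n_nonsi - vh_nonsi)
    rng.shuffle(si_risk)  # type: ignore[arg-type]
    rng.shuffle(nonsi_risk)  # type: ignore[arg-type]
    si_risk_iter = iter(si_risk)
    nonsi_risk_iter = iter(nonsi_risk)

    # non-SI LLT strata and SI rule templates
    nonsi_counts = apportion(spec.llt_mix, n_nonsi) if n_nonsi else {}
    nonsi_strata = [s for s, c in sorted(nonsi_counts.items()) for _ in range(c)]
    rng.shuffle(nonsi_strata)  # type: ignore[arg-type]
    nonsi_iter = iter(nonsi_strata)

    abs_counts = apportion(ABSOLUTE_TEMPLATES, si_counts["absolute"]) if si_counts["absolute"] else {}
    part_counts = apportion(PARTIAL_TEMPLATES, si_counts["partial"]) if si_counts["partial"] else {}
    abs_templates = [t for t, c in sorted(abs_counts.items()) for _ in range(c)]
    part_templates = [t for t, c in sorted(part_counts.items()) for _ in range(c)]
    rng.shuffle(abs_templates)  # type: ignore[arg-type]
    rng.shuffle(part_templates)  # type: ignore[arg-type]
    abs_iter = iter(abs_templates)
    part_iter = iter(part_templates)

    window_days = (config.selection_end - config.selection_start).days
    width = len(str(n))
    cohort: dict[str, PatientRecord] = {}
    labels: list[PlantedLabel] = []

    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        si_cat = categories[i]
        index = config.selection_start + dt.timedelta(days=int(rng.integers(0, window_days)))

        if si_cat is SICategory.absolute:
            template = next(abs_iter)
            risk = next(si_risk_iter)
        elif si_cat is SICategory.partial:
            template = next(part_iter)
            risk = next(si_risk_iter)
        else:
            template = next(nonsi_iter)
            risk = next(nonsi_risk_iter)

        if si_cat is SICategory.none:
            prescriptions = [
                s
                for regimen in _NONSI_REGIMENS[template]
                for s in _continuous(pid, index, rng, regimen)
            ]
            diagnoses: list[DiagnosisEvent] = []
        else:
            prescriptions, diagnoses = SI_TEMPLATE_BUILDERS[template](pid, index, rng)
            if template.startswith("abs_") and rng.random() < 0.35:
                # some absolutely intolerant patients continue on ezetimibe only
                prescriptions += _continuous(pid, index, rng, _EZE)
            if rng.random() < spec.fraction_si_on_advanced_llt:
                advanced = (
                    (DrugClass.bempedoic_acid, "bempedoic acid", 180.0)
                    if rng.random() < 0.5
                    else (DrugClass.pcsk9_inhibitor, "evolocumab", 140.0)
                )
                prescriptions += _continuous(pid, index, rng, advanced)

        diagnoses += _plant_risk(pid, index, risk, rng)
        for name, prev in spec.diagnosis_prevalences.items():
            if rng.random() < prev:
                diagnoses.append(
                    DiagnosisEvent(
                        pid,
                        index - dt.timedelta(days=int(rng.integers(10, 2000))),
                        DiagnosisCategory(name),
                    )
                )

        on_llt = any(
            p.date <= index < p.date + dt.timedelta(days=p.supply(config)) for p in prescriptions
        )
        stratum = "on_llt" if on_llt else "no_llt"
        labs = [
            LabMeasurement(pid, index, "ldl_c", round(float(sample_ldl(stratum, spec, rng)), 1))
        ]
        if (index - config.selection_start).days > 60 and rng.random() < 0.3:
            earlier = config.selection_start + dt.timedelta(
                days=int(rng.integers(0, (index - config.selection_start).days - 30))
            )
            labs.append(
                LabMeasurement(
                    pid, earlier, "ldl_c", round(float(sample_ldl(stratum, spec, rng)), 1)
                )
            )

        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 19.0, 105.0))
        record = PatientRecord(
            patient_id=pid,
            sex=Sex.female if rng.random() < spec.fraction_female else Sex.male,
            age_years=round(age, 1),
            prescriptions=prescriptions,
            labs=labs,
            diagnoses=diagnoses,
        )
        record.sort_events()
        cohort[pid] = record
        labels.append(PlantedLabel(pid, si_cat, template, risk))

    return cohort, labels


LABEL_COLUMNS = ["patient_id", "true_si_category", "generating_rule", "true_risk_category"]


def write_labels(labels: list[PlantedLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            (l.patient_id, l.true_si_category.value, l.generating_rule, l.true_risk_category.value)
            for l in labels
        ],
        columns=LABEL_COLUMNS,
    ).to_csv(path, index=False)


def load_labels(path: str | Path) -> list[PlantedLabel]:
    df = pd.read_csv(path, dtype=str)
    return [
        PlantedLabel(
            r.patient_id,
            SICategory(r.true_si_category),
            r.generating_rule,
            RiskCategory(r.true_risk_category),
        )
        for r in df.itertuples(index=False)
    ]


def generate_tables(
    spec: CohortSpec, out_dir: str | Path, config: SelectionConfig | None = None
) -> dict[str, Path]:
    """Generate a cohort and write the four standard tables plus the labels table."""
    cohort, labels = generate_cohort(spec, config)
    paths = write_cohort(cohort, out_dir)
    labels_path = Path(out_dir) / "labels.csv"
    write_labels(labels, labels_path)
    paths["labels"] = labels_path
    return paths
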