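"""End-to-end orchestration: cohort → index LDL-C → risk → SI → simulation.

Keeps an explicit account of every patient at every filter so that cohort
closure (no patient silently lost) is checkable:
``n_total = n_no_valid_ldl + n_no_risk + n_included`` and
``n_si = n_si_excluded_baseline_drugs + n_entering_simulation``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .config import SelectionConfig
from .emr_model import (
    DrugClass,
    EZETIMIBE_CONTAINING,
    Intensity,
    LLTTimeline,
    PatientRecord,
    StatinCatalog,
    build_llt_timeline,
    select_index_ldl,
    trim_outliers,
)
from .errors import ConfigurationError
from .risk_targets import RiskProfile, RiskRules, assign_risk
from .si_classifier import (
    SICategory,
    SIClassification,
    SIRuleSet,
    classify_si,
    detect_signals,
)
from .treatment_sim import (
    PatientSimState,
    SimulationConfig,
    SimulationResult,
    StatinStratum,
    run_monte_carlo,
)

_EXCLUDABLE = {
    "bempedoic_acid": DrugClass.bempedoic_acid,
    "pcsk9_inhibitor": DrugClass.pcsk9_inhibitor,
}


@dataclass
class CohortAccounting:
    n_total: int = 0
    n_trimmed_ldl_measurements: int = 0
    n_no_valid_index_ldl: int = 0
    n_no_risk_category: int = 0
    n_included: int = 0
    n_si: int = 0
    n_si_excluded_baseline_drugs: int = 0
    n_entering_simulation: int = 0

    def check_closure(self) -> None:
        if self.n_total != self.n_no_valid_index_ldl + self.n_no_risk_category + self.n_included:
            raise ConfigurationError("cohort accounting does not close at inclusion")
        if self.n_si != self.n_si_excluded_baseline_drugs + self.n_entering_simulation:
            raise ConfigurationError("cohort accounting does not close at simulation entry")


@dataclass
class PatientResult:
    patient_id: str
    index_date: dt.date
    baseline_ldl: float
    risk: RiskProfile
    classification: SIClassification
    timeline: LLTTimeline


@dataclass
class PipelineResult:
    accounting: CohortAccounting
    patients: dict[str, PatientResult] = field(default_factory=dict)
    simulation: SimulationResult | None = None
    sim_states: list[PatientSimState] = field(default_factory=list)

    @property
    def classifications(self) -> dict[str, SIClassification]:
        return {pid: p.classification for pid, p in self.patients.items()}

    @property
    def risk_profiles(self) -> dict[str, RiskProfile]:
        return {pid: p.risk for pid, p in self.patients.items()}


def classify_cohort(
    cohort: dict[str, PatientRecord],
    config: SelectionConfig | None = None,
    catalog: StatinCatalog | None = None,
    rules: SIRuleSet | None = None,
    risk_rules: RiskRules | None = None,
) -> PipelineResult:
    """Apply outlier trimming, index selection, risk assignment and SI rules."""
    config = config or SelectionConfig()
    catalog = catalog or StatinCatalog()
    rules = rules or SIRuleSet()
    risk_rules = risk_rules or RiskRules()

    acc = CohortAccounting(n_total=len(cohort))

    # cohort-wide laboratory outlier trim before index selection
    keyed = [
        (pid, k)
        for pid in sorted(cohort)
        for k, lab in enumerate(cohort[pid].labs)
        if lab.analyte == "ldl_c"
    ]
    values = [cohort[pid].labs[k].value for pid, k in keyed]
    mask = trim_outliers(values, config.outlier_trim_fraction)
    dropped = {key for key, keep in zip(keyed, mask) if not keep}
    acc.n_trimmed_ldl_measurements = len(dropped)

    result = PipelineResult(accounting=acc)
    for pid in sorted(cohort):
        record = cohort[pid]
        if dropped:
            record = PatientRecord(
                patient_id=record.patient_id,
                sex=record.sex,
                age_years=record.age_years,
                prescriptions=record.prescriptions,
                labs=[lab for k, lab in enumerate(record.labs) if (pid, k) not in dropped],
                diagnoses=record.diagnoses,
            )
        index_lab = select_index_ldl(record, config)
        if index_lab is None:
            acc.n_no_valid_index_ldl += 1
            continue
        risk = assign_risk(record, index_lab.date, config, risk_rules)
        if risk is None:
            acc.n_no_risk_category += 1
            continue
        acc.n_included += 1
        timeline = build_llt_timeline(record, index_lab.date, config, catalog)
        signals = detect_signals(timeline, record.diagnoses, config)
        classification = classify_si(signals, timeline, rules)
        if classification.category is not SICategory.none:
            acc.n_si += 1
        result.patients[pid] = PatientResult(
            patient_id=pid,
            index_date=index_lab.date,
            baseline_ldl=index_lab.value,
            risk=risk,
            classification=classification,
            timeline=timeline,
        )
    return result


def build_sim_states(
    result: PipelineResult, sim_config: SimulationConfig
) -> list[PatientSimState]:
    """Simulation entry states for the SI cohort, after baseline-drug exclusion."""
    excluded_classes = {
        _EXCLUDABLE[name] for name in sim_config.exclude_baseline_drugs if name in _EXCLUDABLE
    }
    states: list[PatientSimState] = []
    for pid in sorted(result.patients):
        p = result.patients[pid]
        if p.classification.category is SICategory.none:
            continue
        active = p.timeline.latest_llt_classes
        if active & excluded_classes:
            result.accounting.n_si_excluded_baseline_drugs += 1
            continue
        statin_active = not p.timeline.statin_free_at_index
        stratum = (
            StatinStratum.moderate_or_high
            if statin_active
            and p.timeline.latest_statin is not None
            and p.timeline.latest_statin.intensity in (Intensity.moderate, Intensity.high)
            else StatinStratum.low_or_none
        )
        states.append(
            PatientSimState(
                patient_id=pid,
                baseline_ldl=p.baseline_ldl,
                risk_category=p.risk.category,
                on_ezetimibe_baseline=bool(active & EZETIMIBE_CONTAINING),
                baseline_statin_stratum=stratum,
            )
        )
    result.accounting.n_entering_simulation = len(states)
    return states


def run_pipeline(
    cohort: dict[str, PatientRecord],
    config: SelectionConfig | None = None,
    catalog: StatinCatalog | None = None,
    rules: SIRuleSet | None = None,
    risk_rules: RiskRules | None = None,
    sim_config: SimulationConfig | None = None,
) -> PipelineResult:
    """Full pipeline; the simulation step runs only if any SI patient enters."""
    sim_config = sim_config or SimulationConfig()
    result = classify_cohort(cohort, config, catalog, rules, risk_rules)
    states = build_sim_states(result, sim_config)
    result.sim_states = states
    result.accounting.check_closure()
    if states:
        result.simulation = run_monte_carlo(states, sim_config)
    return result
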