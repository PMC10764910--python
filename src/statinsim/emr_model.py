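"""EMR domain model: patients, prescriptions, labs, diagnoses, statin catalog,
lipid-lowering-therapy timelines and index-date selection.

The substrate of the whole pipeline: longitudinal outpatient records are read
from four delimited tables, prescriptions are turned into supply-based
treatment episodes relative to a per-patient index date (the last valid LDL-C
in the selection window), and statin-free gaps are measured on the day-level
supply coverage so that discontinuation rules operate on exhausted supply,
not raw prescription dates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SelectionConfig
from .errors import CatalogError, InputError, ValidationError


class Sex(str, Enum):
    female = "female"
    male = "male"


class DrugClass(str, Enum):
    statin = "statin"
    ezetimibe = "ezetimibe"
    bempedoic_acid = "bempedoic_acid"
    pcsk9_inhibitor = "pcsk9_inhibitor"
    other_llt = "other_llt"
    fixed_combination = "fixed_combination"


#: Drug classes whose presence at index marks the patient as already on ezetimibe.
EZETIMIBE_CONTAINING = frozenset({DrugClass.ezetimibe, DrugClass.fixed_combination})


class Intensity(str, Enum):
    low = "low"
    moderate = "moderate"
    high = "high"


INTENSITY_RANK = {Intensity.low: 1, Intensity.moderate: 2, Intensity.high: 3}


class DiagnosisCategory(str, Enum):
    coronary_artery_disease = "coronary_artery_disease"
    cerebrovascular_disease = "cerebrovascular_disease"
    peripheral_artery_disease = "peripheral_artery_disease"
    diabetes = "diabetes"
    hypertension = "hypertension"
    smoking = "smoking"
    chronic_kidney_disease = "chronic_kidney_disease"
    liver_disease = "liver_disease"
    gout = "gout"
    hyperuricaemia = "hyperuricaemia"
    documented_si_note = "documented_si_note"
    sams = "sams"
    other_si_event = "other_si_event"


@dataclass(frozen=True)
class PrescriptionEvent:
    patient_id: str
    date: dt.date
    drug_class: DrugClass
    molecule: str
    dose_mg: float
    supply_days: int | None = None

    def supply(self, config: SelectionConfig) -> int:
        return self.supply_days if self.supply_days is not None else config.default_supply_days


@dataclass(frozen=True)
class LabMeasurement:
    patient_id: str
    date: dt.date
    analyte: str
    value: float  # mg/dL


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    date: dt.date
    category: DiagnosisCategory


@dataclass
class PatientRecord:
    """One patient's demographic fields and date-sorted event streams."""

    patient_id: str
    sex: Sex
    age_years: float
    prescriptions: list[PrescriptionEvent] = field(default_factory=list)
    labs: list[LabMeasurement] = field(default_factory=list)
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)

    def sort_events(self) -> None:
        self.prescriptions.sort(key=lambda e: (e.date, e.drug_class.value, e.molecule, e.dose_mg))
        self.labs.sort(key=lambda e: (e.date, e.value))
        self.diagnoses.sort(key=lambda e: (e.date, e.category.value))


# ---------------------------------------------------------------------------
# Statin intensity catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatinCatalogEntry:
    molecule: str
    dose_min_mg: float
    dose_max_mg: float  # inclusive band
    intensity: Intensity

    @property
    def intensity_rank(self) -> int:
        return INTENSITY_RANK[self.intensity]

    @property
    def is_low_dose(self) -> bool:
        # low-dose and low-intensity are used interchangeably in this pipeline
        return self.intensity is Intensity.low


_INF = float("inf")

#: Default dose→intensity bands. The published registry table this emulates is
#: not public; the bands are a conventional low/moderate/high reading and the
#: catalog is configuration so the exact table can be swapped in.
DEFAULT_CATALOG_ENTRIES: tuple[StatinCatalogEntry, ...] = (
    StatinCatalogEntry("simvastatin", 0.0, 10.0, Intensity.low),
    StatinCatalogEntry("simvastatin", 20.0, 40.0, Intensity.moderate),
    StatinCatalogEntry("simvastatin", 80.0, 80.0, Intensity.high),
    StatinCatalogEntry("pravastatin", 0.0, _INF, Intensity.low),
    StatinCatalogEntry("fluvastatin", 0.0, _INF, Intensity.low),
    StatinCatalogEntry("lovastatin", 0.0, 20.0, Intensity.low),
    StatinCatalogEntry("lovastatin", 40.0, 40.0, Intensity.moderate),
    StatinCatalogEntry("rosuvastatin", 5.0, 5.0, Intensity.low),
    StatinCatalogEntry("rosuvastatin", 10.0, 10.0, Intensity.moderate),
    StatinCatalogEntry("rosuvastatin", 20.0, 40.0, Intensity.high),
    StatinCatalogEntry("atorvastatin", 5.0, 5.0, Intensity.low),
    StatinCatalogEntry("atorvastatin", 10.0, 20.0, Intensity.moderate),
    StatinCatalogEntry("atorvastatin", 40.0, 80.0, Intensity.high),
)


class StatinCatalog:
    """Dose-band lookup from (molecule, dose) to statin intensity."""

    def __init__(self, entries: Iterable[StatinCatalogEntry] = DEFAULT_CATALOG_ENTRIES):
        self.entries: list[StatinCatalogEntry] = list(entries)
        self._by_molecule: dict[str, list[StatinCatalogEntry]] = {}
        for e in self.entries:
            self._by_molecule.setdefault(e.molecule, []).append(e)
        for mol, bands in self._by_molecule.items():
            bands.sort(key=lambda e: e.dose_min_mg)
            for a, b in zip(bands, bands[1:]):
                if b.dose_min_mg <= a.dose_max_mg:
                    raise CatalogError(f"overlapping dose bands for {mol}")

    @property
    def molecules(self) -> frozenset[str]:
        return frozenset(self._by_molecule)

    def classify(self, molecule: str, dose_mg: float) -> tuple[Intensity, bool]:
        """Return ``(intensity, is_low_dose)`` for one statin regimen."""
        bands = self._by_molecule.get(molecule)
        if bands is None:
            raise CatalogError(f"unknown statin molecule: {molecule!r}")
        for e in bands:
            if e.dose_min_mg <= dose_mg <= e.dose_max_mg:
                return e.intensity, e.is_low_dose
        raise CatalogError(f"dose {dose_mg} mg of {molecule} outside every configured band")

    def to_records(self) -> list[dict]:
        return [
            {
                "molecule": e.molecule,
                "dose_min_mg": e.dose_min_mg,
                "dose_max_mg": None if e.dose_max_mg == _INF else e.dose_max_mg,
                "intensity": e.intensity.value,
            }
            for e in self.entries
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "StatinCatalog":
        entries = [
            StatinCatalogEntry(
                r["molecule"],
                float(r["dose_min_mg"]),
                _INF if r.get("dose_max_mg") is None else float(r["dose_max_mg"]),
                Intensity(r["intensity"]),
            )
            for r in records
        ]
        return cls(entries)


def classify_statin_regimen(
    molecule: str, dose_mg: float, catalog: StatinCatalog
) -> tuple[Intensity, bool]:
    """Deterministic catalog lookup; see :meth:`StatinCatalog.classify`."""
    return catalog.classify(molecule, dose_mg)


# ---------------------------------------------------------------------------
# Timeline construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatinEpisode:
    molecule: str
    dose_mg: float
    intensity: Intensity
    start: dt.date
    end: dt.date  # end of last supply, half-open

    @property
    def intensity_rank(self) -> int:
        return INTENSITY_RANK[self.intensity]


@dataclass(frozen=True)
class SupplyGap:
    start: dt.date
    end: dt.date

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days


@dataclass
class LLTTimeline:
    """Statin episodes, supply gaps and discontinuation flags before an index date.

    ``gaps`` are statin-free holes in the day-level supply coverage, including
    the trailing hole from the last supply end up to the index date. Long-term
    discontinuation means some hole strictly exceeds the configured gap;
    permanent discontinuation means the trailing hole does (no statin between
    that gap and the index date).
    """

    index_date: dt.date
    statin_episodes: list[StatinEpisode] = field(default_factory=list)
    gaps: list[SupplyGap] = field(default_factory=list)
    latest_statin: StatinEpisode | None = None
    latest_llt_classes: frozenset[DrugClass] = frozenset()
    long_term_discontinued: bool = False
    permanently_discontinued: bool = False
    statin_free_at_index: bool = True


def _merge_intervals(intervals: list[tuple[dt.date, dt.date]]) -> list[tuple[dt.date, dt.date]]:
    """Union of half-open day intervals, sorted and coalesced (adjacent merge)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage_runs(
    prescriptions: Sequence[PrescriptionEvent],
    config: SelectionConfig,
    drug_classes: Iterable[DrugClass] | None = None,
    merge_gap_days: int = 0,
) -> list[tuple[dt.date, dt.date]]:
    """Merged supply-coverage intervals ``[date, date + supply)`` per drug-class set.

    ``merge_gap_days > 0`` additionally coalesces runs separated by holes of
    at most that many days (used to treat refill gaps as one regimen when
    judging stability, while gap detection itself uses the raw holes).
    """
    wanted = None if drug_classes is None else set(drug_classes)
    intervals = [
        (p.date, p.date + dt.timedelta(days=p.supply(config)))
        for p in prescriptions
        if wanted is None or p.drug_class in wanted
    ]
    runs = _merge_intervals(intervals)
    if merge_gap_days <= 0 or not runs:
        return runs
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if (s - merged[-1][1]).days <= merge_gap_days:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_llt_timeline(
    patient: PatientRecord,
    index_date: dt.date,
    config: SelectionConfig,
    catalog: StatinCatalog,
) -> LLTTimeline:
    """Construct the lipid-lowering timeline over the SI look-back window.

    Same-day statin duplicates keep the higher-intensity (then higher-dose)
    regimen. Consecutive same-regimen prescriptions merge into one episode as
    long as the statin-free hole between end-of-supply and the next
    prescription does not exceed ``discontinuation_gap_days``; a regimen
    change always starts a new episode. Holes in the pooled statin supply
    coverage — including the trailing hole up to the index date — are recorded
    as gaps and drive the discontinuation flags.
    """
    window_start = index_date - dt.timedelta(days=config.si_lookback_days)
    in_window = [p for p in patient.prescriptions if window_start <= p.date < index_date]

    timeline = LLTTimeline(index_date=index_date)

    # drug classes with supply covering the index date
    timeline.latest_llt_classes = frozenset(
        p.drug_class
        for p in in_window
        if p.date <= index_date < p.date + dt.timedelta(days=p.supply(config))
    )

    statins = [p for p in in_window if p.drug_class is DrugClass.statin]
    if not statins:
        # statin-naive within the look-back: all discontinuation flags stay False
        timeline.statin_free_at_index = True
        return timeline

    # same-day tie-break: higher intensity, then higher dose
    by_day: dict[dt.date, tuple[PrescriptionEvent, Intensity]] = {}
    for p in sorted(statins, key=lambda p: p.date):
        intensity, _ = catalog.classify(p.molecule, p.dose_mg)
        kept = by_day.get(p.date)
        if (
            kept is None
            or INTENSITY_RANK[intensity] > INTENSITY_RANK[kept[1]]
            or (INTENSITY_RANK[intensity] == INTENSITY_RANK[kept[1]] and p.dose_mg > kept[0].dose_mg)
        ):
            by_day[p.date] = (p, intensity)
    daily = [by_day[d] for d in sorted(by_day)]

    # episodes: contiguous same-regimen runs
    episodes: list[StatinEpisode] = []
    cur: dict | None = None
    for p, intensity in daily:
        end = p.date + dt.timedelta(days=p.supply(config))
        if (
            cur is not None
            and cur["molecule"] == p.molecule
            and cur["dose_mg"] == p.dose_mg
            and (p.date - cur["end"]).days <= config.discontinuation_gap_days
        ):
            cur["end"] = max(cur["end"], end)
        else:
            if cur is not None:
                episodes.append(
                    StatinEpisode(
                        cur["molecule"], cur["dose_mg"], cur["intensity"], cur["start"], cur["end"]
                    )
                )
            cur = {
                "molecule": p.molecule,
                "dose_mg": p.dose_mg,
                "intensity": intensity,
                "start": p.date,
                "end": end,
            }
    if cur is not None:
        episodes.append(
            StatinEpisode(cur["molecule"], cur["dose_mg"], cur["intensity"], cur["start"], cur["end"])
        )
    timeline.statin_episodes = episodes
    timeline.latest_statin = episodes[-1] if episodes else None

    # gaps = holes in pooled statin supply coverage, plus the trailing hole
    runs = coverage_runs(in_window, config, [DrugClass.statin])
    gaps: list[SupplyGap] = []
    for (s1, e1), (s2, _) in zip(runs, runs[1:]):
        if s2 > e1:
            gaps.append(SupplyGap(e1, s2))
    last_end = runs[-1][1]
    if last_end < index_date:
        gaps.append(SupplyGap(last_end, index_date))
    timeline.gaps = gaps

    timeline.statin_free_at_index = not any(s <= index_date < e for s, e in runs)
    gap_days = config.discontinuation_gap_days
    timeline.long_term_discontinued = any(g.length_days > gap_days for g in gaps)
    timeline.permanently_discontinued = (
        last_end < index_date and (index_date - last_end).days > gap_days
    )
    return timeline


# ---------------------------------------------------------------------------
# Index LDL-C selection and outlier trimming
# ---------------------------------------------------------------------------

def select_index_ldl(
    patient: PatientRecord, config: SelectionConfig
) -> LabMeasurement | None:
    """Latest valid LDL-C in the selection window, or ``None``.

    A measurement is valid if the patient is on no lipid-lowering therapy at
    the draw date, or every LLT drug class active at the draw started its
    current coverage run at least ``llt_stability_days`` before the draw.
    Supply holes up to ``discontinuation_gap_days`` within one class count as
    refill gaps of the same regimen, not a new start.
    """
    candidates = [
        lab
        for lab in patient.labs
        if lab.analyte == "ldl_c" and config.selection_start <= lab.date < config.selection_end
    ]
    runs_by_class: dict[DrugClass, list[tuple[dt.date, dt.date]]] = {}
    for lab in sorted(candidates, key=lambda l: l.date, reverse=True):
        valid = True
        for cls in DrugClass:
            if cls not in runs_by_class:
                runs_by_class[cls] = coverage_runs(
                    patient.prescriptions,
                    config,
                    [cls],
                    merge_gap_days=config.discontinuation_gap_days,
                )
            for s, e in runs_by_class[cls]:
                if s <= lab.date < e:
                    if (lab.date - s).days < config.llt_stability_days:
                        valid = False
                    break
            if not valid:
                break
        if valid:
            return lab
    return None


def trim_outliers(values: Sequence[float], trim_fraction: float) -> np.ndarray:
    """Boolean retain-mask excluding extreme-tail laboratory values.

    Cutoffs are the ``trim_fraction`` and ``1 - trim_fraction`` quantiles
    under midpoint (Hazen) plotting positions; values strictly outside the
    cutoffs are dropped. With small fractions and small n both cutoffs fall
    on the extreme order statistics and nothing is removed.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise ValidationError(f"trim_fraction must lie in [0, 0.5), got {trim_fraction}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return np.zeros(0, dtype=bool)
    lo = np.quantile(arr, trim_fraction, method="hazen")
    hi = np.quantile(arr, 1.0 - trim_fraction, method="hazen")
    return (arr >= lo) & (arr <= hi)


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ["patient_id", "sex", "age_years"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_class", "molecule", "dose_mg", "supply_days"]
LAB_COLUMNS = ["patient_id", "date", "analyte", "value_mg_dl"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "category"]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _parse_date(raw: str, table: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(raw)
    except ValueError as exc:
        raise ValidationError(f"{table} row {row}: bad date {raw!r}") from exc


def load_cohort(
    patient_table_path: str | Path,
    prescription_table_path: str | Path,
    lab_table_path: str | Path,
    diagnosis_table_path: str | Path,
) -> dict[str, PatientRecord]:
    """Read the four delimited tables into one :class:`PatientRecord` per patient.

    Rows with unparseable required fields raise :class:`ValidationError`
    naming the offending table and row (1-based, excluding the header);
    events attached to unknown patient ids are rejected the same way.
    """
    patients = _read_table(patient_table_path, PATIENT_COLUMNS)
    prescriptions = _read_table(prescription_table_path, PRESCRIPTION_COLUMNS)
    labs = _read_table(lab_table_path, LAB_COLUMNS)
    diagnoses = _read_table(diagnosis_table_path, DIAGNOSIS_COLUMNS)

    cohort: dict[str, PatientRecord] = {}
    for i, row in enumerate(patients.itertuples(index=False), start=1):
        pid = row.patient_id
        if pid in cohort:
            raise ValidationError(f"patients row {i}: duplicate patient_id {pid!r}")
        try:
            sex = Sex(row.sex)
        except ValueError as exc:
            raise ValidationError(f"patients row {i}: bad sex {row.sex!r}") from exc
        try:
            age = float(row.age_years)
        except ValueError as exc:
            raise ValidationError(f"patients row {i}: bad age {row.age_years!r}") from exc
        cohort[pid] = PatientRecord(patient_id=pid, sex=sex, age_years=age)

    for i, row in enumerate(prescriptions.itertuples(index=False), start=1):
        if row.patient_id not in cohort:
            raise ValidationError(f"prescriptions row {i}: unknown patient_id {row.patient_id!r}")
        date = _parse_date(row.date, "prescriptions", i)
        try:
            drug_class = DrugClass(row.drug_class)
        except ValueError as exc:
            raise ValidationError(f"prescriptions row {i}: bad drug_class {row.drug_class!r}") from exc
        try:
            dose = float(row.dose_mg)
        except ValueError as exc:
            raise ValidationError(f"prescriptions row {i}: bad dose_mg {row.dose_mg!r}") from exc
        if dose <= 0:
            raise ValidationError(f"prescriptions row {i}: non-positive dose_mg {row.dose_mg!r}")
        supply: int | None = None
        if row.supply_days != "":
            try:
                supply = int(row.supply_days)
            except ValueError as exc:
                raise ValidationError(
                    f"prescriptions row {i}: bad supply_days {row.supply_days!r}"
                ) from exc
            if supply <= 0:
                raise ValidationError(f"prescriptions row {i}: non-positive supply_days {supply}")
        cohort[row.patient_id].prescriptions.append(
            PrescriptionEvent(row.patient_id, date, drug_class, row.molecule, dose, supply)
        )

    for i, row in enumerate(labs.itertuples(index=False), start=1):
        if row.patient_id not in cohort:
            raise ValidationError(f"labs row {i}: unknown patient_id {row.patient_id!r}")
        date = _parse_date(row.date, "labs", i)
        try:
            value = float(row.value_mg_dl)
        except ValueError as exc:
            raise ValidationError(f"labs row {i}: bad value_mg_dl {row.value_mg_dl!r}") from exc
        if value <= 0:
            raise ValidationError(f"labs row {i}: non-positive value_mg_dl {value}")
        cohort[row.patient_id].labs.append(LabMeasurement(row.patient_id, date, row.analyte, value))

    for i, row in enumerate(diagnoses.itertuples(index=False), start=1):
        if row.patient_id not in cohort:
            raise ValidationError(f"diagnoses row {i}: unknown patient_id {row.patient_id!r}")
        date = _parse_date(row.date, "diagnoses", i)
        try:
            category = DiagnosisCategory(row.category)
        except ValueError as exc:
            raise ValidationError(f"diagnoses row {i}: bad category {row.category!r}") from exc
        cohort[row.patient_id].diagnoses.append(DiagnosisEvent(row.patient_id, date, category))

    for record in cohort.values():
        record.sort_events()
    return cohort


def write_cohort(cohort: dict[str, PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write the four standard delimited tables; inverse of :func:`load_cohort`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = sorted(cohort)

    patients = pd.DataFrame(
        [(pid, cohort[pid].sex.value, cohort[pid].age_years) for pid in ids],
        columns=PATIENT_COLUMNS,
    )
    prescriptions = pd.DataFrame(
        [
            (
                pid,
                p.date.isoformat(),
                p.drug_class.value,
                p.molecule,
                p.dose_mg,
                "" if p.supply_days is None else p.supply_days,
            )
            for pid in ids
            for p in cohort[pid].prescriptions
        ],
        columns=PRESCRIPTION_COLUMNS,
    )
    labs = pd.DataFrame(
        [(pid, l.date.isoformat(), l.analyte, l.value) for pid in ids for l in cohort[pid].labs],
        columns=LAB_COLUMNS,
    )
    diagnoses = pd.DataFrame(
        [(pid, d.date.isoformat(), d.category.value) for pid in ids for d in cohort[pid].diagnoses],
        columns=DIAGNOSIS_COLUMNS,
    )

    paths = {
        "patients": out_dir / "patients.csv",
        "prescriptions": out_dir / "prescriptions.csv",
        "labs": out_dir / "labs.csv",
        "diagnoses": out_dir / "diagnoses.csv",
    }
    patients.to_csv(paths["patients"], index=False)
    prescriptions.to_csv(paths["prescriptions"], index=False)
    labs.to_csv(paths["labs"], index=False)
    diagnoses.to_csv(paths["diagnoses"], index=False)
    return paths
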