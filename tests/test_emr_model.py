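"""Domain model: catalog lookup, timeline/gap construction, index LDL-C, I/O."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statinsim import (
    DrugClass,
    Intensity,
    SelectionConfig,
    StatinCatalog,
    build_llt_timeline,
    classify_statin_regimen,
    load_cohort,
    select_index_ldl,
    trim_outliers,
    write_cohort,
)
from statinsim.errors import CatalogError, InputError, ValidationError

from conftest import INDEX, lab, patient, quarterly, rx


class TestStatinCatalog:
    @pytest.mark.parametrize(
        "molecule, dose, intensity, low",
        [
            ("rosuvastatin", 5, Intensity.low, True),
            ("rosuvastatin", 10, Intensity.moderate, False),
            ("rosuvastatin", 40, Intensity.high, False),
            ("atorvastatin", 80, Intensity.high, False),
            ("atorvastatin", 5, Intensity.low, True),
            ("simvastatin", 10, Intensity.low, True),
            ("simvastatin", 40, Intensity.moderate, False),
            ("simvastatin", 80, Intensity.high, False),
            ("pravastatin", 40, Intensity.low, True),
            ("fluvastatin", 80, Intensity.low, True),
            ("lovastatin", 40, Intensity.moderate, False),
        ],
    )
    def test_dose_band_lookup(self, catalog, molecule, dose, intensity, low):
        assert classify_statin_regimen(molecule, dose, catalog) == (intensity, low)

    def test_unknown_molecule_raises(self, catalog):
        with pytest.raises(CatalogError):
            classify_statin_regimen("unobtanium", 10, catalog)

    def test_out_of_band_dose_raises(self, catalog):
        with pytest.raises(CatalogError):
            classify_statin_regimen("simvastatin", 15, catalog)

    def test_overlapping_bands_rejected(self):
        records = [
            {"molecule": "x", "dose_min_mg": 0, "dose_max_mg": 10, "intensity": "low"},
            {"molecule": "x", "dose_min_mg": 10, "dose_max_mg": 20, "intensity": "moderate"},
        ]
        with pytest.raises(CatalogError):
            StatinCatalog.from_records(records)

    def test_catalog_record_round_trip(self, catalog):
        rebuilt = StatinCatalog.from_records(catalog.to_records())
        assert rebuilt.classify("pravastatin", 999.0) == (Intensity.low, True)
        assert rebuilt.to_records() == catalog.to_records()


class TestTimeline:
    def test_continuous_use_single_episode(self, config, catalog):
        p = patient(quarterly(1020, 30))
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert len(tl.statin_episodes) == 1
        assert tl.gaps == []
        assert tl.latest_statin is not None
        assert not tl.long_term_discontinued
        assert not tl.permanently_discontinued
        assert not tl.statin_free_at_index

    def test_supply_end_200_days_before_index_is_permanent(self, config, catalog):
        # last 90-day supply starts 290 d before index, ends 200 d before
        p = patient(quarterly(650, 290))
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert tl.long_term_discontinued
        assert tl.permanently_discontinued
        assert tl.statin_free_at_index

    def test_exact_180_day_gap_is_not_discontinuation(self, config, catalog):
        p = patient(quarterly(360, 270))  # supply ends 180 d before index
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert tl.gaps[-1].length_days == 180
        assert not tl.long_term_discontinued

    def test_same_day_duplicates_keep_higher_intensity(self, config, catalog):
        p = patient([rx(100, "simvastatin", 10.0), rx(100, "atorvastatin", 80.0)])
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert len(tl.statin_episodes) == 1
        assert tl.statin_episodes[0].molecule == "atorvastatin"
        assert tl.statin_episodes[0].intensity is Intensity.high

    def test_interrupted_then_resumed_is_long_term_but_not_permanent(self, config, catalog):
        p = patient(quarterly(900, 810) + quarterly(400, 40))  # 320-day hole, then resumed
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert tl.long_term_discontinued
        assert not tl.permanently_discontinued
        assert not tl.statin_free_at_index

    def test_regimen_change_splits_episodes(self, config, catalog):
        p = patient(
            quarterly(900, 720, molecule="atorvastatin", dose=40.0)
            + quarterly(630, 30, molecule="pravastatin", dose=20.0)
        )
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert [e.molecule for e in tl.statin_episodes] == ["atorvastatin", "pravastatin"]

    def test_events_outside_lookback_ignored(self, config, catalog):
        p = patient([rx(2000)])
        tl = build_llt_timeline(p, INDEX, config, catalog)
        assert tl.statin_episodes == []
        assert tl.statin_free_at_index
        assert not tl.long_term_discontinued

    def test_shrinking_gap_threshold_never_hides_discontinuation(self, catalog):
        p = patient(quarterly(650, 290))
        wide = build_llt_timeline(p, INDEX, SelectionConfig(discontinuation_gap_days=180), catalog)
        narrow = build_llt_timeline(p, INDEX, SelectionConfig(discontinuation_gap_days=90), catalog)
        assert wide.long_term_discontinued
        assert narrow.long_term_discontinued


@st.composite
def random_timeline(draw):
    n = draw(st.integers(1, 50))
    offsets = draw(st.lists(st.integers(1, 1000), min_size=n, max_size=n, unique=True))
    supplies = draw(st.lists(st.integers(10, 180), min_size=n, max_size=n))
    return [rx(off, supply=s) for off, s in zip(offsets, supplies)]


@settings(max_examples=120, deadline=None, derandomize=True)
@given(random_timeline())
def test_gap_detection_matches_day_by_day_scan(prescriptions):
    """Hole detection on merged supply intervals agrees with brute-force coverage."""
    config = SelectionConfig()
    catalog = StatinCatalog()
    tl = build_llt_timeline(patient(prescriptions), INDEX, config, catalog)

    covered_all = set()
    for p in prescriptions:
        for k in range(p.supply_days):
            covered_all.add(p.date + dt.timedelta(days=k))
    covered = {d for d in covered_all if d < INDEX}
    first = min(p.date for p in prescriptions)
    uncovered_runs = []
    run = 0
    day = first
    while day < INDEX:
        if day in covered:
            if run:
                uncovered_runs.append(run)
            run = 0
        else:
            run += 1
        day += dt.timedelta(days=1)
    trailing = run
    if run:
        uncovered_runs.append(run)

    gap_days = config.discontinuation_gap_days
    assert sorted(g.length_days for g in tl.gaps) == sorted(uncovered_runs)
    assert tl.long_term_discontinued == any(g > gap_days for g in uncovered_runs)
    assert tl.permanently_discontinued == (trailing > gap_days)
    assert tl.statin_free_at_index == (INDEX not in covered_all)
    # permanent implies long-term implies some gap
    if tl.permanently_discontinued:
        assert tl.long_term_discontinued and tl.statin_free_at_index
    # episode intervals jointly cover every supplied day
    episode_days = set()
    for e in tl.statin_episodes:
        day = e.start
        while day < min(e.end, INDEX):
            episode_days.add(day)
            day += dt.timedelta(days=1)
    assert covered <= episode_days


class TestIndexLdl:
    def test_latest_valid_measurement_wins(self, config):
        p = patient(labs=[lab(61, 120.0), lab(0, 110.0)])  # 2021-03-01 and 2021-05-01
        chosen = select_index_ldl(p, config)
        assert chosen is not None and chosen.date == INDEX and chosen.value == 110.0

    def test_measurement_too_soon_after_new_llt_start_is_invalid(self, config):
        p = patient(prescriptions=[rx(10)], labs=[lab(0, 120.0)])
        assert select_index_ldl(p, config) is None

    def test_falls_back_to_earlier_valid_measurement(self, config):
        p = patient(prescriptions=[rx(10)], labs=[lab(90, 130.0), lab(0, 120.0)])
        chosen = select_index_ldl(p, config)
        assert chosen is not None and chosen.value == 130.0

    def test_no_measurement_in_window(self, config):
        p = patient(labs=[lab(600, 140.0)])
        assert select_index_ldl(p, config) is None

    def test_stable_regimen_measurement_is_valid(self, config):
        p = patient(prescriptions=quarterly(400, 40), labs=[lab(0, 95.0)])
        chosen = select_index_ldl(p, config)
        assert chosen is not None and chosen.value == 95.0

    def test_refill_gap_does_not_reset_regimen_start(self, config):
        # 100-day hole, then refill 20 d before the draw: same regimen, still valid
        p = patient(prescriptions=[rx(300), rx(110), rx(20)], labs=[lab(0, 95.0)])
        assert select_index_ldl(p, config) is not None


class TestTrimOutliers:
    def test_distinct_grid_removes_single_min_and_max(self):
        values = np.arange(1000, dtype=float) + 50.0
        mask = trim_outliers(values, 0.001)
        assert mask.sum() == 998
        assert not mask[0] and not mask[-1]

    def test_identical_values_untouched(self):
        assert trim_outliers([7.0] * 50, 0.001).all()

    def test_tiny_sample_untouched(self):
        assert trim_outliers([1.0, 2.0, 3.0], 0.001).all()

    def test_empty_input(self):
        assert trim_outliers([], 0.001).size == 0

    def test_retained_count_lower_bound(self):
        rng = np.random.default_rng(5)
        for n in (10, 101, 1234):
            values = rng.normal(100, 30, size=n)
            kept = trim_outliers(values, 0.01).sum()
            assert kept >= int(np.ceil(n * (1 - 0.02))) - 2

    def test_bad_fraction_raises(self):
        with pytest.raises(ValidationError):
            trim_outliers([1.0], 0.5)


class TestCohortIO:
    def _write_tables(self, tmp_path, rows_by_table):
        headers = {
            "patients": "patient_id,sex,age_years",
            "prescriptions": "patient_id,date,drug_class,molecule,dose_mg,supply_days",
            "labs": "patient_id,date,analyte,value_mg_dl",
            "diagnoses": "patient_id,date,category",
        }
        paths = {}
        for name, header in headers.items():
            path = tmp_path / f"{name}.csv"
            path.write_text("\n".join([header] + rows_by_table.get(name, [])) + "\n")
            paths[name] = path
        return paths

    def test_empty_tables_give_empty_cohort(self, tmp_path):
        paths = self._write_tables(tmp_path, {})
        cohort = load_cohort(
            paths["patients"], paths["prescriptions"], paths["labs"], paths["diagnoses"]
        )
        assert cohort == {}

    def test_counts_preserved(self, tmp_path):
        paths = self._write_tables(
            tmp_path,
            {
                "patients": ["A,female,70", "B,male,61.5", "C,female,55"],
                "prescriptions": [
                    f"{pid},2020-0{m}-01,statin,simvastatin,40,90"
                    for pid, m in [("A", 1), ("A", 4), ("A", 7), ("B", 2), ("B", 5), ("C", 3), ("C", 6)]
                ],
            },
        )
        cohort = load_cohort(
            paths["patients"], paths["prescriptions"], paths["labs"], paths["diagnoses"]
        )
        assert len(cohort) == 3
        assert sum(len(r.prescriptions) for r in cohort.values()) == 7

    def test_negative_dose_names_offending_row(self, tmp_path):
        paths = self._write_tables(
            tmp_path,
            {
                "patients": ["A,female,70"],
                "prescriptions": [
                    "A,2020-01-01,statin,simvastatin,40,90",
                    "A,2020-04-01,statin,simvastatin,-10,90",
                ],
            },
        )
        with pytest.raises(ValidationError, match="row 2"):
            load_cohort(paths["patients"], paths["prescriptions"], paths["labs"], paths["diagnoses"])

    def test_bad_date_rejected(self, tmp_path):
        paths = self._write_tables(
            tmp_path,
            {"patients": ["A,female,70"], "labs": ["A,31-01-2021,ldl_c,100"]},
        )
        with pytest.raises(ValidationError, match="labs row 1"):
            load_cohort(paths["patients"], paths["prescriptions"], paths["labs"], paths["diagnoses"])

    def test_missing_file_is_input_error(self, tmp_path):
        paths = self._write_tables(tmp_path, {})
        with pytest.raises(InputError):
            load_cohort(tmp_path / "nope.csv", paths["prescriptions"], paths["labs"], paths["diagnoses"])

    def test_round_trip(self, tmp_path):
        from statinsim import CohortSpec, generate_cohort

        cohort, _ = generate_cohort(CohortSpec(n_patients=40, seed=9))
        paths = write_cohort(cohort, tmp_path)
        reloaded = load_cohort(
            paths["patients"], paths["prescriptions"], paths["labs"], paths["diagnoses"]
        )
        assert reloaded == cohort
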