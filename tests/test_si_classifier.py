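"""Signal detection and declarative SI rule evaluation."""

from __future__ import annotations

import dataclasses

import pytest
import yaml

from statinsim import (
    DiagnosisCategory,
    DrugClass,
    SICategory,
    SIRuleSet,
    build_llt_timeline,
    classify_si,
    detect_signals,
)
from statinsim.errors import ConfigurationError
from statinsim.si_classifier import SIStratum

from conftest import INDEX, dx, patient, quarterly, rx


def signals_for(prescriptions, diagnoses, config, catalog):
    p = patient(prescriptions, diagnoses=diagnoses)
    tl = build_llt_timeline(p, INDEX, config, catalog)
    return detect_signals(tl, p.diagnoses, config), tl


class TestDetectSignals:
    def test_switch_with_down_titration_to_specific_low(self, config, catalog):
        rxs = quarterly(900, 720, molecule="atorvastatin", dose=40.0) + quarterly(
            660, 30, molecule="pravastatin", dose=20.0
        )
        s, _ = signals_for(rxs, [], config, catalog)
        assert s.statin_switch
        assert s.down_titration_different_molecule
        assert s.specific_switch_to_low
        assert not s.down_titration_same_molecule

    def test_same_molecule_down_titration_only(self, config, catalog):
        rxs = quarterly(900, 720, dose=40.0) + quarterly(660, 30, dose=10.0)
        s, _ = signals_for(rxs, [], config, catalog)
        assert s.down_titration_same_molecule
        assert not s.statin_switch
        assert not s.down_titration_different_molecule
        assert not s.specific_switch_to_low

    def test_up_titration_is_not_down_titration(self, config, catalog):
        rxs = quarterly(900, 720, dose=10.0) + quarterly(660, 30, dose=40.0)
        s, _ = signals_for(rxs, [], config, catalog)
        assert not s.down_titration_same_molecule
        assert not s.down_titration_different_molecule

    def test_switch_to_rosuvastatin_5_is_specific(self, config, catalog):
        rxs = quarterly(900, 720, molecule="simvastatin", dose=40.0) + quarterly(
            660, 30, molecule="rosuvastatin", dose=5.0
        )
        s, _ = signals_for(rxs, [], config, catalog)
        assert s.specific_switch_to_low

    def test_switch_to_rosuvastatin_10_is_not_specific(self, config, catalog):
        rxs = quarterly(900, 720, molecule="simvastatin", dose=40.0) + quarterly(
            660, 30, molecule="rosuvastatin", dose=10.0
        )
        s, _ = signals_for(rxs, [], config, catalog)
        assert s.statin_switch and not s.specific_switch_to_low

    def test_two_intermediate_gaps_make_intermittent_dosing(self, config, catalog):
        # supply holes of 100 and 120 days, both in (60, 180]
        rxs = [rx(880), rx(790), rx(600), rx(390), rx(120), rx(30)]
        s, _ = signals_for(rxs, [], config, catalog)
        assert s.intermittent_dosing
        assert not s.long_term_discontinued

    def test_single_gap_is_not_intermittent(self, config, catalog):
        rxs = [rx(600), rx(390), rx(300), rx(210), rx(120), rx(30)]
        s, _ = signals_for(rxs, [], config, catalog)
        assert not s.intermittent_dosing

    def test_note_signals_respect_lookback(self, config, catalog):
        s, _ = signals_for([], [dx(30, DiagnosisCategory.documented_si_note)], config, catalog)
        assert s.documented_si_note
        s, _ = signals_for([], [dx(1200, DiagnosisCategory.documented_si_note)], config, catalog)
        assert not s.documented_si_note

    def test_empty_timeline_all_false(self, config, catalog):
        s, _ = signals_for([], [], config, catalog)
        assert not any(v for k, v in s.as_dict().items() if k != "statin_free_at_index")

    def test_nonstatin_llt_present(self, config, catalog):
        rxs = quarterly(400, 40, molecule="ezetimibe", dose=10.0, drug_class=DrugClass.ezetimibe)
        s, _ = signals_for(rxs, [], config, catalog)
        assert s.nonstatin_llt_present


class TestClassifySI:
    def test_documented_si_with_permanent_discontinuation_is_absolute(self, config, catalog):
        rxs = quarterly(900, 380) + quarterly(
            400, 40, molecule="ezetimibe", dose=10.0, drug_class=DrugClass.ezetimibe
        )
        s, tl = signals_for(rxs, [dx(200, DiagnosisCategory.documented_si_note)], config, catalog)
        cls = classify_si(s, tl)
        assert cls.category is SICategory.absolute
        assert "abs_documented_si" in cls.fired_rules
        assert cls.stratum is SIStratum.only_nonstatin_llt

    def test_specific_switch_with_continued_use_is_partial(self, config, catalog):
        rxs = quarterly(900, 720, molecule="atorvastatin", dose=40.0) + quarterly(
            660, 30, molecule="pravastatin", dose=20.0
        )
        s, tl = signals_for(rxs, [], config, catalog)
        cls = classify_si(s, tl)
        assert cls.category is SICategory.partial
        assert "part_specific_switch_to_low" in cls.fired_rules

    def test_stable_moderate_monotherapy_is_none(self, config, catalog):
        s, tl = signals_for(quarterly(900, 30, dose=40.0), [], config, catalog)
        cls = classify_si(s, tl)
        assert cls.category is SICategory.none
        assert cls.fired_rules == ()

    def test_statin_naive_with_no_events_is_none(self, config, catalog):
        s, tl = signals_for([], [], config, catalog)
        assert classify_si(s, tl).category is SICategory.none

    def test_si_note_with_long_gap_then_resumed_statin_is_not_partial(self, config, catalog):
        # >180-day interruption violates the continued-use requirement
        rxs = quarterly(900, 810) + quarterly(400, 40)
        s, tl = signals_for(rxs, [dx(200, DiagnosisCategory.documented_si_note)], config, catalog)
        assert classify_si(s, tl).category is SICategory.none

    def test_absolute_wins_over_partial(self, config, catalog):
        ruleset = SIRuleSet(
            {
                "absolute": {"a": "documented_si_note"},
                "partial": {"p": "documented_si_note"},
            }
        )
        rxs = quarterly(900, 30, dose=40.0)
        s, tl = signals_for(rxs, [dx(100, DiagnosisCategory.documented_si_note)], config, catalog)
        cls = classify_si(s, tl, ruleset)
        assert cls.category is SICategory.absolute and cls.fired_rules == ("a",)

    def test_adding_documented_note_never_demotes(self, config, catalog):
        cases = [
            quarterly(900, 720, molecule="atorvastatin", dose=40.0)
            + quarterly(660, 30, molecule="pravastatin", dose=20.0),
            quarterly(900, 380),
        ]
        order = {SICategory.none: 0, SICategory.partial: 1, SICategory.absolute: 2}
        for rxs in cases:
            s0, tl = signals_for(rxs, [], config, catalog)
            s1, _ = signals_for(rxs, [dx(100, DiagnosisCategory.documented_si_note)], config, catalog)
            before = classify_si(s0, tl).category
            after = classify_si(s1, tl).category
            assert order[after] >= order[before]

    def test_unknown_signal_name_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown signal"):
            SIRuleSet({"absolute": {"bad": "permanently_discontinued and flux_capacitor"}})

    def test_non_boolean_expression_rejected(self):
        with pytest.raises(ConfigurationError):
            SIRuleSet({"absolute": {"bad": "__import__('os')"}})

    def test_rules_config_round_trip(self, config, catalog):
        ruleset = SIRuleSet()
        reloaded = SIRuleSet.from_dict(yaml.safe_load(yaml.safe_dump(ruleset.to_dict())))
        fixtures = [
            quarterly(900, 380),
            quarterly(900, 720, molecule="atorvastatin", dose=40.0)
            + quarterly(660, 30, molecule="pravastatin", dose=20.0),
            quarterly(900, 30, dose=40.0),
        ]
        for rxs in fixtures:
            s, tl = signals_for(rxs, [dx(100, DiagnosisCategory.sams)], config, catalog)
            assert classify_si(s, tl, ruleset) == classify_si(s, tl, reloaded)

    def test_every_patient_gets_exactly_one_category(self, config, catalog):
        from statinsim import CohortSpec, generate_cohort, run_pipeline

        cohort, _ = generate_cohort(CohortSpec(n_patients=120, seed=3))
        result = run_pipeline(cohort)
        assert all(
            p.classification.category in SICategory for p in result.patients.values()
        )
        for p in result.patients.values():
            assert (p.classification.category is not SICategory.none) == bool(
                p.classification.fired_rules
            )
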