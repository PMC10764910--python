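"""Rule-based statin-intolerance (SI) phenotyping from prescription timelines.

Two layers: :func:`detect_signals` turns a lipid-lowering timeline plus
diagnosis events into a flat set of boolean signals (down-titration, switch,
documented SI note, intermittent dosing, ...), and :func:`classify_si`
evaluates a declarative rule set over those signals to label each patient
absolute SI (SI events with permanent statin discontinuation), partial SI
(SI events with continued statin use) or none. The rule set lives in config
as boolean expressions over signal names, so alternative operationalisations
are drop-in replacements.
"""

from __future__ import annotations

import ast
import datetime as dt
from dataclasses import dataclass, asdict, fields
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .config import SelectionConfig
from .emr_model import (
    DiagnosisCategory,
    DiagnosisEvent,
    DrugClass,
    Intensity,
    LLTTimeline,
)
from .errors import ConfigurationError

#: origin molecules of the specific low-potency switch rule
_SPECIFIC_SWITCH_FROM = {"atorvastatin", "simvastatin"}


@dataclass(frozen=True)
class SISignalSet:
    """Boolean prescription-pattern and documentation signals for one patient."""

    down_titration_same_molecule: bool = False
    down_titration_different_molecule: bool = False
    statin_switch: bool = False
    specific_switch_to_low: bool = False
    documented_si_note: bool = False
    sams_event: bool = False
    other_si_event: bool = False
    intermittent_dosing: bool = False
    low_dose_latest_statin: bool = False
    nonstatin_llt_present: bool = False
    discontinued_latest_statin: bool = False
    long_term_discontinued: bool = False
    permanently_discontinued: bool = False
    statin_free_at_index: bool = False

    def as_dict(self) -> dict[str, bool]:
        return asdict(self)


SIGNAL_NAMES = tuple(f.name for f in fields(SISignalSet))


class SICategory(str, Enum):
    absolute = "absolute"
    partial = "partial"
    none = "none"


class SIStratum(str, Enum):
    only_nonstatin_llt = "only_nonstatin_llt"
    low_dose_latest = "low_dose_latest"
    other = "other"


@dataclass(frozen=True)
class SIClassification:
    category: SICategory
    fired_rules: tuple[str, ...]
    stratum: SIStratum


def detect_signals(
    timeline: LLTTimeline,
    diagnoses: Sequence[DiagnosisEvent],
    config: SelectionConfig,
) -> SISignalSet:
    """Compute the signal set from a timeline built over the SI look-back.

    Down-titration is any later statin episode of strictly lower intensity
    rank than an earlier one (same- and different-molecule variants tracked
    separately); a switch is a molecule change between consecutive episodes;
    the specific low-potency switch is atorvastatin/simvastatin (any dose) to
    5 mg rosuvastatin or any-dose pravastatin/fluvastatin. Intermittent
    dosing needs at least two supply gaps, each inside
    ``(intermittent_min_gap_days, discontinuation_gap_days]``. Note-based
    signals are read from diagnosis categories within the look-back window.
    """
    episodes = timeline.statin_episodes
    index = timeline.index_date
    lookback_start = index - dt.timedelta(days=config.si_lookback_days)

    down_same = down_diff = switch = specific = False
    for i, earlier in enumerate(episodes):
        for later in episodes[i + 1 :]:
            if later.intensity_rank < earlier.intensity_rank:
                if later.molecule == earlier.molecule:
                    down_same = True
                else:
                    down_diff = True
    for prev, nxt in zip(episodes, episodes[1:]):
        if nxt.molecule != prev.molecule:
            switch = True
            if prev.molecule in _SPECIFIC_SWITCH_FROM and (
                nxt.molecule in {"pravastatin", "fluvastatin"}
                or (nxt.molecule == "rosuvastatin" and nxt.dose_mg == 5.0)
            ):
                specific = True

    intermittent_gaps = [
        g
        for g in timeline.gaps
        if config.intermittent_min_gap_days < g.length_days <= config.discontinuation_gap_days
    ]

    in_window = {
        d.category
        for d in diagnoses
        if lookback_start <= d.date <= index
    }

    latest = timeline.latest_statin
    return SISignalSet(
        down_titration_same_molecule=down_same,
        down_titration_different_molecule=down_diff,
        statin_switch=switch,
        specific_switch_to_low=specific,
        documented_si_note=DiagnosisCategory.documented_si_note in in_window,
        sams_event=DiagnosisCategory.sams in in_window,
        other_si_event=DiagnosisCategory.other_si_event in in_window,
        intermittent_dosing=len(intermittent_gaps) >= 2,
        low_dose_latest_statin=latest is not None and latest.intensity is Intensity.low,
        nonstatin_llt_present=bool(timeline.latest_llt_classes - {DrugClass.statin}),
        discontinued_latest_statin=latest is not None and timeline.statin_free_at_index,
        long_term_discontinued=timeline.long_term_discontinued,
        permanently_discontinued=timeline.permanently_discontinued,
        statin_free_at_index=timeline.statin_free_at_index,
    )


# ---------------------------------------------------------------------------
# Declarative rule evaluation
# ---------------------------------------------------------------------------

#: Default rule set. Absolute SI = permanent statin discontinuation plus any
#: SI signal; partial SI = continued statin use (no long-term gap, statin
#: active at index) plus one of the listed signal combinations. Each named
#: rule is one boolean expression over signal names.
DEFAULT_RULES: dict[str, dict[str, str]] = {
    "absolute": {
        "abs_documented_si": "permanently_discontinued and documented_si_note",
        "abs_sams": "permanently_discontinued and sams_event",
        "abs_other_si_event": "permanently_discontinued and other_si_event",
        "abs_down_titration": (
            "permanently_discontinued and "
            "(down_titration_same_molecule or down_titration_different_molecule)"
        ),
        "abs_statin_switch": "permanently_discontinued and statin_switch",
        "abs_intermittent_dosing": "permanently_discontinued and intermittent_dosing",
        "abs_low_dose_latest": "permanently_discontinued and low_dose_latest_statin",
    },
    "partial": {
        "part_specific_switch_to_low": (
            "not long_term_discontinued and not statin_free_at_index "
            "and specific_switch_to_low"
        ),
        "part_down_titration_different": (
            "not long_term_discontinued and not statin_free_at_index "
            "and down_titration_different_molecule"
        ),
        "part_documented_si": (
            "not long_term_discontinued and not statin_free_at_index "
            "and documented_si_note"
        ),
        "part_down_same_with_switch": (
            "not long_term_discontinued and not statin_free_at_index "
            "and down_titration_same_molecule and statin_switch"
        ),
        "part_low_dose_plus_nonstatin": (
            "not long_term_discontinued and not statin_free_at_index "
            "and low_dose_latest_statin and nonstatin_llt_present"
        ),
    },
}


def _compile_rule(name: str, expression: str):
    """Parse one boolean expression over signal names into a safe evaluator."""
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ConfigurationError(f"rule {name!r}: cannot parse {expression!r}") from exc

    def check(node: ast.AST) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.BoolOp):
            for v in node.values:
                check(v)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            check(node.operand)
        elif isinstance(node, ast.Name):
            if node.id not in SIGNAL_NAMES:
                raise ConfigurationError(f"rule {name!r}: unknown signal {node.id!r}")
        else:
            raise ConfigurationError(
                f"rule {name!r}: only and/or/not over signal names are allowed"
            )

    check(tree)
    code = compile(tree, f"<rule {name}>", "eval")

    def evaluate(signals: Mapping[str, bool]) -> bool:
        return bool(eval(code, {"__builtins__": {}}, dict(signals)))

    return evaluate


class SIRuleSet:
    """Compiled absolute/partial rule expressions with precedence absolute > partial."""

    def __init__(self, rules: Mapping[str, Mapping[str, str]] | None = None):
        rules = DEFAULT_RULES if rules is None else rules
        unknown = set(rules) - {"absolute", "partial"}
        if unknown:
            raise ConfigurationError(f"unknown rule sections: {sorted(unknown)}")
        self.expressions: dict[str, dict[str, str]] = {
            section: dict(rules.get(section, {})) for section in ("absolute", "partial")
        }
        self._compiled = {
            section: {name: _compile_rule(name, expr) for name, expr in exprs.items()}
            for section, exprs in self.expressions.items()
        }

    def to_dict(self) -> dict[str, dict[str, str]]:
        return {s: dict(e) for s, e in self.expressions.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, str]]) -> "SIRuleSet":
        return cls(d)

    def fired(self, section: str, signals: Mapping[str, bool]) -> list[str]:
        # sorted so the output is independent of config-file key order
        return sorted(name for name, fn in self._compiled[section].items() if fn(signals))


def classify_si(
    signals: SISignalSet,
    timeline: LLTTimeline,
    rules: SIRuleSet | None = None,
) -> SIClassification:
    """Evaluate the rule set; absolute takes precedence over partial.

    The stratum reports the latest-prescription stratum used in descriptive
    tables: only non-statin lipid-lowering drugs at index, a low-intensity
    statin as latest prescription, or anything else.
    """
    if rules is None:
        rules = SIRuleSet()
    signal_map = signals.as_dict()

    fired = rules.fired("absolute", signal_map)
    category = SICategory.absolute
    if not fired:
        fired = rules.fired("partial", signal_map)
        category = SICategory.partial if fired else SICategory.none

    if signals.statin_free_at_index and signals.nonstatin_llt_present:
        stratum = SIStratum.only_nonstatin_llt
    elif signals.low_dose_latest_statin:
        stratum = SIStratum.low_dose_latest
    else:
        stratum = SIStratum.other
    return SIClassification(category=category, fired_rules=tuple(fired), stratum=stratum)
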