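"""Summary tables and arithmetic helpers for cohort and simulation reports.

All percentages are printed to one decimal with round-half-up, and every
percentage is recomputed from the counts in its own table.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP
from typing import Mapping

import pandas as pd

from .errors import ConsistencyError, ValidationError
from .risk_targets import RiskCategory, RiskProfile
from .si_classifier import SICategory, SIClassification
from .treatment_sim import STAGES, SimulationResult


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at the cut rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denominator: float, decimals: int = 1) -> float:
    """Share of ``denominator`` as a percentage, one decimal, round-half-up."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, decimals)


_ROWS = ("all", "absolute_si", "partial_si", "no_si")
_CATEGORY_ROW = {
    SICategory.absolute: "absolute_si",
    SICategory.partial: "partial_si",
    SICategory.none: "no_si",
}


def summarize_prevalence(
    classifications: Mapping[str, SIClassification | SICategory],
    risk_profiles: Mapping[str, RiskProfile | RiskCategory],
) -> pd.DataFrame:
    """SI prevalence stratified by cardiovascular risk.

    Rows all/absolute/partial/none; count and percent-of-total-cohort columns
    for the total and for each risk category. Counts are additive by
    construction; a classified patient without a risk profile is an error.
    """
    counts = {row: {"total": 0, "very_high": 0, "high": 0} for row in _ROWS}
    for pid, cls in classifications.items():
        if pid not in risk_profiles:
            raise ConsistencyError(f"patient {pid!r} classified but has no risk profile")
        category = cls.category if isinstance(cls, SIClassification) else SICategory(cls)
        risk = risk_profiles[pid]
        risk_cat = risk.category if isinstance(risk, RiskProfile) else RiskCategory(risk)
        for row in ("all", _CATEGORY_ROW[category]):
            counts[row]["total"] += 1
            counts[row][risk_cat.value] += 1

    n = counts["all"]["total"]
    table = pd.DataFrame(
        [
            {
                "group": row,
                "total_n": counts[row]["total"],
                "total_pct": percent(counts[row]["total"], n),
                "very_high_n": counts[row]["very_high"],
                "very_high_pct": percent(counts[row]["very_high"], n),
                "high_n": counts[row]["high"],
                "high_pct": percent(counts[row]["high"], n),
            }
            for row in _ROWS
        ]
    )
    return table.set_index("group")


def relative_reduction(baseline_mg_dl: float, post_mg_dl: float) -> float:
    """Percent LDL-C reduction from baseline, one decimal, round-half-up."""
    if baseline_mg_dl <= 0:
        raise ValidationError("baseline must be positive")
    if post_mg_dl > baseline_mg_dl:
        raise ValidationError("post-treatment LDL-C exceeds baseline")
    return round_half_up(100.0 * (baseline_mg_dl - post_mg_dl) / baseline_mg_dl, 1)


def bonferroni_threshold(alpha: float, n_comparisons: int, decimals: int = 5) -> float:
    """Bonferroni-corrected significance threshold, truncated at the printed precision."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if n_comparisons < 1:
        raise ValidationError(f"n_comparisons must be >= 1, got {n_comparisons}")
    raw = Decimal(repr(alpha)) / Decimal(n_comparisons)
    return float(raw.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_DOWN))


def stage_summary_table(sim: SimulationResult, n_si_total: int | None = None) -> pd.DataFrame:
    """Per-stage attainment and LDL-C summary in both denominator conventions.

    ``cumulative_pct_entering`` divides the median at-goal count by the
    cohort entering the simulation; ``prior_step_pct`` is the share of
    patients newly reaching goal among those above goal after the previous
    stage (the treatment-algorithm convention); ``cumulative_pct_si_total``
    optionally uses the full SI cohort including baseline-drug exclusions.
    """
    rows = []
    prev_count = None
    for stage in sim.stages:
        row = {
            "stage": stage.stage,
            "median_count_at_target": stage.median_count_at_target,
            "cumulative_pct_entering": percent(stage.median_count_at_target, sim.n_entering),
            "median_of_means_ldl": round_half_up(stage.median_of_means_ldl, 1),
            "median_ldl": round_half_up(stage.median_of_medians_ldl, 1),
            "relative_reduction_pct": round_half_up(stage.relative_reduction_percent, 1),
        }
        if prev_count is None:
            row["prior_step_pct"] = row["cumulative_pct_entering"]
        else:
            newly = stage.median_count_at_target - prev_count
            row["prior_step_pct"] = percent(newly, sim.n_entering - prev_count)
        if n_si_total:
            row["cumulative_pct_si_total"] = percent(stage.median_count_at_target, n_si_total)
        prev_count = stage.median_count_at_target
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")


def attainment_by_risk(sim_states, sim_config) -> pd.DataFrame:
    """Final-stage attainment split by risk category (median count per stratum)."""
    import numpy as np

    from .treatment_sim import run_monte_carlo

    rows = []
    for cat in (RiskCategory.high, RiskCategory.very_high):
        subset = [s for s in sim_states if s.risk_category is cat]
        if not subset:
            continue
        res = run_monte_carlo(subset, sim_config)
        final = res.stage(STAGES[-1])
        rows.append(
            {
                "risk_category": cat.value,
                "n_entering": res.n_entering,
                "final_median_count_at_target": final.median_count_at_target,
                "final_pct_at_target": percent(final.median_count_at_target, res.n_entering),
            }
        )
    return pd.DataFrame(rows).set_index("risk_category")
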