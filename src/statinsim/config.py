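"""Study-selection configuration and YAML round-tripping.

All interval arithmetic in the package is in whole calendar days and every
interval is half-open ``[start, end)``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class SelectionConfig:
    """Windows and thresholds anchoring every cohort filter to the index date.

    Parameters
    ----------
    selection_start, selection_end
        Half-open selection window for the index LDL-C measurement
        (default July 2020 – June 2021).
    si_lookback_days
        Look-back before the index date for statin-intolerance signals
        (default 1095 d ≈ 3 years).
    risk_lookback_days
        Look-back for modifiable risk factors (hypertension, smoking;
        default 365 d).
    ckd_lookback_days
        Look-back for chronic kidney disease (default 1825 d ≈ 60 months).
    llt_stability_days
        Minimum days a lipid-lowering regimen must precede an LDL-C
        measurement for the value to count (default 28 d = 4 weeks).
    discontinuation_gap_days
        A statin-free supply gap strictly longer than this marks long-term
        discontinuation (default 180 d).
    intermittent_min_gap_days
        Lower bound of the intermittent-dosing gap band; gaps in
        ``(intermittent_min_gap_days, discontinuation_gap_days]`` count
        (default 60 d — shorter gaps are refill noise).
    outlier_trim_fraction
        Per-tail fraction of pooled LDL-C values excluded as laboratory
        outliers (default 0.001).
    default_supply_days
        Supply duration assumed when a prescription row carries none
        (default 90 d, typical quarterly prescribing).
    """

    selection_start: dt.date = dt.date(2020, 7, 1)
    selection_end: dt.date = dt.date(2021, 7, 1)
    si_lookback_days: int = 1095
    risk_lookback_days: int = 365
    ckd_lookback_days: int = 1825
    llt_stability_days: int = 28
    discontinuation_gap_days: int = 180
    intermittent_min_gap_days: int = 60
    outlier_trim_fraction: float = 0.001
    default_supply_days: int = 90

    def __post_init__(self) -> None:
        day_fields = (
            "si_lookback_days",
            "risk_lookback_days",
            "ckd_lookback_days",
            "llt_stability_days",
            "discontinuation_gap_days",
            "intermittent_min_gap_days",
            "default_supply_days",
        )
        for name in day_fields:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 <= self.outlier_trim_fraction < 0.5):
            raise ConfigurationError(
                f"outlier_trim_fraction must lie in [0, 0.5), got {self.outlier_trim_fraction}"
            )
        if self.selection_start >= self.selection_end:
            raise ConfigurationError("selection window is empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection_start"] = self.selection_start.isoformat()
        d["selection_end"] = self.selection_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionConfig":
        d = dict(d)
        for key in ("selection_start", "selection_end"):
            if key in d and isinstance(d[key], str):
                d[key] = dt.date.fromisoformat(d[key])
        return cls(**d)


def load_config(path: str | Path) -> dict:
    """Load the full structured config file (YAML mapping of sections)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return data


def save_config(data: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)
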