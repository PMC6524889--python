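"""YEARS triage: stratum assignment and CTPA indication.

The YEARS rule scores three clinical items (clinical signs of deep-vein
thrombosis, hemoptysis, and "PE the most likely diagnosis") and applies a
pretest-dependent D-dimer threshold: patients with no item present need a
D-dimer of at least 1000 ng/mL to be referred for CTPA, patients with one
or more items at least 500 ng/mL. Below the applicable threshold PE is
considered ruled out without imaging.

Thresholds and the boundary convention live in :class:`TriageConfig` so
variants are testable; the defaults are the rule as published.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .cohort import PatientRecord

__all__ = [
    "DEFAULT_CONFIG",
    "Stratum",
    "TriageConfig",
    "TriageDecision",
    "TriageSummary",
    "classify_patient",
    "triage_cohort",
]


class Stratum(str, enum.Enum):
    """The four YEARS strata (item count × D-dimer side)."""

    ITEMS0_LOW_DD = "items0_low_dd"
    ITEMS0_HIGH_DD = "items0_high_dd"
    ITEMS1PLUS_LOW_DD = "items1plus_low_dd"
    ITEMS1PLUS_HIGH_DD = "items1plus_high_dd"


#: Strata in which CTPA is indicated.
CTPA_STRATA = frozenset({Stratum.ITEMS0_HIGH_DD, Stratum.ITEMS1PLUS_HIGH_DD})


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the decision rule.

    ``boundary_inclusive=True`` sends a D-dimer exactly at threshold to
    CTPA (conservative toward imaging).
    """

    dd_threshold_items0: float = 1000.0
    dd_threshold_items1plus: float = 500.0
    boundary_inclusive: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "TriageConfig":
        """Load a config from YAML (or JSON, a YAML subset)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


DEFAULT_CONFIG = TriageConfig()


@dataclass(frozen=True)
class TriageDecision:
    stratum: Stratum
    ctpa_indicated: bool
    pe_excluded_without_imaging: bool

    def __post_init__(self) -> None:
        if self.ctpa_indicated == self.pe_excluded_without_imaging:
            raise ValueError("ctpa_indicated and exclusion are exclusive")


def classify_patient(
    years_items: int,
    ddimer_ng_ml: float,
    config: TriageConfig = DEFAULT_CONFIG,
) -> TriageDecision:
    """Apply the YEARS rule to one patient.

    Pure function of its inputs; raises ``ValueError`` on out-of-range
    inputs (negative or NaN D-dimer, item count outside 0–3).
    """
    if years_items not in (0, 1, 2, 3):
        raise ValueError(f"years_items must be 0-3, got {years_items!r}")
    if not ddimer_ng_ml >= 0:
        raise ValueError(f"ddimer_ng_ml must be non-negative, got {ddimer_ng_ml!r}")
    threshold = (
        config.dd_threshold_items0
        if years_items == 0
        else config.dd_threshold_items1plus
    )
    high = (
        ddimer_ng_ml >= threshold
        if config.boundary_inclusive
        else ddimer_ng_ml > threshold
    )
    if years_items == 0:
        stratum = Stratum.ITEMS0_HIGH_DD if high else Stratum.ITEMS0_LOW_DD
    else:
        stratum = Stratum.ITEMS1PLUS_HIGH_DD if high else Stratum.ITEMS1PLUS_LOW_DD
    return TriageDecision(
        stratum=stratum,
        ctpa_indicated=high,
        pe_excluded_without_imaging=not high,
    )


@dataclass(frozen=True)
class TriageSummary:
    """Per-stratum counts and the overall CTPA fraction of a cohort."""

    counts: dict[Stratum, int]
    n: int
    ctpa_fraction: float | None  # None for an empty cohort

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": {s.value: c for s, c in self.counts.items()},
            "ctpa_fraction": self.ctpa_fraction,
        }


def triage_cohort(
    records: Sequence[PatientRecord],
    config: TriageConfig = DEFAULT_CONFIG,
) -> TriageSummary:
    """Triage every patient; the four strata partition the cohort."""
    counter = Counter(
        classify_patient(r.years_items, r.ddimer_ng_ml, config).stratum
        for r in records
    )
    counts = {s: counter.get(s, 0) for s in Stratum}
    n = len(records)
    n_ctpa = sum(counts[s] for s in CTPA_STRATA)
    return TriageSummary(
        counts=counts,
        n=n,
        ctpa_fraction=None if n == 0 else n_ctpa / n,
    )
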