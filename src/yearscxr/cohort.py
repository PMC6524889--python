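"""Patient-level cohort model and I/O for a suspected-PE diagnostic study.

One record per patient presenting with suspected pulmonary embolism (PE):
the count of YEARS clinical items, the D-dimer concentration, a single
chest-radiograph (CXR) finding category, and the diagnostic outcome.
Cohorts round-trip through a plain CSV schema; group-wise finding counts
are tabulated into :class:`CohortTable` objects.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ABNORMAL_FINDINGS",
    "CSV_COLUMNS",
    "FINDING_ORDER",
    "GROUP_LABELS",
    "CohortTable",
    "CohortValidationError",
    "CxrFinding",
    "PatientRecord",
    "read_cohort_csv",
    "tabulate",
    "write_cohort_csv",
]


class CxrFinding(str, enum.Enum):
    """Single dominant chest-radiograph finding.

    Categories are mutually exclusive and exhaustive: a patient whose
    radiograph shows several abnormalities is coded to one dominant
    category by the data producer, so group-wise counts sum exactly to
    group totals.
    """

    NORMAL = "normal"
    PLEURAL_EFFUSION = "pleural_effusion"
    CONSOLIDATION = "consolidation"
    MALIGNANCY_MASS = "malignancy_mass"
    CONGESTIVE_HEART_FAILURE = "congestive_heart_failure"
    PNEUMOTHORAX = "pneumothorax"
    RIB_FRACTURE = "rib_fracture"
    ATELECTASIS = "atelectasis"


#: Canonical row order for tables and probability vectors.
FINDING_ORDER: tuple[CxrFinding, ...] = tuple(CxrFinding)

#: The seven abnormal categories ("abnormal CXR" = any of these).
ABNORMAL_FINDINGS: tuple[CxrFinding, ...] = tuple(
    f for f in CxrFinding if f is not CxrFinding.NORMAL
)

#: Patient groups recognised by :func:`tabulate` (YEARS strata are also
#: accepted; see :mod:`yearscxr.triage`).
GROUP_LABELS: tuple[str, ...] = (
    "all",
    "pe",
    "no_pe",
    "ctpa_indicated",
    "ctpa_not_indicated",
)

#: Stable column order of the patient CSV schema.
CSV_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "years_items",
    "ddimer_ng_ml",
    "cxr_finding",
    "pe_confirmed",
    "ctpa_indicated",
)


class CohortValidationError(ValueError):
    """A record or CSV row violates the cohort schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One suspected-PE patient.

    Parameters
    ----------
    patient_id
        Opaque identifier.
    years_items
        Number of YEARS items present (0–3). Item identity is not kept:
        the triage rule only distinguishes 0 from ≥1 items.
    ddimer_ng_ml
        D-dimer concentration in ng/mL (≥ 0).
    cxr
        Dominant CXR finding, or ``None`` when no radiograph was taken.
        Records without a CXR are representable but must be filtered out
        before any finding-based statistics.
    pe_confirmed
        PE diagnosed on CTPA at baseline.
    ctpa_indicated
        CTPA indicated by the YEARS rule. A confirmed PE implies CTPA was
        indicated, since the algorithm diagnoses PE only via CTPA.
    """

    patient_id: str
    years_items: int
    ddimer_ng_ml: float
    cxr: CxrFinding | None
    pe_confirmed: bool
    ctpa_indicated: bool

    def __post_init__(self) -> None:
        if self.years_items not in (0, 1, 2, 3):
            raise CohortValidationError(
                f"years_items must be 0-3, got {self.years_items!r}"
            )
        if not self.ddimer_ng_ml >= 0:  # also rejects NaN
            raise CohortValidationError(
                f"ddimer_ng_ml must be non-negative, got {self.ddimer_ng_ml!r}"
            )
        if self.pe_confirmed and not self.ctpa_indicated:
            raise CohortValidationError(
                "pe_confirmed=True requires ctpa_indicated=True: "
                "PE is only diagnosed via CTPA under the algorithm"
            )

    @property
    def has_cxr(self) -> bool:
        return self.cxr is not None


@dataclass(frozen=True)
class CohortTable:
    """Finding counts for one patient group.

    ``counts`` maps every :class:`CxrFinding` to a non-negative count and
    sums exactly to ``total``.
    """

    group: str
    counts: dict[CxrFinding, int]
    total: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(CxrFinding):
            raise CohortValidationError("counts must cover every CxrFinding")
        if any(v < 0 for v in self.counts.values()):
            raise CohortValidationError("counts must be non-negative")
        if sum(self.counts.values()) != self.total:
            raise CohortValidationError(
                f"counts sum {sum(self.counts.values())} != total {self.total}"
            )

    def percentages(self) -> dict[CxrFinding, float] | None:
        """Per-category percentages of the group total.

        Returns ``None`` for an empty group: percentages are undefined
        rather than zero.
        """
        if self.total == 0:
            return None
        return {f: 100.0 * n / self.total for f, n in self.counts.items()}

    def to_dict(self) -> dict:
        pct = self.percentages()
        return {
            "group": self.group,
            "total": self.total,
            "counts": {f.value: n for f, n in self.counts.items()},
            "percentages": None
            if pct is None
            else {f.value: p for f, p in pct.items()},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v == "true":
        return True
    if v == "false":
        return False
    raise CohortValidationError(
        f"row {row}: {column} must be true/false, got {value!r}"
    )


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a patient cohort from CSV.

    Rows with an empty ``cxr_finding`` field are retained with
    ``cxr=None`` (CXR not performed); excluding them is the caller's
    decision. Malformed rows raise :class:`CohortValidationError` naming
    the offending row (1-based file line, header = line 1) and value.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_cxr = getattr(row, "cxr_finding").strip()
        if raw_cxr == "":
            cxr = None
        else:
            try:
                cxr = CxrFinding(raw_cxr)
            except ValueError:
                raise CohortValidationError(
                    f"row {i}: unknown cxr_finding {raw_cxr!r}"
                ) from None
        try:
            years = int(getattr(row, "years_items"))
            ddimer = float(getattr(row, "ddimer_ng_ml"))
        except ValueError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from None
        try:
            records.append(
                PatientRecord(
                    patient_id=getattr(row, "patient_id"),
                    years_items=years,
                    ddimer_ng_ml=ddimer,
                    cxr=cxr,
                    pe_confirmed=_parse_bool(
                        getattr(row, "pe_confirmed"), i, "pe_confirmed"
                    ),
                    ctpa_indicated=_parse_bool(
                        getattr(row, "ctpa_indicated"), i, "ctpa_indicated"
                    ),
                )
            )
        except CohortValidationError as exc:
            if str(exc).startswith("row "):
                raise
            raise CohortValidationError(f"row {i}: {exc}") from None
    return records


def write_cohort_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write a cohort to CSV with a stable column order.

    Floats are written with ``repr`` precision so a write/read cycle is
    the identity and repeated writes of the same records are
    byte-identical. An empty collection yields a header-only file.
    """
    rows = [
        {
            "patient_id": r.patient_id,
            "years_items": str(r.years_items),
            "ddimer_ng_ml": repr(float(r.ddimer_ng_ml)),
            "cxr_finding": "" if r.cxr is None else r.cxr.value,
            "pe_confirmed": "true" if r.pe_confirmed else "false",
            "ctpa_indicated": "true" if r.ctpa_indicated else "false",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS), dtype=object)
    df.to_csv(path, index=False, lineterminator="\n")


def require_cxr(records: Sequence[PatientRecord]) -> Sequence[PatientRecord]:
    """Raise unless every record has a CXR finding."""
    n_missing = sum(1 for r in records if r.cxr is None)
    if n_missing:
        raise CohortValidationError(
            f"{n_missing} record(s) without CXR; filter them out before "
            "finding-based tabulation or statistics"
        )
    return records


def _group_predicate(group: str):
    if group == "all":
        return lambda r: True
    if group == "pe":
        return lambda r: r.pe_confirmed
    if group == "no_pe":
        return lambda r: not r.pe_confirmed
    if group == "ctpa_indicated":
        return lambda r: r.ctpa_indicated
    if group == "ctpa_not_indicated":
        return lambda r: not r.ctpa_indicated
    # YEARS strata are valid group selectors too
    from .triage import Stratum, classify_patient

    try:
        stratum = Stratum(group)
    except ValueError:
        raise CohortValidationError(f"unknown group selector {group!r}") from None
    return (
        lambda r: classify_patient(r.years_items, r.ddimer_ng_ml).stratum
        is stratum
    )


def tabulate(records: Sequence[PatientRecord], group: str = "all") -> CohortTable:
    """Count CXR findings within a patient group.

    ``group`` is one of :data:`GROUP_LABELS` or a YEARS stratum name.
    Every record must carry a CXR finding. An empty group yields a table
    with total 0 and all-zero counts (percentages undefined).
    """
    require_cxr(records)
    pred = _group_predicate(group)
    counter = Counter(r.cxr for r in records if pred(r))
    counts = {f: counter.get(f, 0) for f in FINDING_ORDER}
    return CohortTable(group=group, counts=counts, total=sum(counter.values()))
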