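"""Synthetic suspected-PE cohorts.

Two sources of patient-level data:

* :func:`generate` samples a cohort from a :class:`CohortSpec` — CTPA
  indication, YEARS stratum, PE status and CXR finding are drawn so that
  every patient's item count and D-dimer are consistent with the stratum
  they were sampled into (PE occurs only among CTPA-indicated patients,
  as the algorithm diagnoses PE only via CTPA).
* :func:`reference_cohort` deterministically reconstructs the published
  1,473-patient study cohort cell-for-cell from its group × finding
  contingency structure, so the downstream statistics can be validated
  against the printed results without any raw data.

D-dimer values are drawn uniformly within the stratum-consistent
interval; this is deliberately non-physiological, since the analysis
consumes only the stratum, never the value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cohort import FINDING_ORDER, PatientRecord
from .triage import Stratum

__all__ = [
    "CohortSpec",
    "REFERENCE_COUNTS",
    "generate",
    "recover_parameters",
    "reference_cohort",
]

#: Group × finding counts of the reference study cohort, in
#: :data:`FINDING_ORDER` (normal, pleural effusion, consolidation,
#: malignancy/mass, congestive heart failure, pneumothorax, rib
#: fracture, atelectasis). Columns sum to 1,473 / 214 / 1,259 / 763.
REFERENCE_COUNTS: dict[str, tuple[int, ...]] = {
    "all": (1069, 86, 206, 44, 49, 2, 4, 13),
    "pe": (137, 14, 49, 6, 7, 0, 0, 1),
    "no_pe": (932, 72, 157, 38, 42, 2, 4, 12),
    "ctpa_indicated": (465, 76, 142, 36, 34, 0, 2, 8),
}

_REF_N = 1473
_REF_N_PE = 214
_REF_N_CTPA = 763


def _probs(counts: tuple[int, ...]) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(c / total for c in counts)


#: D-dimer sampling intervals (ng/mL) consistent with each stratum under
#: the default thresholds (1000 at 0 items, 500 at >=1 item).
DEFAULT_DDIMER_RANGES: dict[Stratum, tuple[float, float]] = {
    Stratum.ITEMS0_LOW_DD: (0.0, 1000.0),
    Stratum.ITEMS0_HIGH_DD: (1000.0, 4000.0),
    Stratum.ITEMS1PLUS_LOW_DD: (0.0, 500.0),
    Stratum.ITEMS1PLUS_HIGH_DD: (500.0, 4000.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Defaults reproduce the reference study's marginal structure: PE
    prevalence 214/1,473 (14.5%), CTPA indicated for 763/1,473 (51.8%),
    and CXR-finding multinomials conditional on PE status taken from the
    reference contingency table. The split of each referral arm between
    the 0-item and ≥1-item strata is unreported and defaults to 50/50.
    """

    n: int = _REF_N
    prevalence_pe: float = _REF_N_PE / _REF_N
    p_ctpa: float = _REF_N_CTPA / _REF_N
    finding_probs_pe: tuple[float, ...] = _probs(REFERENCE_COUNTS["pe"])
    finding_probs_nope: tuple[float, ...] = _probs(REFERENCE_COUNTS["no_pe"])
    p_items0_given_ctpa: float = 0.5
    p_items0_given_no_ctpa: float = 0.5
    #: P(years_items = 1, 2, 3) conditional on having >=1 item.
    items_given_1plus: tuple[float, ...] = (0.6, 0.3, 0.1)
    ddimer_ranges: dict[Stratum, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DDIMER_RANGES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("prevalence_pe", "p_ctpa", "p_items0_given_ctpa",
                     "p_items0_given_no_ctpa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v!r}")
        if self.prevalence_pe > self.p_ctpa:
            raise ValueError(
                "infeasible spec: prevalence_pe > p_ctpa (PE can only be "
                "diagnosed among CTPA-indicated patients)"
            )
        for name in ("finding_probs_pe", "finding_probs_nope",
                     "items_given_1plus"):
            v = getattr(self, name)
            if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {v!r}")
        if len(self.finding_probs_pe) != len(FINDING_ORDER):
            raise ValueError("finding_probs_pe must have 8 entries")
        if len(self.finding_probs_nope) != len(FINDING_ORDER):
            raise ValueError("finding_probs_nope must have 8 entries")
        for s, (lo, hi) in self.ddimer_ranges.items():
            if not 0 <= lo < hi:
                raise ValueError(f"bad D-dimer range for {s}: ({lo}, {hi})")


_STRATUM_TABLE = {
    # (has_items, ctpa) -> stratum
    (False, False): Stratum.ITEMS0_LOW_DD,
    (False, True): Stratum.ITEMS0_HIGH_DD,
    (True, False): Stratum.ITEMS1PLUS_LOW_DD,
    (True, True): Stratum.ITEMS1PLUS_HIGH_DD,
}


def generate(spec: CohortSpec) -> list[PatientRecord]:
    """Sample a patient-level cohort from ``spec``.

    Deterministic given ``spec.seed``. Sampling is rejection-free: the
    stratum is drawn first and the (years_items, D-dimer) pair is drawn
    inside the region the stratum defines, so triage maps every patient
    back to the stratum it was sampled into.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    ctpa = rng.random(n) < spec.p_ctpa
    p_items0 = np.where(
        ctpa, spec.p_items0_given_ctpa, spec.p_items0_given_no_ctpa
    )
    items0 = rng.random(n) < p_items0
    years = np.where(
        items0,
        0,
        rng.choice([1, 2, 3], size=n, p=list(spec.items_given_1plus)),
    )
    p_pe = 0.0 if spec.p_ctpa == 0 else spec.prevalence_pe / spec.p_ctpa
    pe = ctpa & (rng.random(n) < p_pe)
    u = rng.random(n)
    lo = np.empty(n)
    hi = np.empty(n)
    for (has_items, is_ctpa), stratum in _STRATUM_TABLE.items():
        mask = (~items0 if has_items else items0) & (ctpa == is_ctpa)
        rlo, rhi = spec.ddimer_ranges[stratum]
        lo[mask], hi[mask] = rlo, rhi
    ddimer = lo + u * (hi - lo)
    finding_idx = np.where(
        pe,
        rng.choice(len(FINDING_ORDER), size=n, p=list(spec.finding_probs_pe)),
        rng.choice(len(FINDING_ORDER), size=n, p=list(spec.finding_probs_nope)),
    )
    width = max(4, len(str(n)))
    return [
        PatientRecord(
            patient_id=f"syn-{i:0{width}d}",
            years_items=int(years[i]),
            ddimer_ng_ml=float(ddimer[i]),
            cxr=FINDING_ORDER[int(finding_idx[i])],
            pe_confirmed=bool(pe[i]),
            ctpa_indicated=bool(ctpa[i]),
        )
        for i in range(n)
    ]


def reference_cohort() -> list[PatientRecord]:
    """Deterministic reconstruction of the reference study cohort.

    Builds 1,473 patients whose finding counts per group equal the
    published contingency table cell-for-cell: the PE column, the
    CTPA-indicated-without-PE counts (CTPA column minus PE column, valid
    because every PE lies within the CTPA-indicated group), and the
    remainder outside the CTPA-indicated group. YEARS item counts and
    D-dimer values are assigned as canonical representatives of the
    patient's referral arm (they carry no information beyond the arm).
    """
    pe_counts = REFERENCE_COUNTS["pe"]
    ctpa_counts = REFERENCE_COUNTS["ctpa_indicated"]
    nope_counts = REFERENCE_COUNTS["no_pe"]
    ctpa_nope = tuple(c - p for c, p in zip(ctpa_counts, pe_counts))
    no_ctpa = tuple(n - c for n, c in zip(nope_counts, ctpa_nope))
    if any(v < 0 for v in ctpa_nope) or any(v < 0 for v in no_ctpa):
        raise ValueError("inconsistent reference counts")

    records: list[PatientRecord] = []

    def emit(prefix: str, counts: tuple[int, ...], pe: bool, ctpa: bool) -> None:
        years, ddimer = (1, 1500.0) if ctpa else (0, 400.0)
        for finding, k in zip(FINDING_ORDER, counts):
            for j in range(k):
                records.append(
                    PatientRecord(
                        patient_id=f"{prefix}-{finding.value}-{j:04d}",
                        years_items=years,
                        ddimer_ng_ml=ddimer,
                        cxr=finding,
                        pe_confirmed=pe,
                        ctpa_indicated=ctpa,
                    )
                )

    emit("pe", pe_counts, pe=True, ctpa=True)
    emit("ctpa", ctpa_nope, pe=False, ctpa=True)
    emit("amb", no_ctpa, pe=False, ctpa=False)
    assert len(records) == _REF_N
    return records


def recover_parameters(records: Sequence[PatientRecord]) -> CohortSpec:
    """Empirical cohort parameters as a :class:`CohortSpec`.

    Conditional finding frequencies for an empty PE (or no-PE) group are
    returned as NaN vectors; the result is an estimate and is not
    re-validated.
    """
    if not records:
        raise ValueError("cohort is empty")
    n = len(records)
    n_pe = sum(r.pe_confirmed for r in records)
    n_ctpa = sum(r.ctpa_indicated for r in records)

    def freqs(flag: bool) -> tuple[float, ...]:
        group = [r for r in records if r.pe_confirmed is flag]
        if not group:
            return tuple(math.nan for _ in FINDING_ORDER)
        return tuple(
            sum(r.cxr is f for r in group) / len(group) for f in FINDING_ORDER
        )

    return replace(
        CohortSpec(),
        n=n,
        prevalence_pe=n_pe / n,
        p_ctpa=n_ctpa / n,
        finding_probs_pe=freqs(True),
        finding_probs_nope=freqs(False),
    )
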