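"""Full analysis pipeline: from patient records to the result tables.

:func:`run_analysis` reconstructs, for any validated cohort, the
finding-count table per patient group, per-finding positive and negative
likelihood ratios in two populations (all patients; CTPA-indicated
patients), the headline odds ratios, and the worked posttest-probability
examples. :func:`render_report` serializes the report to JSON, Markdown
or CSV deterministically.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import (
    FINDING_ORDER,
    GROUP_LABELS,
    CohortTable,
    CxrFinding,
    PatientRecord,
    require_cxr,
    tabulate,
)
from .stats import (
    EstimateWithCI,
    TwoByTwo,
    build_two_by_two,
    format_or,
    format_point,
    format_ratio,
    likelihood_ratio_negative,
    likelihood_ratio_positive,
    odds_ratio,
    posttest_probability,
)
from .triage import Stratum, TriageSummary, triage_cohort

__all__ = [
    "POPULATIONS",
    "AnalysisReport",
    "Table3Row",
    "render_report",
    "run_analysis",
]

logger = logging.getLogger(__name__)

#: Populations in which the likelihood ratios are computed.
POPULATIONS: tuple[str, ...] = ("all", "ctpa_indicated")

#: Row order of the likelihood-ratio table: a normal radiograph is
#: analysed as a test result in its own right, followed by the seven
#: abnormal categories.
TABLE3_FINDINGS: tuple[CxrFinding, ...] = FINDING_ORDER


@dataclass(frozen=True)
class Table3Row:
    """Likelihood ratios for one finding in one population."""

    population: str
    finding: CxrFinding
    cells: tuple[int, int, int, int]  # (a, b, c, d) vs PE status
    lr_positive: EstimateWithCI
    lr_negative: EstimateWithCI


@dataclass(frozen=True)
class AnalysisReport:
    n: int
    n_ctpa: int
    n_pe: int
    table2: dict[str, CohortTable]
    table3: tuple[Table3Row, ...]
    headline_ors: dict[str, dict]
    posttest_examples: dict
    triage: TriageSummary

    def table3_row(self, population: str, finding: CxrFinding) -> Table3Row:
        for row in self.table3:
            if row.population == population and row.finding is finding:
                return row
        raise KeyError((population, finding))


def run_analysis(records: Sequence[PatientRecord]) -> AnalysisReport:
    """Run the complete diagnostic-accuracy analysis on a cohort.

    Requires a non-empty cohort in which every record carries a CXR
    finding and every confirmed PE lies within the CTPA-indicated group
    (otherwise the CTPA-subgroup statistics would be inconsistent).
    """
    if not records:
        raise ValueError("cannot analyse an empty cohort")
    require_cxr(records)
    bad = sum(1 for r in records if r.pe_confirmed and not r.ctpa_indicated)
    if bad:
        raise ValueError(
            f"inconsistent cohort: {bad} confirmed-PE record(s) outside the "
            "CTPA-indicated group"
        )
    logger.info("analysing cohort of %d patients", len(records))

    group_labels = list(GROUP_LABELS) + [s.value for s in Stratum]
    table2 = {g: tabulate(records, g) for g in group_labels}

    ctpa_records = [r for r in records if r.ctpa_indicated]
    populations = {"all": records, "ctpa_indicated": ctpa_records}
    n_pe_ctpa = sum(r.pe_confirmed for r in ctpa_records)
    logger.info(
        "CTPA subgroup: %d patients, %d with PE (non-PE counts obtained "
        "within the subgroup, equivalent to subtracting the PE column)",
        len(ctpa_records), n_pe_ctpa,
    )

    table3 = []
    for pop, recs in populations.items():
        for finding in TABLE3_FINDINGS:
            t = build_two_by_two(recs, finding, outcome="pe")
            lrp = likelihood_ratio_positive(t)
            lrn = likelihood_ratio_negative(t)
            if t.a == 0 and t.c == 0:
                # finding never occurred in this population: no diagnostic
                # statement is made for either LR sign (reported "n.a.";
                # the raw LR- is trivially 1)
                lrn = EstimateWithCI(
                    math.nan, None, None, True, lrn.method
                )
            if t.has_zero_cell:
                logger.info(
                    "zero cell in %s/%s table %s", pop, finding.value, t.cells()
                )
            table3.append(
                Table3Row(
                    population=pop,
                    finding=finding,
                    cells=t.cells(),
                    lr_positive=lrp,
                    lr_negative=lrn,
                )
            )

    def or_entry(t: TwoByTwo) -> dict:
        est = odds_ratio(t)
        return {"cells": t.cells(), "estimate": est}

    headline_ors = {
        # abnormal CXR, PE vs no PE
        "abnormal_cxr_pe": or_entry(build_two_by_two(records, "abnormal", "pe")),
        # consolidation, PE vs no PE
        "consolidation_pe": or_entry(
            build_two_by_two(records, CxrFinding.CONSOLIDATION, "pe")
        ),
        # normal CXR, CTPA not indicated vs indicated
        "normal_cxr_no_ctpa": or_entry(
            build_two_by_two(records, CxrFinding.NORMAL, "no_ctpa")
        ),
    }

    posttest = _posttest_examples(ctpa_records, table3)

    return AnalysisReport(
        n=len(records),
        n_ctpa=len(ctpa_records),
        n_pe=sum(r.pe_confirmed for r in records),
        table2=table2,
        table3=tuple(table3),
        headline_ors=headline_ors,
        posttest_examples=posttest,
        triage=triage_cohort(records),
    )


def _posttest_examples(
    ctpa_records: Sequence[PatientRecord], table3: Sequence[Table3Row]
) -> dict:
    """Worked posttest-probability updates for a CTPA-indicated patient.

    The pretest probability is the PE prevalence among CTPA-indicated
    patients, rounded to report precision (a percentage in whole points),
    and the likelihood ratios enter at report precision too — mirroring
    how the update is quoted at the bedside. The exact odds-scale update
    is reported alongside.
    """
    if not ctpa_records:
        return {}
    pretest_raw = sum(r.pe_confirmed for r in ctpa_records) / len(ctpa_records)
    pretest = round(pretest_raw, 2)

    def printed_lr(finding) -> float:
        for row in table3:
            if row.population == "ctpa_indicated" and row.finding is finding:
                return float(format_point(row.lr_positive.point))
        raise KeyError(finding)

    # LR of an abnormal radiograph = LR+ of the "any abnormality" test,
    # which equals the normal radiograph's LR-.
    lr_normal = printed_lr(CxrFinding.NORMAL)
    t_abn = TwoByTwo(*_abnormal_cells(table3))
    lr_abnormal = float(format_point(likelihood_ratio_positive(t_abn).point))

    def example(lr: float) -> dict:
        mult = posttest_probability(pretest, lr, "multiplicative")
        bayes = posttest_probability(pretest, lr, "bayes_odds")
        return {
            "lr": lr,
            "posttest_multiplicative": mult,
            "posttest_multiplicative_pct": round(100 * mult),
            "posttest_bayes_odds": bayes,
            "posttest_bayes_odds_pct": round(100 * bayes),
        }

    return {
        "pretest": pretest,
        "pretest_raw": pretest_raw,
        "normal_cxr": example(lr_normal),
        "abnormal_cxr": example(lr_abnormal),
    }


def _abnormal_cells(table3: Sequence[Table3Row]) -> tuple[int, int, int, int]:
    # abnormal-vs-normal table in the CTPA population, from the normal row
    for row in table3:
        if row.population == "ctpa_indicated" and row.finding is CxrFinding.NORMAL:
            a, b, c, d = row.cells
            return (b, a, d, c)
    raise KeyError("normal row missing")


def _report_dict(report: AnalysisReport) -> dict:
    table3: dict = {pop: {} for pop in POPULATIONS}
    for row in report.table3:
        table3[row.population][row.finding.value] = {
            "cells": list(row.cells),
            "lr_positive": row.lr_positive.to_dict(),
            "lr_negative": row.lr_negative.to_dict(),
        }
    return {
        "n": report.n,
        "n_ctpa": report.n_ctpa,
        "n_pe": report.n_pe,
        "table2": {g: t.to_dict() for g, t in report.table2.items()},
        "table3": table3,
        "headline_ors": {
            name: {
                "cells": list(entry["cells"]),
                **entry["estimate"].to_dict(),
                "printed": format_or(entry["estimate"]),
            }
            for name, entry in report.headline_ors.items()
        },
        "posttest_examples": report.posttest_examples,
        "triage": report.triage.to_dict(),
    }


def _finding_label(f: CxrFinding) -> str:
    return f.value.replace("_", " ")


def _render_markdown(report: AnalysisReport) -> str:
    out = io.StringIO()
    d = report.table2
    out.write(f"# Analysis report (n = {report.n})\n\n")
    out.write("## CXR findings per patient group\n\n")
    groups = ["all", "pe", "no_pe", "ctpa_indicated"]
    header = {"all": "All", "pe": "PE", "no_pe": "No PE",
              "ctpa_indicated": "CTPA indicated"}
    out.write(
        "| Result of CXR | "
        + " | ".join(f"{header[g]} (n = {d[g].total})" for g in groups)
        + " |\n"
    )
    out.write("|" + "---|" * (len(groups) + 1) + "\n")
    for f in FINDING_ORDER:
        cells = []
        for g in groups:
            pct = d[g].percentages()
            cells.append(
                f"{d[g].counts[f]}"
                + ("" if pct is None else f" ({pct[f]:.1f})")
            )
        out.write(f"| {_finding_label(f)} | " + " | ".join(cells) + " |\n")
    out.write("\n## Likelihood ratios in two populations\n\n")
    out.write(
        "| Results CXR | LR+ (all) | LR− (all) | LR+ (CTPA indicated) "
        "| LR− (CTPA indicated) |\n"
    )
    out.write("|---|---|---|---|---|\n")
    for f in TABLE3_FINDINGS:
        row_all = report.table3_row("all", f)
        row_ctpa = report.table3_row("ctpa_indicated", f)
        out.write(
            f"| {_finding_label(f)} | {format_ratio(row_all.lr_positive)} | "
            f"{format_ratio(row_all.lr_negative)} | "
            f"{format_ratio(row_ctpa.lr_positive)} | "
            f"{format_ratio(row_ctpa.lr_negative)} |\n"
        )
    out.write("\n## Headline odds ratios\n\n")
    for name, entry in report.headline_ors.items():
        out.write(f"- {name}: {format_or(entry['estimate'])}\n")
    ex = report.posttest_examples
    if ex:
        out.write("\n## Posttest probability (CTPA-indicated patient)\n\n")
        out.write(f"- pretest probability: {ex['pretest']:.0%}\n")
        for key in ("normal_cxr", "abnormal_cxr"):
            e = ex[key]
            out.write(
                f"- {key.replace('_', ' ')}: LR {e['lr']} → "
                f"{e['posttest_multiplicative_pct']}% (multiplicative), "
                f"{e['posttest_bayes_odds_pct']}% (odds-scale)\n"
            )
    return out.getvalue()


def _render_csv(report: AnalysisReport) -> str:
    rows = []
    for row in report.table3:
        for sign, est in (
            ("lr_positive", row.lr_positive),
            ("lr_negative", row.lr_negative),
        ):
            rows.append(
                {
                    "population": row.population,
                    "finding": row.finding.value,
                    "measure": sign,
                    "point": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "zero_cell": est.zero_cell,
                    "printed": format_ratio(est),
                    "a": row.cells[0],
                    "b": row.cells[1],
                    "c": row.cells[2],
                    "d": row.cells[3],
                }
            )
    df = pd.DataFrame(rows)
    return df.to_csv(index=False, lineterminator="\n")


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialize a report deterministically as JSON, Markdown or CSV.

    The CSV form is the likelihood-ratio table in long format (one row
    per finding × population × LR sign); the Markdown form mirrors the
    layout of the published tables.
    """
    if format == "json":
        return json.dumps(
            _report_dict(report), indent=2, sort_keys=True, ensure_ascii=False
        )
    if format == "markdown":
        return _render_markdown(report)
    if format == "csv":
        return _render_csv(report)
    raise ValueError(f"unknown format {format!r} (json, markdown, csv)")
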