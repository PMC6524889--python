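#!/usr/bin/env python
"""Posttest-probability updates after a chest radiograph.

Reproduces the worked bedside example (CTPA-indicated patient, pretest
28%) and tabulates a Fagan-style grid of posttest probabilities over a
range of pretest probabilities for each finding's positive likelihood
ratio, on both the multiplicative shortcut and the exact odds scale.
Writes ``results/posttest_examples.json`` and ``results/posttest_grid.csv``.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from yearscxr import (
    CxrFinding,
    posttest_probability,
    reference_cohort,
    run_analysis,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
PRETEST_GRID = (0.05, 0.10, 0.145, 0.28, 0.50)


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    report = run_analysis(reference_cohort())
    RESULTS.mkdir(exist_ok=True)

    ex = report.posttest_examples
    (RESULTS / "posttest_examples.json").write_text(
        json.dumps(ex, indent=2, sort_keys=True) + "\n"
    )
    print(f"pretest {ex['pretest']:.0%} (CTPA subgroup prevalence "
          f"{ex['pretest_raw']:.3f})")
    for key in ("normal_cxr", "abnormal_cxr"):
        e = ex[key]
        print(f"  {key}: LR {e['lr']} -> "
              f"{e['posttest_multiplicative_pct']}% multiplicative, "
              f"{e['posttest_bayes_odds_pct']}% odds-scale")

    rows = []
    for f in CxrFinding:
        row = report.table3_row("ctpa_indicated", f)
        if not row.lr_positive.defined:
            continue
        for pretest in PRETEST_GRID:
            lr = row.lr_positive.point
            rows.append({
                "finding": f.value,
                "lr_positive": lr,
                "pretest": pretest,
                "posttest_multiplicative": posttest_probability(
                    pretest, lr, "multiplicative"),
                "posttest_bayes_odds": posttest_probability(
                    pretest, lr, "bayes_odds"),
            })
    grid = pd.DataFrame(rows)
    out = RESULTS / "posttest_grid.csv"
    grid.to_csv(out, index=False, float_format="%.4f")
    print(f"posttest grid ({len(grid)} rows) -> {out}")


if __name__ == "__main__":
    main()
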