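#!/usr/bin/env python
"""Triage the synthetic cohort with the YEARS rule.

Reads ``results/synthetic_cohort.csv`` (created by 01_simulate_cohort.py),
assigns every patient a stratum, and writes the stratum counts and CTPA
fraction to ``results/triage_summary.json``.
"""

import argparse
import json
import math
from pathlib import Path

from yearscxr import CohortSpec, read_cohort_csv, triage_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    cohort_csv = RESULTS / "synthetic_cohort.csv"
    if not cohort_csv.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    records = read_cohort_csv(cohort_csv)
    summary = triage_cohort(records)
    out = RESULTS / "triage_summary.json"
    out.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    target = CohortSpec().p_ctpa
    se = math.sqrt(target * (1 - target) / summary.n)
    print(f"strata: { {s.value: c for s, c in summary.counts.items()} }")
    print(f"CTPA fraction {summary.ctpa_fraction:.3f} vs target {target:.3f} "
          f"(z = {(summary.ctpa_fraction - target) / se:+.2f}) -> {out}")


if __name__ == "__main__":
    main()
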