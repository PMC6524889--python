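# yearscxr

Does a chest radiograph add diagnostic value once a patient with
suspected pulmonary embolism (PE) has been triaged with the YEARS
algorithm? This package implements the complete post-hoc
diagnostic-accuracy analysis behind that question as a tested pipeline:
YEARS triage (item count + pretest-dependent D-dimer threshold →
CTPA indication), per-finding 2×2 contingency statistics, and
posttest-probability updating — together with a synthetic patient-cohort
generator and a deterministic reconstruction of the 1,473-patient
reference cohort, so every number is reproducible without access to raw
clinical data.

It is aimed at biostatisticians and clinical epidemiologists who want
the analysis as importable, property-tested code rather than a
spreadsheet.

## The statistics

For a finding × outcome table (a = finding present & PE, b = absent &
PE, c = present & no PE, d = absent & no PE):

- odds ratio ad/(bc), 95% CI by the Woolf log method
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d));
- LR⁺ = [a/(a+b)] / [c/(c+d)] and LR⁻ = [b/(a+b)] / [d/(c+d)], 95% CIs
  by the Simel log method;
- posttest probability from pretest probability and LR, either exactly
  on the odds scale (Fagan) or with the multiplicative bedside shortcut
  min(pretest × LR, 1).

Zero-cell conventions, report precision and the interval policy are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from yearscxr import reference_cohort, run_analysis, CxrFinding
from yearscxr.stats import format_or, format_ratio

report = run_analysis(reference_cohort())
print(report.n, report.n_ctpa, report.n_pe)
# 1473 763 214

print(format_or(report.headline_ors["abnormal_cxr_pe"]["estimate"]))
# 1.60 (1.18–2.18)

row = report.table3_row("all", CxrFinding.CONSOLIDATION)
print(format_ratio(row.lr_positive), "|", format_ratio(row.lr_negative))
# 1.8 (1.4–2.4) | 0.88 (0.82–0.95)

ex = report.posttest_examples
print(ex["pretest"], ex["normal_cxr"]["lr"],
      ex["normal_cxr"]["posttest_multiplicative_pct"])
# 0.28 1.1 31
```

Reading: an abnormal radiograph is more frequent with confirmed PE
(odds ratio 1.60), consolidation nearly doubles the odds of PE in the
full cohort (LR⁺ 1.8), yet for a CTPA-indicated patient with pretest
probability 28% a normal radiograph only moves the probability to 31% —
nowhere near the decision boundary, which is the analysis' central
finding.

## Analysis drivers

Numbered scripts under `analysis/` run the study end-to-end and write
tables to `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 0   # synthetic cohort + parameter recovery
python analysis/02_triage_summary.py             # YEARS strata and CTPA fraction
python analysis/03_reference_analysis.py         # reconstructed result tables
python analysis/04_posttest_probability.py       # Fagan-style posttest grid
```

The same operations are available as a CLI (`yearscxr simulate|fixture|
triage|analyze`), e.g.:

```sh
yearscxr fixture --out cohort.csv
yearscxr analyze cohort.csv --format markdown
```

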