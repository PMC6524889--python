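# Methods

## Setting and model

The package analyses the diagnostic value of the chest radiograph (CXR)
in patients with suspected pulmonary embolism (PE) who are managed with
the YEARS algorithm. YEARS scores three clinical items — clinical signs
of deep-vein thrombosis, hemoptysis, and "PE the most likely diagnosis" —
and refers a patient for computed tomography pulmonary angiography
(CTPA) when the D-dimer is at least 1000 ng/mL (no item present) or
500 ng/mL (one or more items). Below the applicable threshold PE is
considered ruled out without imaging; consequently PE can only be
diagnosed inside the CTPA-referred group.

Each patient carries a single dominant CXR finding from eight mutually
exclusive categories (normal, pleural effusion, consolidation,
malignancy/mass, congestive heart failure, pneumothorax, rib fracture,
atelectasis). The question is whether any finding shifts the probability
of PE enough to change the CTPA decision. The analysis is classical
diagnostic-test accuracy on finding × outcome 2×2 tables:

- **Odds ratio.** OR = ad/(bc) with the Woolf interval
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)), z = 1.96.
- **Likelihood ratios.** With sensitivity p₁ = a/(a+b) and
  "false-positive rate" p₂ = c/(c+d), LR⁺ = p₁/p₂ and
  LR⁻ = (1−p₁)/(1−p₂), each with the Simel log-method interval
  exp(ln LR ± z·√((1−p₁)/a + (1−p₂)/c)) (cells b, d for LR⁻).
- **Posttest probability.** Two updating rules are provided:
  the exact odds-scale (Fagan) update, posttest odds = pretest odds × LR,
  and the multiplicative bedside shortcut min(pretest × LR, 1), which is
  the first-order approximation of the exact update as the pretest
  probability goes to 0. The shortcut is the default in the worked
  report examples because it is how such updates are quoted clinically;
  the exact value is always reported alongside (e.g. pretest 28%,
  LR 1.1: 31% by the shortcut, 30% on the odds scale).

A normal radiograph is analysed as a test result in its own right (its
LR⁺ is the ratio of normal-CXR frequencies in the two outcome groups,
not the reciprocal of the abnormal-CXR LR), and "abnormal CXR" is the
pseudo-finding "any non-normal category".

Likelihood ratios are computed in two populations: all patients, and the
CTPA-indicated subgroup. The subgroup's pretest probability (≈28%) is
what makes the posttest question operational: could a CXR finding move
the probability across the decision boundary?

## Numerical and reporting choices

- **z = 1.96** fixed for all 95% intervals; no multiple-testing
  adjustment.
- **Zero cells.** Point estimates are never continuity-corrected. An LR
  whose numerator cell is 0 is reported as exactly 0.00 with no
  interval; a zero denominator cell makes the estimate undefined
  ("n.a."). When an estimate is defined but another cell of its table is
  0, its interval is computed from Haldane-corrected cells (+0.5 on all
  four) because the uncorrected log-method variance loses a term and
  collapses; the point stays uncorrected. When a finding never occurs in
  a population, the report prints "n.a." for both LR signs (the raw LR⁻
  is trivially 1 and carries no information); the statistics functions
  themselves still return that exact 1.
- **Report precision.** Likelihood ratios print with two significant
  figures at or above 1 and two decimals below 1; values rounding to
  1.00 print as "1.0" from either side. Odds ratios print at two
  decimals. Raw unrounded values are retained everywhere (`point`,
  `ci` in the JSON report alongside `printed`).
- **Triage boundary.** A D-dimer exactly at threshold refers to CTPA
  (conservative toward imaging). Thresholds and the boundary convention
  are configurable (`TriageConfig`, YAML-loadable) so rule variants are
  testable.
- **Posttest worked examples** enter the update at report precision
  (pretest rounded to whole percent, LR at printed precision), mirroring
  how the numbers are quoted at the bedside; the raw prevalence is kept
  in the report.

## Synthetic cohorts

`reference_cohort()` is the deterministic reconstruction of the
published 1,473-patient study: patient-level records whose group ×
finding counts equal the published contingency table cell-for-cell. The
non-PE counts inside the CTPA-indicated subgroup are the CTPA column
minus the PE column — valid because every PE lies within that subgroup —
and the remainder forms the no-CTPA group (whose normal-CXR count, 604
of 710, the reconstruction reproduces). YEARS item counts and D-dimer
values in this cohort are canonical representatives of each referral arm
(1 item / 1500 ng/mL vs 0 items / 400 ng/mL): the analysis consumes only
the arm, never the values.

`generate(CohortSpec)` samples cohorts with the study's marginal
structure for property testing at arbitrary n: CTPA indication
(p = 763/1473), the YEARS stratum within each referral arm, PE status
(Bernoulli with prevalence 214/1473 overall, placed only among
CTPA-indicated patients), and the CXR finding from multinomials
conditional on PE status (the published PE and no-PE columns). Sampling
is rejection-free: the stratum is drawn first and (items, D-dimer) are
drawn inside the region that stratum defines, so triage maps every
patient back to the stratum it was sampled into. Where the study reports
no value, a fixed choice was made once: the split of each referral arm
between the 0-item and ≥1-item strata is 50/50 (unreported; configurable),
item counts within the ≥1 arm are 1/2/3 with probabilities 0.6/0.3/0.1,
and D-dimer is uniform within the stratum-consistent interval (upper
bound 4000 ng/mL). The D-dimer model is deliberately non-physiological —
no skew, no covariate dependence — because nothing downstream reads the
value; equally, comorbidity structure, the missing-CXR selection
mechanism, and any correlation between findings and YEARS items are not
modelled. Passing tests therefore validate the arithmetic of the
pipeline and the marginal structure of the cohort, not clinical realism
of individual records.

## Validation strategy

- The deterministic reconstruction is pushed end-to-end through the
  pipeline and compared cell-by-cell with the published tables at report
  precision (counts, percentages, all LR cells in both populations, the
  three headline ORs, the posttest examples). One published interval
  bound (congestive heart failure, CTPA subgroup, LR⁻ upper bound) is
  asserted at the value this method computes, 1.0, where the source
  prints 1.1; the computed interval is exp(ln 1.0173 ± 1.96·0.0159) =
  (0.99, 1.05), and no variant of the log method reproduces 1.1 at two
  significant figures.
- The Woolf interval is cross-checked against an independent
  implementation (statsmodels' `Table2x2`) on random tables.
- Analytic intervals are compared with a 10,000-resample percentile
  bootstrap (patients resampled within each outcome group). The
  comparison is made on tables whose four cells are all ≥ 30 — the
  standard validity region of the normal approximation — where the two
  approaches agree within 0.05 on the log-ratio scale. For sparse
  findings (≤ 14 events) the percentile bootstrap's lower bound sits at
  or near 0 (with one event, the resampled numerator is 0 with
  probability ≈ 0.37), so no fixed agreement with a Wald-type interval
  exists there; this is a property of the estimators, not a defect of
  either.
- Generator faithfulness is a parameter-recovery test: at n = 50,000
  every generative probability is re-estimated within three standard
  errors.
- Triage invariants (monotonicity in D-dimer and in item count; the four
  strata partition any cohort) and CSV round-trip identity are property
  tests under randomized inputs.

Problem sizes were chosen so the whole suite runs in a few seconds on
one CPU: the exact layer is a fixed 1,473-patient cohort, the bootstrap
uses 10⁴ resamples, and recovery uses one 50,000-patient cohort.

## Known limitations

- The multiplicative posttest update can exceed 1 before capping and is
  quoted only because it is the bedside convention; the odds-scale
  update is the statistically correct form and both are always computed.
- The synthetic generator draws the no-PE finding distribution
  identically inside and outside the CTPA group, so sampled cohorts
  reproduce the published CTPA-column finding counts only through the
  PE/no-PE mixture, not exactly; the deterministic reconstruction is the
  object that matches all four columns.
- Patients without a CXR are representable (and excluded by the caller,
  as in the study, where 238 of 1,711 had no radiograph) but no
  missingness mechanism is modelled, so selection effects cannot be
  explored synthetically.
- CXR categories are single-valued by construction; a precedence rule
  for multi-finding radiographs is the data producer's responsibility.
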