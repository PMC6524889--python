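"""Diagnostic-accuracy statistics on 2×2 contingency tables.

Odds ratios with Woolf (log-normal) confidence intervals, positive and
negative likelihood ratios with Simel log-method intervals, and pretest →
posttest probability updating, plus a percentile-bootstrap interval used
as an independent numerical cross-check of the analytic intervals.

Conventions
-----------
The 2×2 table is oriented finding × outcome::

                outcome +   outcome −
    finding +       a           c
    finding −       b           d

so ``a + b`` is the outcome-positive total and ``c + d`` the
outcome-negative total. The outcome is PE status for the likelihood-ratio
analyses and can be any dichotomy (e.g. CTPA not indicated vs indicated)
for odds ratios.

Zero-cell policy
----------------
Point estimates are never continuity-corrected. A likelihood ratio whose
numerator cell is 0 is reported as exactly 0.00 with no interval; one
whose denominator cell is 0 is undefined (``point`` = NaN, printed
"n.a."). When a defined estimate comes from a table containing a zero
cell elsewhere, its interval is computed from Haldane-corrected cells
(0.5 added to all four) because the uncorrected log-method variance
degenerates; the point estimate stays uncorrected. Odds-ratio intervals
are simply suppressed whenever any cell is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cohort import (
    ABNORMAL_FINDINGS,
    CxrFinding,
    PatientRecord,
    require_cxr,
)

__all__ = [
    "Z95",
    "EstimateWithCI",
    "TwoByTwo",
    "bootstrap_ci",
    "build_two_by_two",
    "format_point",
    "format_ratio",
    "likelihood_ratio_negative",
    "likelihood_ratio_positive",
    "odds_ratio",
    "posttest_probability",
]

#: Normal quantile for two-sided 95% intervals, fixed by convention.
Z95 = 1.96


@dataclass(frozen=True)
class TwoByTwo:
    """Finding × outcome counts (see module docstring for orientation)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a count >= 0, got {v!r}")

    @property
    def n_pos(self) -> int:
        """Outcome-positive total (a + b)."""
        return self.a + self.b

    @property
    def n_neg(self) -> int:
        """Outcome-negative total (c + d)."""
        return self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EstimateWithCI:
    """Point estimate with a 95% interval.

    ``point`` is NaN when the estimate is undefined (printed "n.a.").
    ``ci_low``/``ci_high`` are ``None`` when no interval is reported.
    ``zero_cell`` flags that the source table contained a zero cell.
    """

    point: float
    ci_low: float | None
    ci_high: float | None
    zero_cell: bool
    method: str

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not math.isnan(self.point) and not (
                self.ci_low <= self.point <= self.ci_high
            ):
                raise ValueError(
                    f"interval [{self.ci_low}, {self.ci_high}] does not "
                    f"bracket point {self.point}"
                )

    @property
    def defined(self) -> bool:
        return not math.isnan(self.point)

    def to_dict(self) -> dict:
        return {
            "point": None if math.isnan(self.point) else self.point,
            "ci": None
            if self.ci_low is None
            else [self.ci_low, self.ci_high],
            "zero_cell": self.zero_cell,
            "method": self.method,
            "printed": format_ratio(self),
        }


FindingSelector = CxrFinding | str  # a category, "abnormal", or "normal"


def _finding_predicate(finding: FindingSelector) -> Callable[[PatientRecord], bool]:
    if finding == "abnormal":
        return lambda r: r.cxr in ABNORMAL_FINDINGS
    f = CxrFinding(finding)
    return lambda r: r.cxr is f


def _outcome_predicate(outcome: str) -> Callable[[PatientRecord], bool]:
    if outcome == "pe":
        return lambda r: r.pe_confirmed
    if outcome == "no_ctpa":
        return lambda r: not r.ctpa_indicated
    raise ValueError(f"unknown outcome {outcome!r} (expected 'pe' or 'no_ctpa')")


def build_two_by_two(
    records: Sequence[PatientRecord],
    finding: FindingSelector,
    outcome: str = "pe",
) -> TwoByTwo:
    """Cross-tabulate finding presence against a dichotomous outcome.

    ``finding`` is a :class:`CxrFinding` (or its string value) or the
    pseudo-category ``"abnormal"`` meaning any non-normal finding. A
    normal radiograph can itself be the "finding", matching how it is
    analysed as a test result in its own right.
    """
    require_cxr(records)
    present = _finding_predicate(finding)
    positive = _outcome_predicate(outcome)
    a = b = c = d = 0
    for r in records:
        if positive(r):
            if present(r):
                a += 1
            else:
                b += 1
        else:
            if present(r):
                c += 1
            else:
                d += 1
    return TwoByTwo(a=a, b=b, c=c, d=d)


def _log_interval(point: float, se: float) -> tuple[float, float]:
    half = Z95 * se
    return (point * math.exp(-half), point * math.exp(half))


def odds_ratio(t: TwoByTwo) -> EstimateWithCI:
    """Odds ratio (a·d)/(b·c) with a Woolf log-method 95% CI.

    With any zero cell the interval is suppressed: the point is 0 when
    the numerator product is 0, undefined (NaN) when only the denominator
    product is 0.
    """
    method = "woolf_log"
    if t.has_zero_cell:
        if t.a * t.d == 0:
            point = math.nan if t.b * t.c == 0 else 0.0
        else:
            point = math.nan  # infinite OR: reported undefined with flag
        return EstimateWithCI(point, None, None, True, method)
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    low, high = _log_interval(point, se)
    return EstimateWithCI(point, low, high, False, method)


def _lr(
    t: TwoByTwo, num_cell: str, den_cell: str
) -> EstimateWithCI:
    # num_cell/den_cell are 'a'/'c' for LR+ and 'b'/'d' for LR-.
    method = "simel_log"
    if t.n_pos == 0 or t.n_neg == 0:
        raise ValueError("both outcome groups must be non-empty")
    num = getattr(t, num_cell)
    den = getattr(t, den_cell)
    if den == 0:
        return EstimateWithCI(math.nan, None, None, True, method)
    if num == 0:
        return EstimateWithCI(0.0, None, None, True, method)
    p1 = num / t.n_pos
    p2 = den / t.n_neg
    point = p1 / p2
    if t.has_zero_cell:
        # zero elsewhere in the table (not in the CI-defining cells):
        # interval from Haldane-corrected cells, point uncorrected
        num_c, den_c = num + 0.5, den + 0.5
        n_pos_c, n_neg_c = t.n_pos + 1.0, t.n_neg + 1.0
        p1_c, p2_c = num_c / n_pos_c, den_c / n_neg_c
        centre = p1_c / p2_c
        se = math.sqrt((1 - p1_c) / num_c + (1 - p2_c) / den_c)
        low, high = _log_interval(centre, se)
        low, high = min(low, point), max(high, point)
        return EstimateWithCI(point, low, high, False, method + "_haldane_ci")
    se = math.sqrt((1 - p1) / num + (1 - p2) / den)
    low, high = _log_interval(point, se)
    return EstimateWithCI(point, low, high, False, method)


def likelihood_ratio_positive(t: TwoByTwo) -> EstimateWithCI:
    """LR+ = [a/(a+b)] / [c/(c+d)] with a Simel log-method 95% CI."""
    return _lr(t, "a", "c")


def likelihood_ratio_negative(t: TwoByTwo) -> EstimateWithCI:
    """LR− = [b/(a+b)] / [d/(c+d)] with a Simel log-method 95% CI."""
    return _lr(t, "b", "d")


def posttest_probability(
    pretest: float, lr: float, method: str = "multiplicative"
) -> float:
    """Update a pretest probability with a likelihood ratio.

    ``multiplicative`` is the clinical shortcut ``min(pretest × LR, 1)``
    used in bedside worked examples; ``bayes_odds`` is the exact Bayesian
    update on the odds scale (the Fagan-nomogram computation). The two
    agree to first order as the pretest probability goes to 0.
    """
    if not 0 <= pretest <= 1:
        raise ValueError(f"pretest must be a probability, got {pretest!r}")
    if not lr >= 0:
        raise ValueError(f"likelihood ratio must be non-negative, got {lr!r}")
    if method == "multiplicative":
        return min(pretest * lr, 1.0)
    if method == "bayes_odds":
        if pretest == 1.0:
            return 1.0
        odds = pretest / (1.0 - pretest)
        post_odds = odds * lr
        return post_odds / (1.0 + post_odds)
    raise ValueError(f"unknown method {method!r}")


def bootstrap_ci(
    t: TwoByTwo,
    statistic: str,
    n_resamples: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile-bootstrap 95% interval for an LR or OR.

    Patients are resampled independently within each outcome group, which
    for a table whose only patient feature is finding presence reduces to
    binomial resampling of the two proportions. Serves as an independent
    numerical check of the analytic (Woolf / Simel) intervals where the
    normal approximation is expected to hold.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = t.n_pos, t.n_neg
    if n1 == 0 or n2 == 0:
        raise ValueError("both outcome groups must be non-empty")
    if statistic == "lr_positive":
        num, den = t.a, t.c
    elif statistic == "lr_negative":
        num, den = t.b, t.d
    elif statistic == "odds_ratio":
        a_star = rng.binomial(n1, t.a / n1, n_resamples).astype(float)
        c_star = rng.binomial(n2, t.c / n2, n_resamples).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (a_star * (n2 - c_star)) / ((n1 - a_star) * c_star)
        return tuple(
            np.nanpercentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        )
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    x = rng.binomial(n1, num / n1, n_resamples).astype(float)
    y = rng.binomial(n2, den / n2, n_resamples).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (x / n1) / (y / n2)
    return tuple(
        np.nanpercentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    )


def format_point(x: float) -> str:
    """Render a ratio at report precision.

    Two significant figures at or above 1, two decimals below 1; values
    rounding to 1.00 print as "1.0" from either side; NaN prints "n.a."
    and exact 0 prints "0.00".
    """
    if math.isnan(x):
        return "n.a."
    if x == 0:
        return "0.00"
    if x < 1:
        s = f"{x:.2f}"
        return "1.0" if s == "1.00" else s
    if x < 10:
        return f"{x:.1f}"
    return f"{x:.0f}"


def format_ratio(est: EstimateWithCI) -> str:
    """Render an estimate and interval the way clinical tables print them,
    e.g. ``"1.8 (1.4–2.4)"``, bare ``"0.00"``, or ``"n.a."``."""
    if not est.defined:
        return "n.a."
    p = format_point(est.point)
    if est.ci_low is None:
        return p
    return f"{p} ({format_point(est.ci_low)}–{format_point(est.ci_high)})"


def format_or(est: EstimateWithCI) -> str:
    """Render an odds ratio at two decimals, e.g. ``"1.60 (1.18–2.18)"``."""
    if not est.defined:
        return "n.a."
    if est.ci_low is None:
        return f"{est.point:.2f}"
    return f"{est.point:.2f} ({est.ci_low:.2f}–{est.ci_high:.2f})"
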