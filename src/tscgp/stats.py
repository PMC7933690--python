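"""2x2 contingency analysis: test-selection rule, chi-square with and without
continuity correction, exact Fisher test, Woolf odds-ratio intervals, and the
crude logistic odds ratio.

Orientation contract for :class:`Table2x2`: rows are exposure (yes / no),
columns are outcome (RAML yes / no)::

            RAML   no RAML
  exposed     a       b
  unexposed   c       d

so OR = ad / bc and OR > 1 means the exposure is associated with RAML.

The test-selection rule mirrors common clinical-statistics practice: Fisher's
exact test when any expected count is below 1 or the total is below 40; the
continuity-corrected chi-square when the total is at least 40 but some
expected count is below 5; the plain chi-square otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "Table2x2", "TestResult", "ORResult", "DegenerateTableError",
    "expected_counts", "select_test", "chi_square_test", "fisher_exact_test",
    "run_selected_test", "odds_ratio_woolf", "logistic_crude_or",
]


class DegenerateTableError(ValueError):
    """Table with a zero margin (or all-zero), on which the test is undefined."""


@dataclass(frozen=True)
class Table2x2:
    a: int  # exposed, RAML
    b: int  # exposed, no RAML
    c: int  # unexposed, RAML
    d: int  # unexposed, no RAML

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("all-zero table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d

    @property
    def col_totals(self) -> tuple[int, int]:
        return self.a + self.c, self.b + self.d

    def swap_exposure(self) -> "Table2x2":
        return Table2x2(self.c, self.d, self.a, self.b)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    method: str  # chi_square | chi_square_yates | fisher_exact
    p_value: float
    statistic: Optional[float] = None  # absent for Fisher

    def to_dict(self) -> dict:
        return {"method": self.method, "statistic": self.statistic, "p_value": self.p_value}


@dataclass(frozen=True)
class ORResult:
    or_point: Optional[float]  # None when a zero cell leaves the OR undefined
    ci_low: Optional[float]
    ci_high: Optional[float]
    alpha: float
    method: str  # woolf | logistic_wald
    p_value: Optional[float] = None  # Wald p for the logistic method
    adjusted: bool = False  # Haldane-Anscombe 0.5 added to every cell

    @property
    def defined(self) -> bool:
        return self.or_point is not None

    def to_dict(self) -> dict:
        return {"or": self.or_point, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "alpha": self.alpha, "method": self.method, "p_value": self.p_value}


def expected_counts(t: Table2x2) -> np.ndarray:
    """Expected cell counts under independence: row total x col total / N."""
    r = np.array(t.row_totals, dtype=float)
    c = np.array(t.col_totals, dtype=float)
    return np.outer(r, c) / t.n


def select_test(t: Table2x2) -> str:
    """Method token per the selection rule (Fisher's condition takes precedence)."""
    e_min = expected_counts(t).min()
    if e_min < 1 or t.n < 40:
        return "fisher_exact"
    if e_min < 5:
        return "chi_square_yates"
    return "chi_square"


def chi_square_test(t: Table2x2, yates: bool = False) -> TestResult:
    """df=1 chi-square test from the closed form on the four cells.

    Uncorrected statistic N(ad-bc)^2 / (r1 r2 c1 c2); the Yates version
    replaces |ad-bc| by max(|ad-bc| - N/2, 0), so heavily discrete tables
    floor at statistic 0 / p = 1.
    """
    r1, r2 = t.row_totals
    c1, c2 = t.col_totals
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError(f"zero margin in table {t}")
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.n / 2, 0.0)
    stat = t.n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return TestResult(method="chi_square_yates" if yates else "chi_square",
                      p_value=p, statistic=float(stat))


def fisher_exact_test(t: Table2x2, *, tie_rel_tol: float = 1e-7) -> TestResult:
    """Two-sided Fisher exact p by the probability-mass rule.

    Conditional on both margins, cell ``a`` is hypergeometric; the two-sided
    p-value sums the probabilities of all tables no more probable than the
    observed one.  Table probabilities are compared through their exact
    integer weights C(r1, k) * C(r2, c1-k), so ties are exact and
    ``tie_rel_tol`` (kept for parity with floating implementations) has no
    effect at default settings.
    """
    r1, r2 = t.row_totals
    c1, _ = t.col_totals
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    if k_lo == k_hi:  # degenerate margins: single possible table
        return TestResult(method="fisher_exact", p_value=1.0)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)]
    obs = weights[t.a - k_lo]
    # all-integer comparison: w <= obs * (1 + tol) without any float rounding
    scale = 10 ** 9
    cutoff_num, cutoff_den = obs * (scale + int(tie_rel_tol * scale)), scale
    num = sum(w for w in weights if w * cutoff_den <= cutoff_num)
    from fractions import Fraction
    p = min(1.0, float(Fraction(num, sum(weights))))
    return TestResult(method="fisher_exact", p_value=p)


def run_selected_test(t: Table2x2) -> TestResult:
    """Apply the selection rule and run the chosen test."""
    method = select_test(t)
    if method == "fisher_exact":
        return fisher_exact_test(t)
    return chi_square_test(t, yates=(method == "chi_square_yates"))


def odds_ratio_woolf(t: Table2x2, alpha: float = 0.05, *,
                     haldane: bool = False) -> ORResult:
    """Cross-product odds ratio with the Woolf log-normal confidence interval.

    OR = ad/bc; CI = exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).  A zero
    cell leaves the OR undefined (flagged result) unless ``haldane`` adds 0.5
    to every cell.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    adjusted = False
    if min(a, b, c, d) == 0:
        if not haldane:
            return ORResult(None, None, None, alpha, "woolf")
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        adjusted = True
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(sps.norm.ppf(1 - alpha / 2))
    lo = math.exp(math.log(or_point) - z * se)
    hi = math.exp(math.log(or_point) + z * se)
    return ORResult(float(or_point), lo, hi, alpha, "woolf", adjusted=adjusted)


def logistic_crude_or(t: Table2x2, alpha: float = 0.05) -> ORResult:
    """Crude (single-predictor) logistic-regression odds ratio with Wald CI/p.

    Fits outcome ~ intercept + exposure by maximum likelihood on the N
    observations (frequency-weighted).  For a saturated 2x2 model the MLE
    slope equals ln(ad/bc) and the Wald interval equals the Woolf interval,
    so this agrees with :func:`odds_ratio_woolf` to numerical precision; a
    zero cell means separation and raises.
    """
    import statsmodels.api as sm

    if min(t.a, t.b, t.c, t.d) == 0:
        raise DegenerateTableError(
            f"zero cell in table {t}: the logistic MLE does not exist (separation)")
    X = sm.add_constant(np.array([[1.0], [1.0], [0.0], [0.0]]))
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array([t.a, t.b, t.c, t.d], dtype=float)
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
        tol=1e-12, maxiter=200)
    slope, se = fit.params[1], fit.bse[1]
    z = float(sps.norm.ppf(1 - alpha / 2))
    wald_z = slope / se
    p = 2 * float(sps.norm.sf(abs(wald_z)))
    return ORResult(float(math.exp(slope)), float(math.exp(slope - z * se)),
                    float(math.exp(slope + z * se)), alpha, "logistic_wald", p_value=p)
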