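"""Odds-ratio, confidence-interval, fold-enrichment and Bonferroni arithmetic.

The odds ratio compares overlap counts in the real trait-associated set
against a null (sampled or permuted) set:

    OR = (hits_real * nonhits_null) / (nonhits_real * hits_null)

Null cells may be non-integer (means over permutations or samples).  No
continuity correction is applied by default, so zero null cells yield
infinite ORs/bounds, reported literally as "Infinity"; a Haldane–Anscombe
+0.5 correction is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "DegenerateTableError",
    "odds_ratio",
    "wald_ci",
    "wald_pvalue",
    "fold_enrichment",
    "bonferroni_threshold",
]


class DegenerateTableError(ValueError):
    """Raised when an odds ratio is 0/0 and carries no information."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 overlap table: real (trait-associated) vs null margins.

    ``hits_null``/``nonhits_null`` may be real-valued means over null
    replicates.
    """

    hits_real: float
    nonhits_real: float
    hits_null: float
    nonhits_null: float

    def __post_init__(self):
        if min(self.hits_real, self.nonhits_real, self.hits_null, self.nonhits_null) < 0:
            raise ValueError("table cells must be nonnegative")
        if self.hits_real + self.nonhits_real <= 0:
            raise ValueError("real margin must be positive")
        if self.hits_null + self.nonhits_null <= 0:
            raise ValueError("null margin must be positive")

    def corrected(self) -> "ContingencyTable":
        """Haldane–Anscombe +0.5 on every cell."""
        return ContingencyTable(
            self.hits_real + 0.5,
            self.nonhits_real + 0.5,
            self.hits_null + 0.5,
            self.nonhits_null + 0.5,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-annotation enrichment: observed vs null, OR with CI and p."""

    annotation: str
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    pvalue_is_bound: bool
    fold_enrichment: float
    method: str  # "permutation" | "sampling" | "wald"


def odds_ratio(t: ContingencyTable) -> float:
    """(hits_real · nonhits_null) / (nonhits_real · hits_null).

    Returns +inf when the denominator vanishes with a positive numerator;
    a 0/0 table raises :class:`DegenerateTableError`.
    """
    num = t.hits_real * t.nonhits_null
    den = t.nonhits_real * t.hits_null
    if den == 0:
        if num == 0:
            raise DegenerateTableError(f"0/0 odds ratio for table {t}")
        return math.inf
    return num / den


def wald_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Wald (log-scale normal) confidence interval for the odds ratio.

    ``exp(ln OR ± z · sqrt(1/a + 1/b + 1/c + 1/d))``.  Any zero cell makes
    the interval unbounded on the corresponding side (0 or +inf).
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    a, b, c, d = t.hits_real, t.nonhits_real, t.hits_null, t.nonhits_null
    num_zero = a == 0 or d == 0  # OR = 0
    den_zero = b == 0 or c == 0  # OR = +inf
    if num_zero and den_zero:
        raise DegenerateTableError(f"uninformative zero pattern in {t}")
    if num_zero:
        return 0.0, wald_ci(t.corrected(), level)[1]
    if den_zero:
        return wald_ci(t.corrected(), level)[0], math.inf
    z = sps.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.log(odds_ratio(t)) - z * se
    hi = math.log(odds_ratio(t)) + z * se
    return math.exp(lo), math.exp(hi)


def wald_pvalue(t: ContingencyTable) -> float:
    """Two-sided normal-approximation p for ln OR ≠ 0.

    Zero cells give p via the Haldane–Anscombe-corrected table (the
    uncorrected statistic is infinite).
    """
    cells = (t.hits_real, t.nonhits_real, t.hits_null, t.nonhits_null)
    if min(cells) == 0:
        t = t.corrected()
    a, b, c, d = t.hits_real, t.nonhits_real, t.hits_null, t.nonhits_null
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log(odds_ratio(t)) / se
    return 2 * sps.norm.sf(abs(z))


def fold_enrichment(hits_obs: float, null_mean_hits: float) -> float:
    """Observed hits over mean null hits; approximates the OR when rare."""
    if null_mean_hits <= 0:
        raise DegenerateTableError("fold enrichment undefined for zero null hits")
    return hits_obs / null_mean_hits


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests
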