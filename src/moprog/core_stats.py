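"""Shared statistical primitives used by every pipeline stage.

Thin, validated wrappers around scipy/statsmodels that return a uniform
:class:`TestResult` so downstream tables carry a consistent schema
(statistic, two-sided p, context-dependent estimate, df or sample size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "DegenerateInputError",
    "fisher_exact",
    "bh_adjust",
    "t_test_two_sided",
    "pearson_cor",
    "hypergeom_upper_tail",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unable to support the test."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test.

    ``estimate`` is context dependent: an odds ratio for Fisher's exact
    test, a mean difference for the t test, a correlation coefficient for
    Pearson's test. ``df_or_n`` carries the degrees of freedom where the
    test has one, otherwise the sample size used.
    """

    statistic: float
    p_value: float
    estimate: float
    df_or_n: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _sample_odds_ratio(a: float, b: float, c: float, d: float) -> float:
    ad, bc = a * d, b * c
    if bc == 0:
        return float("nan") if ad == 0 else float("inf")
    return ad / bc


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p sums the probabilities of all tables (with the observed
    margins) whose point hypergeometric probability does not exceed the
    observed table's — the convention of R's ``fisher.test``. The estimate
    is the sample odds ratio ``ad/bc`` (``inf`` when ``bc == 0`` with
    ``ad > 0``, ``0`` when ``ad == 0`` with ``bc > 0``).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be nonnegative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise DegenerateInputError("all-zero 2x2 table")
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b = t[0]
    c, d = t[1]
    odds = _sample_odds_ratio(a, b, c, d)
    return TestResult(
        statistic=odds,
        p_value=float(min(res.pvalue, 1.0)),
        estimate=odds,
        df_or_n=float(t.sum()),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def t_test_two_sided(x, y, pooled: bool = True) -> TestResult:
    """Two-sided two-sample t test.

    Uses the pooled-variance Student statistic by default; ``pooled=False``
    switches to the Welch statistic. The degenerate case of zero variance
    in both groups with equal means returns ``t = 0, p = 1`` by convention.
    The estimate is ``mean(x) - mean(y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if diff == 0.0:
            df = float(x.size + y.size - 2)
            return TestResult(0.0, 1.0, 0.0, df)
        raise DegenerateInputError(
            "zero variance in both groups with unequal means"
        )
    res = stats.ttest_ind(x, y, equal_var=pooled)
    return TestResult(float(res.statistic), float(res.pvalue), diff, float(res.df))


def pearson_cor(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.var() == 0.0 or y.var() == 0.0:
        raise DegenerateInputError("zero variance input to pearson_cor")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    # t statistic of the correlation; guard the |r| = 1 boundary.
    if abs(r) >= 1.0:
        t_stat = float("inf") if r > 0 else float("-inf")
    else:
        t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
    return TestResult(float(t_stat), float(res.pvalue), r, float(n - 2))


def hypergeom_upper_tail(k: int, set_size: int, selected: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, set_size, selected).

    The upper-tail enrichment p used by overrepresentation analysis:
    drawing ``selected`` genes from a universe of ``universe`` that
    contains ``set_size`` set members, the probability of an overlap of
    at least ``k``.
    """
    if not (0 <= set_size <= universe and 0 <= selected <= universe):
        raise ValueError("require 0 <= set_size, selected <= universe")
    if not (0 <= k <= min(set_size, selected)):
        raise ValueError("require 0 <= k <= min(set_size, selected)")
    return float(stats.hypergeom.sf(k - 1, universe, set_size, selected))
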