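"""Univariate group comparison of the coagulation factors.

Each factor is compared between hematuria and non-hematuria records with a
two-sided pooled-variance Student t-test and a two-sided Mann-Whitney test,
then ranked by ascending t-test p-value.  A summary-only t-test is provided
so the published group statistics (mean, SD, n) can be re-tested without
raw data; the pooled (not Welch) form is the one consistent with the
published p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort, FACTOR_COLUMNS

__all__ = ["TestResult", "student_t_from_summary", "mann_whitney", "screen_factors"]

#: largest n1*n2 for which the exact Mann-Whitney null is enumerated
_EXACT_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    factor: str
    statistic: float
    p_value: float
    method: str  # "t" or "mann-whitney"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def student_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    factor: str = "",
) -> TestResult:
    """Two-sided pooled-variance Student t-test from group summaries alone."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var <= 0:
        raise ValueError("zero pooled variance; t-statistic undefined")
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(factor=factor, statistic=float(t), p_value=float(min(p, 1.0)), method="t")


def mann_whitney(values_a, values_b, factor: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when ``n1*n2 <= 400`` and the data are
    tie-free, and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= _EXACT_LIMIT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        factor=factor,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney",
    )


def screen_factors(
    cohort: Cohort, methods: tuple[str, ...] = ("t", "mann-whitney")
) -> list[TestResult]:
    """Compare every factor between the two label groups.

    Returns one :class:`TestResult` per factor per requested method, ordered
    by ascending t-test p-value (the reference reporting order); within a
    factor the t result precedes the Mann-Whitney result.
    """
    pos = cohort.group(True)
    neg = cohort.group(False)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("screening needs at least two records in each class")
    rows: dict[str, dict[str, TestResult]] = {}
    for f in FACTOR_COLUMNS:
        a = pos[f].to_numpy(dtype=float)
        b = neg[f].to_numpy(dtype=float)
        per: dict[str, TestResult] = {}
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant factors
            res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t_p):  # both groups constant and identical
            t_stat, t_p = 0.0, 1.0
        per["t"] = TestResult(f, t_stat, t_p, "t")
        if "mann-whitney" in methods:
            per["mann-whitney"] = mann_whitney(a, b, factor=f)
        rows[f] = per
    order = sorted(FACTOR_COLUMNS, key=lambda f: (rows[f]["t"].p_value, f))
    out: list[TestResult] = []
    for f in order:
        for m in methods:
            if m in rows[f]:
                out.append(rows[f][m])
    return out


def t_pvalue_ranking(cohort: Cohort) -> dict[str, float]:
    """Factor -> two-sided pooled t-test p-value on the cohort (pruning priority)."""
    return {
        r.factor: r.p_value for r in screen_factors(cohort, methods=("t",))
    }
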