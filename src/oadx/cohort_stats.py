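"""Supporting nonparametric statistics for cohort comparisons.

Thin, contract-enforcing wrappers around SciPy: median/IQR summaries,
the Mann-Whitney rank-sum test (exact for small untied samples, normal
approximation with tie and continuity corrections otherwise), Mood's
median test across k groups, and the one-sample proportion test used for
within-cohort sex balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError

__all__ = [
    "MedianSummary",
    "TestResult",
    "median_iqr",
    "mann_whitney",
    "moods_median_test",
    "one_sample_proportion",
]

#: largest pooled sample size at which the exact Mann-Whitney null is used
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class MedianSummary:
    """Median with interquartile range, the summary used for skewed assays."""

    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise DomainError("quartiles must satisfy q1 <= median <= q3")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p-value out of [0, 1]: {self.p_value}")


def median_iqr(values: Sequence[float]) -> MedianSummary:
    """Median and quartiles by linear interpolation between order statistics.

    This is numpy's default quantile convention; quartile conventions
    differ between stats packages, so the choice is fixed and documented
    here rather than configurable.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("median_iqr requires at least one value")
    if not np.all(np.isfinite(x)):
        raise DomainError("values must be finite")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return MedianSummary(n=int(x.size), median=float(med), q1=float(q1), q3=float(q3))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U rank-sum test for two independent samples.

    The exact null distribution is enumerated when the pooled size is at
    most ``EXACT_MW_LIMIT`` and no ties are present; otherwise the
    normal approximation with midrank tie correction and continuity
    correction is used.  The reported statistic is U for the first
    sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and pooled.size <= EXACT_MW_LIMIT
    res = stats.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney exact" if exact else "mann-whitney normal (cc)",
        n_per_group=(int(x.size), int(y.size)),
    )


def moods_median_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Mood's median test across two or more groups.

    Counts values above versus not-above the grand median in each group
    and applies a chi-square test to the 2xk table, without continuity
    correction (the convention of Minitab-style median tests; with k > 2
    a correction has no standard definition).
    """
    if len(groups) < 2:
        raise DomainError("Mood's median test requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise DegenerateDataError(
            "all values are identical: the 2xk median table is degenerate"
        )
    try:
        stat, p, grand_median, table = stats.median_test(
            *arrays, ties="below", correction=False
        )
    except ValueError as exc:  # e.g. all values on one side of the median
        raise DegenerateDataError(f"degenerate median table: {exc}") from exc
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method="mood's median (chi-square, no correction)",
        n_per_group=tuple(int(a.size) for a in arrays),
        extra={"grand_median": float(grand_median), "table": table.tolist()},
    )


def one_sample_proportion(x: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided test of a binomial proportion against ``p0``.

    The primary p-value is the exact binomial (minimum-likelihood) test;
    for n >= 30 the normal approximation with continuity correction is
    additionally reported under ``extra['p_normal_cc']`` along with its
    z statistic, since large-sample software typically prints that
    value.
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise DomainError("x and n must be integers")
    if n <= 0 or not 0 <= x <= n:
        raise DomainError(f"require 0 <= x <= n with n > 0, got x={x}, n={n}")
    if not 0 < p0 < 1:
        raise DomainError(f"p0 must lie in (0, 1), got {p0}")
    exact_p = float(stats.binomtest(int(x), int(n), p0).pvalue)
    extra: dict = {"p_hat": x / n}
    if n >= 30:
        se = math.sqrt(n * p0 * (1 - p0))
        diff = x - n * p0
        cc = min(0.5, abs(diff))  # continuity correction, never overshooting
        z = (abs(diff) - cc) / se
        extra["z"] = math.copysign(z, diff) if diff else 0.0
        extra["p_normal_cc"] = float(min(1.0, 2 * stats.norm.sf(z)))
    return TestResult(
        statistic=float(x),
        p_value=min(exact_p, 1.0),
        method="exact binomial (two-sided)",
        n_per_group=(int(n),),
        extra=extra,
    )
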