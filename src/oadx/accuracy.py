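"""2x2 contingency construction and diagnostic-performance statistics.

Implements the full MedCalc-style diagnostic test evaluation: sensitivity,
specificity, overall accuracy (each with exact Clopper-Pearson intervals),
predictive values and accuracy at arbitrary disease prevalence (Bayes'
theorem), likelihood ratios with log-method intervals, the Youden index,
and per-subgroup sensitivity tables.

Conventions
-----------
* Condition positive = clinically diagnosed primary OA; the RA, CA and
  NSA cohorts are pooled into a single condition-negative class.
* Proportion intervals are exact (beta-quantile) Clopper-Pearson, which
  is conservative: empirical coverage is at least nominal.
* PPV/NPV intervals at a chosen prevalence use the standard logit
  (delta-method) construction of Mercaldo et al.; these bounds depend on
  an unverifiable method choice upstream and are informational.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import DomainError, UndefinedMetricError
from .model import ClassificationResult, Specimen, _round_half_up

__all__ = [
    "ContingencyTable",
    "IntervalEstimate",
    "AccuracyReport",
    "SubgroupRow",
    "SubgroupTable",
    "build_contingency",
    "sensitivity",
    "specificity",
    "overall_accuracy",
    "clopper_pearson",
    "predictive_values",
    "accuracy_at_prevalence",
    "likelihood_ratios",
    "likelihood_ratio_intervals",
    "youden_index",
    "subgroup_sensitivity",
    "full_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FN/FP/TN counts with primary OA as the condition-positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise DomainError("contingency table must contain at least one count")

    @property
    def condition_positive(self) -> int:
        return self.tp + self.fn

    @property
    def condition_negative(self) -> int:
        return self.fp + self.tn

    @property
    def test_positive(self) -> int:
        return self.tp + self.fp

    @property
    def test_negative(self) -> int:
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.condition_positive / self.total


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    confidence: float = 0.95
    method: str = ""

    def __post_init__(self) -> None:
        if math.isfinite(self.point) and not (
            self.lower - 1e-12 <= self.point <= self.upper + 1e-12
        ):
            raise DomainError(
                f"interval [{self.lower}, {self.upper}] does not bracket "
                f"point {self.point}"
            )


def build_contingency(
    calls: Sequence[Union[str, bool, ClassificationResult]],
    truth: Sequence[Union[str, bool]],
) -> ContingencyTable:
    """Cross-tabulate test calls against clinical truth.

    ``calls`` may be "positive"/"negative" strings, booleans, or
    :class:`ClassificationResult` objects; ``truth`` may be
    "condition_positive"/"condition_negative" strings or booleans
    (True = primary OA).
    """
    if len(calls) != len(truth):
        raise DomainError(
            f"calls ({len(calls)}) and truth ({len(truth)}) differ in length"
        )
    if len(calls) == 0:
        raise DomainError("cannot build a contingency table from empty input")
    tp = fn = fp = tn = 0
    for c, t in zip(calls, truth):
        pos_call = _as_positive_call(c)
        pos_truth = _as_positive_truth(t)
        if pos_truth:
            tp, fn = (tp + 1, fn) if pos_call else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pos_call else (fp, tn + 1)
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


def _as_positive_call(c) -> bool:
    if isinstance(c, ClassificationResult):
        return c.is_positive
    if isinstance(c, (bool, np.bool_)):
        return bool(c)
    if isinstance(c, str) and c in ("positive", "negative"):
        return c == "positive"
    raise DomainError(f"unrecognised call {c!r}")


def _as_positive_truth(t) -> bool:
    if isinstance(t, (bool, np.bool_)):
        return bool(t)
    if isinstance(t, str) and t in ("condition_positive", "condition_negative"):
        return t == "condition_positive"
    raise DomainError(f"unrecognised truth label {t!r}")


def sensitivity(ct: ContingencyTable) -> float:
    """True-positive rate tp/(tp+fn)."""
    if ct.condition_positive == 0:
        raise UndefinedMetricError("sensitivity undefined: no condition positives")
    return ct.tp / ct.condition_positive


def specificity(ct: ContingencyTable) -> float:
    """True-negative rate tn/(tn+fp)."""
    if ct.condition_negative == 0:
        raise UndefinedMetricError("specificity undefined: no condition negatives")
    return ct.tn / ct.condition_negative


def overall_accuracy(ct: ContingencyTable) -> float:
    """Fraction of all specimens called correctly, (tp+tn)/total."""
    return (ct.tp + ct.tn) / ct.total


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> IntervalEstimate:
    """Exact two-sided binomial confidence interval via beta quantiles.

    The lower bound is 0 when ``x`` = 0 and the upper bound is 1 when
    ``x`` = ``n`` (the one-sided closed forms apply at the edges).
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise DomainError("x and n must be integers")
    if n <= 0 or not 0 <= x <= n:
        raise DomainError(f"require 0 <= x <= n with n > 0, got x={x}, n={n}")
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return IntervalEstimate(x / n, lower, upper, confidence, "clopper-pearson")


def predictive_values(
    sens: float, spec: float, prevalence: float
) -> tuple[float, float]:
    """Positive and negative predictive value at a given disease prevalence.

    Bayes' theorem on the error rates; at the sample prevalence this
    reproduces the column-wise ratios tp/(tp+fp) and tn/(tn+fn) of the
    contingency table exactly.  Prevalence endpoints are rejected
    (degenerate populations); sensitivity or specificity of exactly 0
    or 1 is allowed and only fails when it produces a zero denominator.
    """
    if not 0 < prevalence < 1:
        raise DomainError(
            f"prevalence must lie strictly in (0, 1), got {prevalence}"
        )
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    ppv_den = sens * prevalence + (1 - spec) * (1 - prevalence)
    npv_den = spec * (1 - prevalence) + (1 - sens) * prevalence
    if ppv_den == 0 or npv_den == 0:
        raise UndefinedMetricError("predictive value has zero denominator")
    return sens * prevalence / ppv_den, spec * (1 - prevalence) / npv_den


def accuracy_at_prevalence(sens: float, spec: float, prevalence: float) -> float:
    """Prevalence-weighted overall accuracy, prev*sens + (1-prev)*spec."""
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    return prevalence * sens + (1 - prevalence) * spec


def likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec) and LR- = (1-sens)/spec.

    ``spec`` = 1 yields LR+ = +inf (a flagged, CI-free estimate rather
    than an exception); ``spec`` = 0 likewise yields LR- = +inf.
    """
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    lr_pos = math.inf if spec == 1 else sens / (1 - spec)
    lr_neg = math.inf if spec == 0 else (1 - sens) / spec
    return lr_pos, lr_neg


def likelihood_ratio_intervals(
    ct: ContingencyTable, confidence: float = 0.95
) -> tuple[IntervalEstimate, IntervalEstimate]:
    """Likelihood ratios with standard log-method confidence intervals.

    The interval is exp(ln LR +/- z * SE) with
    SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)) and the
    mirrored expression for LR-.  Degenerate margins (a zero cell in the
    SE formula) yield infinite bounds rather than an exception.
    """
    sens_, spec_ = sensitivity(ct), specificity(ct)
    lr_pos, lr_neg = likelihood_ratios(sens_, spec_)
    z = float(stats.norm.ppf(0.5 + confidence / 2))

    def _log_interval(point: float, se: float) -> tuple[float, float]:
        if not math.isfinite(point) or point == 0 or not math.isfinite(se):
            return (0.0, math.inf)
        return (point * math.exp(-z * se), point * math.exp(z * se))

    se_pos = (
        math.sqrt(1 / ct.tp - 1 / ct.condition_positive
                  + 1 / ct.fp - 1 / ct.condition_negative)
        if ct.tp > 0 and ct.fp > 0
        else math.inf
    )
    se_neg = (
        math.sqrt(1 / ct.fn - 1 / ct.condition_positive
                  + 1 / ct.tn - 1 / ct.condition_negative)
        if ct.fn > 0 and ct.tn > 0
        else math.inf
    )
    lo_p, hi_p = _log_interval(lr_pos, se_pos)
    lo_n, hi_n = _log_interval(lr_neg, se_neg)
    return (
        IntervalEstimate(lr_pos, lo_p, hi_p, confidence, "log"),
        IntervalEstimate(lr_neg, lo_n, hi_n, confidence, "log"),
    )


def youden_index(sens: float, spec: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    return sens + spec - 1


# ---------------------------------------------------------------------------
# subgroup sensitivity


@dataclass(frozen=True)
class SubgroupRow:
    group: object
    n: int
    tp: int
    sensitivity: IntervalEstimate


@dataclass(frozen=True)
class SubgroupTable:
    rows: tuple[SubgroupRow, ...]
    excluded: tuple[str, ...]  # ids of condition positives without a group value

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group": [r.group for r in self.rows],
                "n": [r.n for r in self.rows],
                "tp": [r.tp for r in self.rows],
                "sensitivity": [r.sensitivity.point for r in self.rows],
                "ci_lower": [r.sensitivity.lower for r in self.rows],
                "ci_upper": [r.sensitivity.upper for r in self.rows],
            }
        )


def subgroup_sensitivity(
    specimens: Sequence[Specimen],
    calls: Sequence[Union[str, bool, ClassificationResult]],
    group_key: Union[str, Callable[[Specimen], object]] = "kl_grade",
    confidence: float = 0.95,
) -> SubgroupTable:
    """Per-subgroup sensitivity among condition-positive specimens.

    ``group_key`` is a specimen attribute name (default the radiographic
    KL grade) or a callable.  Condition positives whose group value is
    missing are listed in ``excluded`` rather than silently dropped;
    included groups partition the remaining condition positives.
    """
    if len(specimens) != len(calls):
        raise DomainError("specimens and calls differ in length")
    key = (lambda s: getattr(s, group_key)) if isinstance(group_key, str) else group_key
    groups: dict = {}
    excluded: list[str] = []
    for s, c in zip(specimens, calls):
        if not s.condition_positive:
            continue
        g = key(s)
        if g is None:
            excluded.append(s.id)
            continue
        n, tp = groups.get(g, (0, 0))
        groups[g] = (n + 1, tp + int(_as_positive_call(c)))
    rows = tuple(
        SubgroupRow(g, n, tp, clopper_pearson(tp, n, confidence))
        for g, (n, tp) in sorted(groups.items(), key=lambda kv: str(kv[0]))
    )
    return SubgroupTable(rows=rows, excluded=tuple(excluded))


# ---------------------------------------------------------------------------
# aggregate report


@dataclass(frozen=True)
class AccuracyReport:
    """Everything a diagnostic-accuracy write-up reports for one 2x2 table."""

    table: ContingencyTable
    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    accuracy: IntervalEstimate
    ppv: IntervalEstimate
    npv: IntervalEstimate
    lr_pos: IntervalEstimate
    lr_neg: IntervalEstimate
    youden_j: float
    prevalence_used: float
    n: int
    confidence: float = 0.95

    def __post_init__(self) -> None:
        j = self.sensitivity.point + self.specificity.point - 1
        if abs(j - self.youden_j) > 1e-12:
            raise DomainError("youden_j inconsistent with sensitivity/specificity")


def _logit_predictive_interval(
    point: float, sens_ie: IntervalEstimate, spec_ie: IntervalEstimate,
    ct: ContingencyTable, prevalence: float, which: str, confidence: float,
) -> IntervalEstimate:
    """Delta-method logit interval for PPV/NPV at arbitrary prevalence."""
    sens_, spec_ = sens_ie.point, spec_ie.point
    n1, n0 = ct.condition_positive, ct.condition_negative
    var_sens = sens_ * (1 - sens_) / n1 if n1 else math.nan
    var_spec = spec_ * (1 - spec_) / n0 if n0 else math.nan
    # gradient of the logit: logit PPV = ln(sens*p) - ln((1-spec)*(1-p)),
    # logit NPV = ln(spec*(1-p)) - ln((1-sens)*p); prevalence is fixed
    try:
        if which == "ppv":
            d_sens = 1 / sens_
            d_spec = 1 / (1 - spec_)
        else:
            d_sens = 1 / (1 - sens_)
            d_spec = 1 / spec_
        var_logit = d_sens**2 * var_sens + d_spec**2 * var_spec
    except ZeroDivisionError:
        var_logit = math.inf
    if not math.isfinite(var_logit) or point in (0.0, 1.0):
        return IntervalEstimate(point, 0.0, 1.0, confidence, "logit (degenerate)")
    z = float(stats.norm.ppf(0.5 + confidence / 2))
    logit = math.log(point / (1 - point))
    lo = 1 / (1 + math.exp(-(logit - z * math.sqrt(var_logit))))
    hi = 1 / (1 + math.exp(-(logit + z * math.sqrt(var_logit))))
    return IntervalEstimate(point, lo, hi, confidence, "logit")


def full_report(
    ct: ContingencyTable,
    prevalence: Optional[float] = None,
    confidence: float = 0.95,
) -> AccuracyReport:
    """Aggregate every diagnostic statistic for a contingency table.

    With no ``prevalence``, predictive values and accuracy are evaluated
    at the sample prevalence, where they coincide with the direct column
    ratios of the table (and accuracy gets an exact Clopper-Pearson
    interval on tp+tn successes).  With an explicit ``prevalence``, PPV,
    NPV and accuracy are prevalence-adjusted via Bayes' theorem; the
    adjusted accuracy interval uses a delta-method normal approximation.
    """
    sample_prev = ct.prevalence
    at_sample = prevalence is None
    prev = sample_prev if at_sample else float(prevalence)
    if not 0 < prev < 1:
        raise DomainError(f"prevalence must lie strictly in (0, 1), got {prev}")

    sens_ie = clopper_pearson(ct.tp, ct.condition_positive, confidence)
    spec_ie = clopper_pearson(ct.tn, ct.condition_negative, confidence)
    sens_, spec_ = sens_ie.point, spec_ie.point
    ppv, npv = predictive_values(sens_, spec_, prev)
    acc = accuracy_at_prevalence(sens_, spec_, prev)

    if at_sample:
        acc_ie = clopper_pearson(ct.tp + ct.tn, ct.total, confidence)
        # keep the Bayes-consistent point (identical to (tp+tn)/total)
        acc_ie = IntervalEstimate(acc, acc_ie.lower, acc_ie.upper, confidence,
                                  "clopper-pearson")
    else:
        n1, n0 = ct.condition_positive, ct.condition_negative
        var = (prev**2 * sens_ * (1 - sens_) / n1
               + (1 - prev) ** 2 * spec_ * (1 - spec_) / n0)
        z = float(stats.norm.ppf(0.5 + confidence / 2))
        acc_ie = IntervalEstimate(
            acc, max(0.0, acc - z * math.sqrt(var)),
            min(1.0, acc + z * math.sqrt(var)), confidence, "delta-normal",
        )
    ppv_ie = _logit_predictive_interval(ppv, sens_ie, spec_ie, ct, prev, "ppv",
                                        confidence)
    npv_ie = _logit_predictive_interval(npv, sens_ie, spec_ie, ct, prev, "npv",
                                        confidence)
    lr_pos_ie, lr_neg_ie = likelihood_ratio_intervals(ct, confidence)
    return AccuracyReport(
        table=ct,
        sensitivity=sens_ie,
        specificity=spec_ie,
        accuracy=acc_ie,
        ppv=ppv_ie,
        npv=npv_ie,
        lr_pos=lr_pos_ie,
        lr_neg=lr_neg_ie,
        youden_j=youden_index(sens_, spec_),
        prevalence_used=prev,
        n=ct.total,
        confidence=confidence,
    )
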