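"""Empirical ROC analysis for the COMP/IL-8 ratio score.

The ratio is the continuous score underlying the binary decision rule;
its ROC curve summarises how well it separates primary OA from the
pooled inflammatory-arthritis class at every possible cut-off.  Two
scoring policies are offered because the published algorithm never
computes a ratio for specimens failing the COMP gate:

* ``ratio_everywhere`` (default) — score every specimen by comp/il8.
* ``gated_zero`` — specimens at or below the COMP gate score 0 (they can
  never be called positive, whatever the ratio limit).

AUC uses the trapezoidal rule on the empirical curve, which equals the
Mann-Whitney probability of correct pairwise ordering (ties count 1/2).
The AUC confidence interval is DeLong's, from the variance of placement
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .accuracy import IntervalEstimate
from .errors import DegenerateDataError, DomainError
from .model import DecisionLimits, Specimen, compute_ratio

__all__ = [
    "RocCurve",
    "roc_score",
    "empirical_roc",
    "auc_ci_delong",
    "optimal_threshold",
]

POLICIES = ("ratio_everywhere", "gated_zero")


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: descending thresholds with aligned rates.

    The convention is "call positive when score > threshold"; the first
    threshold is the maximum score (nothing lies strictly above it, the
    (0,0) corner) and the last is -inf (everything positive, the (1,1)
    corner).
    """

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float

    def __post_init__(self) -> None:
        t, f, s = self.thresholds, self.fpr, self.tpr
        if not (len(t) == len(f) == len(s) >= 2):
            raise DomainError("curve needs >= 2 aligned points")
        if any(later > earlier for later, earlier in zip(t[1:], t[:-1])):
            raise DomainError("thresholds must be non-increasing")
        if any(a > b for a, b in zip(f[:-1], f[1:])) or any(
            a > b for a, b in zip(s[:-1], s[1:])
        ):
            raise DomainError("tpr and fpr must be non-decreasing")
        if not (f[0] == s[0] == 0.0 and f[-1] == s[-1] == 1.0):
            raise DomainError("curve must run from (0,0) to (1,1)")
        if not 0.0 <= self.auc <= 1.0:
            raise DomainError(f"auc out of range: {self.auc}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.array(self.thresholds), np.array(self.fpr), np.array(self.tpr))


def roc_score(
    s: Specimen,
    policy: str = "ratio_everywhere",
    limits: Optional[DecisionLimits] = None,
) -> float:
    """Continuous score for one specimen under the chosen policy."""
    if policy not in POLICIES:
        raise DomainError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy == "gated_zero":
        if limits is None:
            raise DomainError("gated_zero scoring requires decision limits")
        if s.comp <= limits.comp_limit:
            return 0.0
    return compute_ratio(s.comp, s.il8)


def empirical_roc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Build the empirical ROC curve from scores and truth labels.

    ``labels`` are truthy for condition positives.  Thresholds are the
    unique observed scores in descending order (tied scores grouped),
    followed by -inf for the (1,1) corner; the operating point at
    threshold t counts every specimen scoring strictly above t.
    """
    y = np.asarray([bool(l) for l in labels])
    x = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise DomainError("scores and labels must be equal-length 1-D sequences")
    if not np.all(np.isfinite(x)):
        raise DomainError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError(
            "ROC requires both classes present "
            f"(got {n_pos} positives, {n_neg} negatives)"
        )
    order = np.argsort(-x, kind="mergesort")
    xs, ys = x[order], y[order]
    # group ties: cumulative counts evaluated at the last index of each group
    distinct = np.r_[np.nonzero(np.diff(xs))[0], len(xs) - 1]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(~ys)[distinct]
    thresholds = np.r_[xs[distinct], -np.inf]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=tuple(float(t) for t in thresholds),
        fpr=tuple(float(v) for v in fpr),
        tpr=tuple(float(v) for v in tpr),
        auc=auc,
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (midrank fractions) for each observation."""
    v10 = np.array(
        [(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos]
    )
    v01 = np.array(
        [(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg]
    )
    return v10, v01


def auc_ci_delong(
    scores: Sequence[float], labels: Sequence[bool], confidence: float = 0.95
) -> IntervalEstimate:
    """AUC with DeLong's asymptotic confidence interval.

    Variance is s10/m + s01/n from the sample variances of placement
    values; the interval is truncated to [0, 1].  Perfect separation
    yields zero variance and a degenerate interval at the point.
    """
    from scipy import stats

    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    y = np.asarray([bool(l) for l in labels])
    x = np.asarray(scores, dtype=float)
    pos, neg = x[y], x[~y]
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateDataError(
            "DeLong interval requires >= 2 specimens per class "
            f"(got {len(pos)} positives, {len(neg)} negatives)"
        )
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))
    z = float(stats.norm.ppf(0.5 + confidence / 2))
    half = z * math.sqrt(max(var, 0.0))
    return IntervalEstimate(
        auc, max(0.0, auc - half), min(1.0, auc + half), confidence, "delong"
    )


def optimal_threshold(curve: RocCurve) -> tuple[float, float]:
    """Youden-optimal operating point: (threshold, J at threshold).

    Maximises tpr - fpr over the curve; ties are broken toward the
    larger threshold (the more specific rule).
    """
    best_j = -math.inf
    best_t = math.inf
    for t, f, s in zip(curve.thresholds, curve.fpr, curve.tpr):
        j = s - f
        if j > best_j:  # first occurrence wins; thresholds descend
            best_j, best_t = j, t
    return best_t, best_j
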