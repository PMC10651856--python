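"""Diagnostic-test evaluation and ROC machinery.

2x2 contingency tables; sensitivity / specificity / PPV / NPV / accuracy
with 95% confidence intervals (Clopper-Pearson exact for the direct
proportions, standard-logit for the predictive values); Bayes-rule
reconstruction of predictive values from (sensitivity, specificity,
prevalence); empirical ROC curves whose AUC is the Mann-Whitney statistic
(ties counted 1/2) with a Hanley-McNeil normal-approximation CI; and
cutoff selection by the sensitivity x specificity product or the Youden
index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .cycle_data import ValidationError

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "MetricEstimate",
    "ROCCurve",
    "build_contingency",
    "diagnostic_metrics",
    "format_percent",
    "metrics_from_rates",
    "roc_curve",
    "select_cutoff",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Counts with "positive" meaning the condition is present."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a nonnegative count, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        if self.total == 0:
            raise ValidationError("empty contingency table")
        return (self.tp + self.fn) / self.total


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its 95% CI; ``defined=False`` marks a 0/0 case."""

    point: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    defined: bool = True

    @property
    def percent(self) -> Optional[float]:
        return None if self.point is None else 100.0 * self.point


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate


def build_contingency(
    truth: Sequence[int], predicted: Sequence[int]
) -> ContingencyTable:
    """Cross-tabulate binary truth and prediction vectors."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValidationError("truth and predicted must be equal-length, nonempty")
    t = t.astype(bool)
    p = p.astype(bool)
    return ContingencyTable(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def _exact_ci(successes: int, trials: int) -> Tuple[float, float]:
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="beta")
    return float(lo), float(hi)


def _logit_ci(successes: int, trials: int) -> Tuple[float, float]:
    """Standard-logit CI for a proportion (predictive-value convention)."""
    failures = trials - successes
    if successes == 0 or failures == 0:
        # logit undefined at the boundary; fall back to the exact interval
        return _exact_ci(successes, trials)
    p = successes / trials
    logit = math.log(p / (1 - p))
    se = math.sqrt(1.0 / successes + 1.0 / failures)
    lo = logit - Z95 * se
    hi = logit + Z95 * se
    return 1.0 / (1.0 + math.exp(-lo)), 1.0 / (1.0 + math.exp(-hi))


def _proportion(
    successes: int, trials: int, ci_policy: str
) -> MetricEstimate:
    if trials == 0:
        return MetricEstimate(point=None, defined=False)
    point = successes / trials
    if ci_policy == "exact":
        lo, hi = _exact_ci(successes, trials)
    elif ci_policy == "logit":
        lo, hi = _logit_ci(successes, trials)
    elif ci_policy == "wilson":
        lo, hi = proportion_confint(successes, trials, alpha=0.05, method="wilson")
        lo, hi = float(lo), float(hi)
    else:
        raise ValidationError(f"unknown CI policy {ci_policy!r}")
    return MetricEstimate(point=point, ci_low=lo, ci_high=hi)


def diagnostic_metrics(
    table: ContingencyTable,
    proportion_ci: str = "exact",
    predictive_ci: str = "logit",
) -> DiagnosticMetrics:
    """Sens/spec/PPV/NPV/accuracy with 95% CIs from a 2x2 table.

    A metric with an empty denominator is returned undefined rather than
    failing the whole computation.
    """
    if table.total == 0:
        raise ValidationError("empty contingency table")
    return DiagnosticMetrics(
        sensitivity=_proportion(table.tp, table.tp + table.fn, proportion_ci),
        specificity=_proportion(table.tn, table.tn + table.fp, proportion_ci),
        ppv=_proportion(table.tp, table.tp + table.fp, predictive_ci),
        npv=_proportion(table.tn, table.tn + table.fn, predictive_ci),
        accuracy=_proportion(table.tp + table.tn, table.total, proportion_ci),
    )


def metrics_from_rates(
    sensitivity: float, specificity: float, prevalence: float = 0.5
) -> Tuple[Optional[float], Optional[float], float]:
    """(PPV, NPV, accuracy) implied by Bayes' rule at a given prevalence.

    The balanced default (0.5) matches the convention under which
    published predictive values of day-contrast markers are mutually
    consistent (equal numbers of positive-day and comparison-day visits).
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [0, 1]")
    p = prevalence
    ppv_den = sensitivity * p + (1.0 - specificity) * (1.0 - p)
    npv_den = specificity * (1.0 - p) + (1.0 - sensitivity) * p
    ppv = sensitivity * p / ppv_den if ppv_den > 0 else None
    npv = specificity * (1.0 - p) / npv_den if npv_den > 0 else None
    accuracy = sensitivity * p + specificity * (1.0 - p)
    return ppv, npv, accuracy


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve over all distinct score thresholds.

    ``thresholds`` are on the original score scale and decreasing in
    aggressiveness: a point's (sensitivity, 1-specificity) is obtained by
    calling positive every score at or beyond that threshold in the
    positive direction.
    """

    thresholds: Tuple[float, ...]
    sensitivity: Tuple[float, ...]
    one_minus_specificity: Tuple[float, ...]
    auc: float
    auc_ci: Tuple[float, float]
    n_positive: int
    n_negative: int
    higher_is_positive: bool = True

    def points(self) -> Tuple[Tuple[float, float, float], ...]:
        return tuple(
            zip(self.thresholds, self.sensitivity, self.one_minus_specificity)
        )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_curve(
    scores: Sequence[float],
    truth: Sequence[int],
    higher_is_positive: bool = True,
) -> ROCCurve:
    """Empirical ROC with Mann-Whitney AUC (ties 1/2) and Hanley-McNeil CI.

    ``higher_is_positive=False`` orients the curve for markers where a
    *lower* (e.g. more negative percent-change) score indicates the
    positive day; thresholds are reported on the original scale.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(bool)
    if s.shape != t.shape or s.ndim != 1 or s.size == 0:
        raise ValidationError("scores and truth must be equal-length, nonempty")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be represented")
    oriented = s if higher_is_positive else -s
    fpr, tpr, thr = _sk_roc_curve(t.astype(int), oriented, drop_intermediate=False)
    auc = float(_trapezoid_auc(fpr, tpr))
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    thresholds = thr if higher_is_positive else -thr
    return ROCCurve(
        thresholds=tuple(float(x) for x in thresholds),
        sensitivity=tuple(float(x) for x in tpr),
        one_minus_specificity=tuple(float(x) for x in fpr),
        auc=auc,
        auc_ci=ci,
        n_positive=n_pos,
        n_negative=n_neg,
        higher_is_positive=higher_is_positive,
    )


def select_cutoff(
    curve: ROCCurve, criterion: str = "sens_times_spec"
) -> Tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing the criterion.

    ``"sens_times_spec"`` maximizes the product; ``"youden"`` maximizes
    sensitivity + specificity - 1.  Ties break toward higher specificity,
    then toward the higher threshold.
    """
    if criterion not in ("sens_times_spec", "youden"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    best = None
    for thr, sens, fpr in curve.points():
        if not math.isfinite(thr):
            continue
        spec = 1.0 - fpr
        value = sens * spec if criterion == "sens_times_spec" else sens + spec - 1.0
        key = (value, spec, thr if curve.higher_is_positive else -thr)
        if best is None or key > best[0]:
            best = (key, (float(thr), float(sens), float(spec)))
    if best is None:
        raise ValidationError("degenerate ROC curve: no finite thresholds")
    return best[1]


def format_percent(fraction: float) -> str:
    """Render a proportion as a percent to one decimal, rounding half up."""
    value = Decimal(str(100.0 * fraction)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{value}%"
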