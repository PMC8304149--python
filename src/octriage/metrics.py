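"""Diagnostic-accuracy arithmetic.

Confusion-count metrics with exact (Clopper-Pearson) binomial confidence
intervals, ROC/AUC, and the one-sample proportion sample-size computation
with dropout inflation. Percent renditions round half-up, matching the way
diagnostic tables are conventionally printed; metrics with a zero
denominator are reported as absent, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .exceptions import DomainError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")
        if self.total < 1:
            raise DomainError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricValue:
    """One diagnostic proportion with its exact CI and percent rendition."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    percent: int

    @property
    def ci_percent(self) -> tuple[int, int]:
        return round_half_up(self.ci_low * 100), round_half_up(self.ci_high * 100)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricValue | None
    specificity: MetricValue | None
    ppv: MetricValue | None
    npv: MetricValue | None
    accuracy: MetricValue | None
    level: float


def round_half_up(x: float, ndigits: int = 0) -> int | float:
    """Round with ties away from zero (printed-table convention)."""
    factor = 10**ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
    return int(r) if ndigits == 0 else r


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    ``low = BetaInv(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``high = BetaInv(1-alpha/2; x+1, n-x)`` (1 when x = n).
    """
    if not 0 < level < 1:
        raise DomainError("confidence level must be in (0, 1)")
    if n < 1 or not 0 <= x <= n:
        raise DomainError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _metric(x: int, n: int, level: float) -> MetricValue | None:
    if n == 0:
        return None
    low, high = exact_binomial_ci(x, n, level)
    return MetricValue(
        numerator=x,
        denominator=n,
        point=x / n,
        ci_low=low,
        ci_high=high,
        percent=round_half_up(100.0 * x / n),
    )


def confusion_metrics(c: ConfusionCounts, level: float = 0.95) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs."""
    return DiagnosticMetrics(
        sensitivity=_metric(c.tp, c.tp + c.fn, level),
        specificity=_metric(c.tn, c.tn + c.fp, level),
        ppv=_metric(c.tp, c.tp + c.fp, level),
        npv=_metric(c.tn, c.tn + c.fn, level),
        accuracy=_metric(c.tp + c.tn, c.total, level),
        level=level,
    )


def roc_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Stepwise ROC curve (fpr, tpr, thresholds) and trapezoidal AUC.

    Tied scores advance the curve in one simultaneous step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise DomainError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels.astype(int), scores)
    auc = float(_skm.auc(fpr, tpr))
    return fpr, tpr, thr, auc


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    return roc_curve(scores, labels)[3]


@dataclass(frozen=True)
class SampleSizeSpec:
    """One-sample sensitivity test design: null p0 vs alternative p1."""

    p0: float
    p1: float
    alpha: float = 0.05
    power: float = 0.80
    dropout_rate: float = 0.20

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "alpha", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DomainError(f"{name} must be in (0, 1), got {v}")
        if self.p0 == self.p1:
            raise DomainError("p0 and p1 must differ")
        if not 0 <= self.dropout_rate < 1:
            raise DomainError("dropout_rate must be in [0, 1)")


def sample_size_sensitivity(spec: SampleSizeSpec) -> int:
    """Two-sided normal-approximation one-sample proportion sample size.

    ``n = ceil(((z_{1-a/2} sqrt(p0 q0) + z_{1-b} sqrt(p1 q1)) / (p1-p0))^2)``.
    For p0=0.85, p1=0.91, alpha=0.05, power=0.80 this yields 246.
    """
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    num = z_a * math.sqrt(spec.p0 * (1 - spec.p0)) + z_b * math.sqrt(
        spec.p1 * (1 - spec.p1)
    )
    return int(math.ceil((num / (spec.p1 - spec.p0)) ** 2))


def inflate_for_dropout(n: int, rate: float) -> int:
    """Enrollment size after allowing for a dropout fraction: ceil(n(1+r))."""
    if not 0 <= rate < 1:
        raise DomainError("dropout rate must be in [0, 1)")
    if n < 0:
        raise DomainError("n must be non-negative")
    return int(math.ceil(n * (1.0 + rate)))
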