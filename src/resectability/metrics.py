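"""Confusion-matrix metrics for a single-operating-point binary test.

The positive class throughout is *non-resectable*: a true positive is a
patient correctly flagged as non-resectable before surgery.  Because each
assessor produces a single binary call, its ROC has one interior operating
point and the area under it equals balanced accuracy, ``(Se + Sp) / 2``.

Point metrics carry 95% confidence intervals: Wilson score intervals for
the binomial proportions (sensitivity, specificity, predictive values,
accuracy) and a normal interval on the structural-component (DeLong-type)
standard error for the AUC of a binary score.  F-beta scores are reported
without intervals; they are ratios of correlated counts with no standard
closed-form interval, and the paired bootstrap in
:mod:`resectability.noninferiority` covers inference on their differences.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables;
    Python's builtin ``round`` is half-even)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with non-resectable as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            if iv != v or iv < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, iv)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Reference non-resectable ("diseased") count."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """Reference resectable count."""
        return self.tn + self.fp


def confusion(predictions: Sequence, references: Sequence) -> ConfusionCounts:
    """Cross-tabulate aligned prediction/reference label sequences.

    Indeterminate predictions and inoperable reference labels must have
    been removed upstream; encountering one raises.
    """
    from .criteria import PredictedLabel, ReferenceLabel  # cycle guard

    if len(predictions) != len(references):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(references)} references"
        )
    tp = fp = fn = tn = 0
    for pred, ref in zip(predictions, references):
        if pred is PredictedLabel.INDETERMINATE:
            raise ValueError("indeterminate prediction must be dropped upstream")
        if ref is ReferenceLabel.EXCLUDED_INOPERABLE:
            raise ValueError("inoperable reference label must be excluded upstream")
        p = pred is PredictedLabel.NON_RESECTABLE
        r = ref is ReferenceLabel.NON_RESECTABLE
        if p and r:
            tp += 1
        elif p:
            fp += 1
        elif r:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class IntervalMethod:
    proportion_method: str = "wilson"  # or "clopper_pearson"
    auc_method: str = "delong_binary"  # or "hanley_mcneil"


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)


def _proportion_interval(successes, n, confidence, method):
    if n == 0:
        return None
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method=sm_method)
    return float(lo), float(hi)


def auc_interval(
    counts: ConfusionCounts,
    method: IntervalMethod = IntervalMethod(),
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Normal-theory interval for the single-operating-point AUC.

    ``delong_binary`` uses the structural-component variance of the
    empirical AUC for a two-valued score,
    ``SE^2 = [Se(1-Se)/n1 + Sp(1-Sp)/n2] / 4``; ``hanley_mcneil`` uses the
    exponential-approximation variance with ``Q1 = A/(2-A)`` and
    ``Q2 = 2A^2/(1+A)``.  Bounds are truncated to [0, 1].
    """
    n1, n2 = counts.n_pos, counts.n_neg
    if n1 == 0 or n2 == 0:
        raise ValueError("both reference classes must be non-empty")
    se = counts.tp / n1
    sp = counts.tn / n2
    a = (se + sp) / 2.0
    if method.auc_method == "delong_binary":
        var = (se * (1 - se) / n1 + sp * (1 - sp) / n2) / 4.0
    elif method.auc_method == "hanley_mcneil":
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    else:
        raise ValueError(f"unknown AUC interval method {method.auc_method!r}")
    z = norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, a - half), min(1.0, a + half)


@dataclass(frozen=True)
class MetricSet:
    """Point metrics (proportions in [0, 1]; None when the denominator is 0)
    with per-metric 95% intervals under ``ci`` (keys ``sensitivity`` ...
    ``auc``; absent when undefined)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    fbeta: dict = field(default_factory=dict)
    auc: Optional[float] = None
    ci: dict = field(default_factory=dict)

    def percent(self, name: str, ndigits: int = 1) -> Optional[float]:
        value = getattr(self, name)
        return None if value is None else round_half_up(100.0 * value, ndigits)


def f_beta(ppv: float, se: float, beta: float) -> float:
    """F-beta from precision and recall; beta < 1 up-weights precision."""
    b2 = beta * beta
    denom = b2 * ppv + se
    if denom == 0:
        raise ZeroDivisionError("F-beta undefined when precision and recall are both 0")
    return (1 + b2) * ppv * se / denom


def point_metrics(
    counts: ConfusionCounts,
    betas: Sequence[float] = (1.0, 0.5),
    confidence: float = 0.95,
    methods: IntervalMethod = IntervalMethod(),
) -> MetricSet:
    """All point metrics of a 2x2 table, with confidence intervals.

    Zero-denominator metrics are set to None with a logged warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on an empty table")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    pieces = {
        "sensitivity": (tp, counts.n_pos),
        "specificity": (tn, counts.n_neg),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
        "accuracy": (tp + tn, counts.total),
    }
    values: dict[str, Optional[float]] = {}
    cis: dict[str, tuple[float, float]] = {}
    for name, (k, n) in pieces.items():
        if n == 0:
            logger.warning("%s undefined (zero denominator)", name)
            values[name] = None
            continue
        values[name] = k / n
        cis[name] = _proportion_interval(k, n, confidence, methods.proportion_method)
    fbeta: dict[float, Optional[float]] = {}
    for beta in betas:
        if values["ppv"] is None or values["sensitivity"] is None or (
            values["ppv"] == 0 and values["sensitivity"] == 0
        ):
            logger.warning("F_%g undefined (zero denominator)", beta)
            fbeta[beta] = None
        else:
            fbeta[beta] = f_beta(values["ppv"], values["sensitivity"], beta)
    auc = None
    if counts.n_pos > 0 and counts.n_neg > 0:
        auc = (values["sensitivity"] + values["specificity"]) / 2.0
        cis["auc"] = auc_interval(counts, methods, confidence)
    return MetricSet(
        sensitivity=values["sensitivity"],
        specificity=values["specificity"],
        ppv=values["ppv"],
        npv=values["npv"],
        accuracy=values["accuracy"],
        fbeta=fbeta,
        auc=auc,
        ci=cis,
    )


class DiagnosticAccuracy:
    """Single-modality diagnostic accuracy against the surgical reference.

    A thin model object in the fit/results idiom: construct from aligned
    label sequences (or a cohort plus an assessor), call :meth:`fit`, and
    read estimates, intervals and a rendered summary off the results.
    """

    def __init__(self, predictions: Sequence, references: Sequence, label: str = ""):
        self.counts = confusion(predictions, references)
        self.label = label

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, label: str = "") -> "DiagnosticAccuracy":
        obj = cls.__new__(cls)
        obj.counts = counts
        obj.label = label
        return obj

    @classmethod
    def from_cohort(cls, cohort, assessor, label: str = "") -> "DiagnosticAccuracy":
        from .criteria import modality_labels

        preds, refs, _ = modality_labels(cohort, assessor)
        return cls(preds, refs, label=label or assessor.value)

    def fit(
        self,
        betas: Sequence[float] = (1.0, 0.5),
        confidence: float = 0.95,
        methods: IntervalMethod = IntervalMethod(),
    ) -> "DiagnosticAccuracyResults":
        metrics = point_metrics(self.counts, betas=betas, confidence=confidence,
                                methods=methods)
        return DiagnosticAccuracyResults(self.label, self.counts, metrics, confidence)


@dataclass(frozen=True)
class DiagnosticAccuracyResults:
    label: str
    counts: ConfusionCounts
    metrics: MetricSet
    confidence: float = 0.95

    def summary(self) -> str:
        from .report import render_metric_table  # cycle guard

        return render_metric_table([self])
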