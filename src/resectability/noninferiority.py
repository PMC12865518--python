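"""Paired non-inferiority tests for two modalities read on the same patients.

Both tests are one-sided shifted Z tests with margin Delta (default 5
percentage points): the null hypothesis is that modality A is worse than
modality B by at least Delta, H0: theta_A - theta_B <= -Delta, rejected
(non-inferiority concluded) when Z = (delta_hat + Delta) / SE > z_{1-alpha}.

For the AUC of binary reads, the paired standard error comes from the
structural components of the DeLong decomposition.  For two-valued scores
the placement value of a diseased patient is 0.5 * (x_i + Sp), so the
placement *differences* between modalities reduce to 0.5 * (x_A - x_B)
plus a constant within each reference class, and

    SE^2 = [ S^2_d(x_A - x_B) / n1 + S^2_nd(x_A - x_B) / n2 ] / 4

with S^2 the within-class sample variance (ddof 1).  The F1 test offers an
analytic delta-method variance over the multinomial of the eight joint
cells (label_A x label_B x reference) and a patient-level paired bootstrap
(the default: more robust when cells are small).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Reported in place of an exact p-value when the paired difference is
#: degenerate (identical predictions => zero standard error).
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class PairedPredictions:
    """Per-patient binary predictions of two modalities plus the reference.

    Complete cases only: every patient carries both modality calls and a
    binary reference (True = non-resectable).
    """

    label_a: np.ndarray
    label_b: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.label_a, dtype=bool)
        b = np.asarray(self.label_b, dtype=bool)
        r = np.asarray(self.reference, dtype=bool)
        if not (a.shape == b.shape == r.shape) or a.ndim != 1:
            raise ValueError("label_a, label_b and reference must be equal-length 1-D")
        if a.size < 2:
            raise ValueError("need at least two paired patients")
        object.__setattr__(self, "label_a", a)
        object.__setattr__(self, "label_b", b)
        object.__setattr__(self, "reference", r)

    @property
    def n(self) -> int:
        return self.reference.size

    @property
    def n_pos(self) -> int:
        return int(self.reference.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.reference).sum())

    def take(self, idx: np.ndarray) -> "PairedPredictions":
        return PairedPredictions(self.label_a[idx], self.label_b[idx], self.reference[idx])

    @classmethod
    def from_cohort(cls, cohort, assessor_a, assessor_b) -> "PairedPredictions":
        """Complete-case paired labels for two assessors of a cohort.

        Inoperable patients must already be excluded; indeterminate
        predictions (NA rule) are dropped with a logged count.
        """
        from .criteria import PredictedLabel, ReferenceLabel, classify_prediction, derive_reference

        la, lb, ref = [], [], []
        dropped = 0
        for r in cohort:
            if not (r.has(assessor_a) and r.has(assessor_b)) or r.outcome is None:
                dropped += 1
                continue
            y = derive_reference(r.outcome)
            if y is ReferenceLabel.EXCLUDED_INOPERABLE:
                raise ValueError(
                    f"patient {r.patient_id} is inoperable; run exclude_inoperable first"
                )
            pa = classify_prediction(r.assessments[assessor_a])
            pb = classify_prediction(r.assessments[assessor_b])
            if PredictedLabel.INDETERMINATE in (pa, pb):
                dropped += 1
                continue
            la.append(pa is PredictedLabel.NON_RESECTABLE)
            lb.append(pb is PredictedLabel.NON_RESECTABLE)
            ref.append(y is ReferenceLabel.NON_RESECTABLE)
        if dropped:
            logger.info("paired labels %s vs %s: dropped %d record(s)",
                        assessor_a.value, assessor_b.value, dropped)
        return cls(np.array(la), np.array(lb), np.array(ref))


@dataclass(frozen=True)
class NoninfResult:
    statistic_name: str  # "AUC" or "F1"
    estimate_a: float
    estimate_b: float
    delta_hat: float
    margin: float
    se_diff: float
    z: float
    p_one_sided: float
    conclusion: str  # "noninferior" or "not_demonstrated"
    alpha: float
    variance_engine: str = "analytic"
    b_reps: Optional[int] = None
    seed: Optional[int] = None
    n: Optional[int] = None

    def summary(self) -> str:
        return (
            f"{self.statistic_name}: A={self.estimate_a:.3f} B={self.estimate_b:.3f} "
            f"diff={self.delta_hat:+.3f} margin={self.margin:g} "
            f"Z={self.z:.3f} p={self.p_one_sided:.4g} -> {self.conclusion}"
        )

    def to_json(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(payload, sort_keys=True)


def _conclude(delta_hat: float, margin: float, se: float, alpha: float):
    """Shared Z / p / conclusion logic, with the degenerate-SE convention."""
    if se > 0:
        z = (delta_hat + margin) / se
        p = float(norm.sf(z))
    else:
        # Identical (or perfectly offsetting) predictions: declare by sign.
        z = math.inf if delta_hat + margin > 0 else -math.inf
        p = P_FLOOR if delta_hat + margin > 0 else 1.0
        logger.info("degenerate zero SE; conclusion by sign of delta_hat + margin")
    conclusion = "noninferior" if p < alpha else "not_demonstrated"
    return z, p, conclusion


def _auc_components(pairs: PairedPredictions):
    """Per-modality AUC estimates and the paired structural-component SE."""
    d = pairs.reference
    n1, n2 = pairs.n_pos, pairs.n_neg
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two patients in each reference class")
    xa, xb = pairs.label_a.astype(float), pairs.label_b.astype(float)
    se_a, se_b = xa[d].mean(), xb[d].mean()
    sp_a, sp_b = 1 - xa[~d].mean(), 1 - xb[~d].mean()
    auc_a = (se_a + sp_a) / 2
    auc_b = (se_b + sp_b) / 2
    u = xa[d] - xb[d]
    v = xa[~d] - xb[~d]
    var = (u.var(ddof=1) / n1 + v.var(ddof=1) / n2) / 4.0
    return auc_a, auc_b, math.sqrt(max(var, 0.0))


def paired_auc_noninf(
    pairs: PairedPredictions, margin: float = 0.05, alpha: float = 0.05
) -> NoninfResult:
    """One-sided non-inferiority test of AUC_A - AUC_B against -margin."""
    auc_a, auc_b, se = _auc_components(pairs)
    delta_hat = auc_a - auc_b
    z, p, conclusion = _conclude(delta_hat, margin, se, alpha)
    return NoninfResult(
        statistic_name="AUC", estimate_a=auc_a, estimate_b=auc_b,
        delta_hat=delta_hat, margin=margin, se_diff=se, z=z, p_one_sided=p,
        conclusion=conclusion, alpha=alpha, variance_engine="analytic", n=pairs.n,
    )


# ---------------------------------------------------------------------------
# F1

def _f1_from_arrays(x: np.ndarray, r: np.ndarray) -> Optional[float]:
    tp = float(np.sum(x & r))
    fp = float(np.sum(x & ~r))
    fn = float(np.sum(~x & r))
    denom = 2 * tp + fp + fn
    return None if denom == 0 else 2 * tp / denom


def _joint_cells(pairs: PairedPredictions) -> np.ndarray:
    """Counts of the 8 joint cells, indexed [label_a, label_b, reference]."""
    cells = np.zeros((2, 2, 2))
    np.add.at(cells, (pairs.label_a.astype(int), pairs.label_b.astype(int),
                      pairs.reference.astype(int)), 1)
    return cells


def _f1_diff_from_cells(cells: np.ndarray) -> float:
    tp_a = cells[1, :, 1].sum()
    fp_a = cells[1, :, 0].sum()
    fn_a = cells[0, :, 1].sum()
    tp_b = cells[:, 1, 1].sum()
    fp_b = cells[:, 1, 0].sum()
    fn_b = cells[:, 0, 1].sum()
    return 2 * tp_a / (2 * tp_a + fp_a + fn_a) - 2 * tp_b / (2 * tp_b + fp_b + fn_b)


def _f1_delta_method_se(pairs: PairedPredictions) -> float:
    """Delta-method SE of F1_A - F1_B over the multinomial of joint cells.

    The statistic is scale-invariant in the cell counts, so the gradient in
    the cell probabilities can be taken by finite differences on the
    unnormalized count vector.
    """
    n = pairs.n
    cells = _joint_cells(pairs)
    p = cells.ravel() / n
    base = _f1_diff_from_cells(cells)
    h = 1e-6
    grad = np.zeros(8)
    for k in range(8):
        bumped = p.copy()
        bumped[k] += h
        grad[k] = (_f1_diff_from_cells(bumped.reshape(2, 2, 2)) - base) / h
    mean_g = float(p @ grad)
    var = float(p @ (grad ** 2) - mean_g ** 2) / n
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class BootstrapSummary:
    se: float
    percentile_interval: tuple[float, float]
    n_skipped: int
    b_reps: int
    seed: int


def bootstrap_paired(
    pairs: PairedPredictions,
    statistic: Callable[[PairedPredictions], Optional[float]],
    b_reps: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> BootstrapSummary:
    """Patient-level paired bootstrap of an arbitrary statistic.

    Resamples whole patients (keeping the two modality calls and reference
    together), evaluates ``statistic`` per resample, and summarizes the
    resample distribution.  Resamples where the statistic is undefined
    (None/NaN) are skipped with a count.  Deterministic given ``seed``.
    """
    if b_reps < 100:
        raise ValueError("b_reps < 100 gives an unusable SE estimate")
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(b_reps):
        idx = rng.integers(0, pairs.n, size=pairs.n)
        value = statistic(pairs.take(idx))
        if value is None or (isinstance(value, float) and math.isnan(value)):
            skipped += 1
        else:
            values.append(value)
    if not values:
        raise ValueError("statistic undefined on every resample")
    arr = np.asarray(values, dtype=float)
    lo, hi = np.quantile(arr, [(1 - confidence) / 2, (1 + confidence) / 2])
    se = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return BootstrapSummary(se=se, percentile_interval=(float(lo), float(hi)),
                            n_skipped=skipped, b_reps=b_reps, seed=seed)


def paired_f1_noninf(
    pairs: PairedPredictions,
    margin: float = 0.05,
    alpha: float = 0.05,
    engine: str = "bootstrap",
    b_reps: int = 2000,
    seed: int = 0,
) -> NoninfResult:
    """One-sided non-inferiority test of F1_A - F1_B against -margin.

    ``engine="analytic"`` uses the multinomial delta method;
    ``engine="bootstrap"`` (default) a patient-level paired bootstrap.
    """
    f1_a = _f1_from_arrays(pairs.label_a, pairs.reference)
    f1_b = _f1_from_arrays(pairs.label_b, pairs.reference)
    if f1_a is None or f1_b is None:
        raise ValueError("F1 undefined for a modality (no predicted or actual positives)")
    delta_hat = f1_a - f1_b
    b_used = seed_used = None
    if engine == "analytic":
        se = _f1_delta_method_se(pairs)
    elif engine == "bootstrap":
        def stat(resample: PairedPredictions) -> Optional[float]:
            a = _f1_from_arrays(resample.label_a, resample.reference)
            b = _f1_from_arrays(resample.label_b, resample.reference)
            return None if a is None or b is None else a - b

        boot = bootstrap_paired(pairs, stat, b_reps=b_reps, seed=seed)
        se = boot.se
        b_used, seed_used = b_reps, seed
    else:
        raise ValueError(f"unknown engine {engine!r}")
    z, p, conclusion = _conclude(delta_hat, margin, se, alpha)
    return NoninfResult(
        statistic_name="F1", estimate_a=f1_a, estimate_b=f1_b, delta_hat=delta_hat,
        margin=margin, se_diff=se, z=z, p_one_sided=p, conclusion=conclusion,
        alpha=alpha, variance_engine=engine, b_reps=b_used, seed=seed_used, n=pairs.n,
    )


class PairedNoninferiority:
    """Model-style front end: build from paired predictions, ``fit()`` runs
    the chosen test and returns a :class:`NoninfResult`."""

    def __init__(
        self,
        pairs: PairedPredictions,
        statistic: str = "auc",
        margin: float = 0.05,
        alpha: float = 0.05,
        engine: str = "bootstrap",
        b_reps: int = 2000,
        seed: int = 0,
    ):
        if statistic not in ("auc", "f1"):
            raise ValueError("statistic must be 'auc' or 'f1'")
        self.pairs = pairs
        self.statistic = statistic
        self.margin = margin
        self.alpha = alpha
        self.engine = engine
        self.b_reps = b_reps
        self.seed = seed

    @classmethod
    def from_cohort(cls, cohort, assessor_a, assessor_b, **kwargs) -> "PairedNoninferiority":
        return cls(PairedPredictions.from_cohort(cohort, assessor_a, assessor_b), **kwargs)

    def fit(self) -> NoninfResult:
        if self.statistic == "auc":
            return paired_auc_noninf(self.pairs, margin=self.margin, alpha=self.alpha)
        return paired_f1_noninf(self.pairs, margin=self.margin, alpha=self.alpha,
                                engine=self.engine, b_reps=self.b_reps, seed=self.seed)
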