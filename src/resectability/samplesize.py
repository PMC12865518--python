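"""Sample size for non-inferiority comparison of two correlated AUCs.

The design question: how many patients are needed so that a one-sided
shifted Z test at level alpha has the desired power to declare one test
non-inferior to another (margin Delta) when both truly have the same AUC?
With n1 diseased patients,

    n1 = (z_{1-alpha} + z_{1-power})^2 * 2 * V(A) * (1 - rho) / Delta^2

where V(A) is the per-diseased-patient variance function of a single AUC
estimate and rho the correlation between the two tests' AUC estimates
(they are read on the same patients, so rho > 0 shrinks the required n).
Total patients = n1 * (1 + R), R the non-diseased : diseased allocation.

Two variance functions are provided:

- ``binormal``: the Obuchowski-McClish closed form
  ``V(A) = 0.0099 * exp(-a^2/2) * (5 a^2 + 8 + (a^2 + 8)/R)``,
  a = Phi^{-1}(A) * sqrt(2), appropriate when planning for a continuous or
  rating-scale test;
- ``binary``: the exact operating-point variance
  ``V = [Se(1-Se) + Sp(1-Sp)/R] / 4`` of a single-threshold test, used to
  cross-check the analytic power against Monte-Carlo power of the paired
  test in this package.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Non-diseased : diseased allocation observed in the motivating cohort
#: (119 resectable per 48 non-resectable complete cases).
DEFAULT_RATIO = 119 / 48


@dataclass(frozen=True)
class SampleSizeSpec:
    """Planning parameters for the correlated-AUC non-inferiority design.

    ``auc_both`` is the common planning AUC of the two tests; ``rho`` the
    assumed correlation of their AUC estimates (0.5 by default; studies of
    paired imaging reads rarely report it, and values from ~0.3 to ~0.95
    are plausible depending on how much the modalities share); ``ratio``
    the non-diseased : diseased allocation.
    """

    auc_both: float = 0.78
    margin: float = 0.05
    alpha: float = 0.05  # one-sided
    power: float = 0.90
    rho: float = 0.5
    ratio: float = DEFAULT_RATIO
    variance: str = "binormal"  # or "binary"
    se_sp: Optional[tuple[float, float]] = None  # operating point for "binary"

    def __post_init__(self):
        if not 0.5 < self.auc_both < 1:
            raise ValueError("auc_both must lie in (0.5, 1)")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.variance not in ("binormal", "binary"):
            raise ValueError("variance must be 'binormal' or 'binary'")
        if self.variance == "binary" and self.se_sp is None:
            raise ValueError("binary variance requires the (Se, Sp) operating point")
        if self.margin >= self.auc_both - 0.5:
            logger.warning(
                "margin %.3g is not small relative to auc_both - 0.5 = %.3g",
                self.margin, self.auc_both - 0.5,
            )


def binormal_auc_variance(auc: float, ratio: float) -> float:
    """Obuchowski-McClish binormal variance function V(A), per diseased patient."""
    a = norm.ppf(auc) * math.sqrt(2.0)
    return 0.0099 * math.exp(-a * a / 2.0) * (5 * a * a + 8 + (a * a + 8) / ratio)


def binary_auc_variance(se: float, sp: float, ratio: float) -> float:
    """Operating-point variance of a binary test's AUC, per diseased patient."""
    return (se * (1 - se) + sp * (1 - sp) / ratio) / 4.0


def _variance(spec: SampleSizeSpec) -> float:
    if spec.variance == "binormal":
        return binormal_auc_variance(spec.auc_both, spec.ratio)
    se, sp = spec.se_sp
    return binary_auc_variance(se, sp, spec.ratio)


def required_n(spec: SampleSizeSpec) -> int:
    """Total patients (diseased + non-diseased, ceiling) for the design."""
    z = norm.ppf(1 - spec.alpha) + norm.ppf(spec.power)
    n1 = z * z * 2.0 * _variance(spec) * (1 - spec.rho) / (spec.margin ** 2)
    return math.ceil(n1 * (1 + spec.ratio))


def power_at_n(spec: SampleSizeSpec, n: int) -> float:
    """Achieved power of the design at a total sample size of n patients."""
    if n < 4:
        raise ValueError("n must be at least 4")
    n1 = n / (1 + spec.ratio)
    se_diff = math.sqrt(2.0 * _variance(spec) * (1 - spec.rho) / n1)
    return float(norm.cdf(spec.margin / se_diff - norm.ppf(1 - spec.alpha)))
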