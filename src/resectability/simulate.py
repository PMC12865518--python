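"""Synthetic cohort generator with the dependence structure the analysis assumes.

Generative model, per patient:

1. draw true resectability (non-resectable with probability ``prevalence``),
   and independently an *inoperable* flag (frailty, unrelated to the tumor);
2. draw the true site-involvement vector: for a non-resectable patient each
   of the eight sites independently with its conditional probability,
   re-drawn until at least one site is involved (non-resectability is the
   presence of at least one prohibitive site); resectable patients use the
   (by default zero) resectable-site probabilities;
3. each assessor reads each site through a latent-Gaussian threshold: with a
   patient-site latent ``w`` shared by all assessors and assessor-specific
   noise ``e``, site s is called positive when
   ``Phi(sqrt(rho) w + sqrt(1-rho) e)`` falls below the assessor's per-site
   detection probability (sensitivity if the site is involved, false-call
   rate otherwise).  ``inter_modality_rho`` spans conditional independence
   (0) to near-duplicated reads (-> 1) with correct marginals throughout;
4. the surgical outcome follows truth: non-resectable -> R2 (suboptimal or
   not feasible at laparoscopy), resectable -> R0/R1; the inoperable flag
   overrides the outcome to R2/inoperable;
5. WB-DWI/MRI is dropped at the configured missingness rate.

:func:`calibrate_from_margins` inverts published margins into generator
parameters by moment matching of the OR-aggregated detection probability:
the truth prevalence and per-site involvement probabilities are solved from
the surgical-exploration margins and operating point, and each assessor's
uniform per-site sensitivity/false-call rate from its patient-level
operating point.  Imaging per-site margins are consequently only
approximate -- patient-level operating points are the calibration targets.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import norm

from . import study_counts as sc
from .cohort import (
    Approach,
    Assessor,
    Cohort,
    N_CRITERIA,
    PatientRecord,
    R2Reason,
    Residual,
    SiteAssessment,
    SurgicalOutcome,
)

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """The requested margins are unattainable under the site model."""


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the generator; a pure function of
    (config, config.seed) determines the cohort."""

    n_patients: int
    prevalence: float = 48 / 167
    site_probs_nonresectable: tuple[float, ...] = (0.7,) * N_CRITERIA
    site_probs_resectable: tuple[float, ...] = (0.0,) * N_CRITERIA
    #: per-assessor uniform per-site detection probability given involvement
    sensitivity: Mapping[Assessor, float] = field(default_factory=dict)
    #: per-assessor uniform per-site detection probability given no involvement
    false_call: Mapping[Assessor, float] = field(default_factory=dict)
    inter_modality_rho: float = 0.25
    inoperable_fraction: float = 18 / 242
    mri_missing_fraction: float = 60 / 242
    r0_fraction: float = 145 / 162          # R0 share among resectable outcomes
    suboptimal_fraction: float = 23 / 62    # suboptimal share among true R2
    seed: int = 0

    def __post_init__(self):
        probs = (
            [self.prevalence, self.inoperable_fraction, self.mri_missing_fraction,
             self.r0_fraction, self.suboptimal_fraction]
            + list(self.site_probs_nonresectable)
            + list(self.site_probs_resectable)
            + list(self.sensitivity.values())
            + list(self.false_call.values())
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0 <= self.inter_modality_rho < 1:
            raise ValueError("inter_modality_rho must lie in [0, 1)")
        if len(self.site_probs_nonresectable) != N_CRITERIA:
            raise ValueError(f"need {N_CRITERIA} site probabilities")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for mapping in (self.sensitivity, self.false_call):
            if set(mapping) - set(Assessor):
                raise ValueError("sensitivity/false_call keyed by Assessor")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "prevalence": self.prevalence,
            "site_probs_nonresectable": list(self.site_probs_nonresectable),
            "site_probs_resectable": list(self.site_probs_resectable),
            "sensitivity": {a.value: float(v) for a, v in self.sensitivity.items()},
            "false_call": {a.value: float(v) for a, v in self.false_call.items()},
            "inter_modality_rho": self.inter_modality_rho,
            "inoperable_fraction": self.inoperable_fraction,
            "mri_missing_fraction": self.mri_missing_fraction,
            "r0_fraction": self.r0_fraction,
            "suboptimal_fraction": self.suboptimal_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimConfig":
        payload = dict(payload)
        for key in ("sensitivity", "false_call"):
            payload[key] = {Assessor(k): float(v) for k, v in payload.get(key, {}).items()}
        for key in ("site_probs_nonresectable", "site_probs_resectable"):
            if key in payload:
                payload[key] = tuple(float(v) for v in payload[key])
        return cls(**payload)


# ---------------------------------------------------------------------------
# Closed-form patient-level operating characteristics

def _truncated_miss_probability(p: np.ndarray, se: float, f: float) -> float:
    """P(no site called | non-resectable) under the >= 1-involved-site rule."""
    p = np.asarray(p, dtype=float)
    p0 = float(np.prod(1 - p))
    if p0 >= 1.0:
        raise ValueError("non-resectable site probabilities are all zero")
    untrunc = float(np.prod(p * (1 - se) + (1 - p) * (1 - f)))
    return (untrunc - p0 * (1 - f) ** N_CRITERIA) / (1 - p0)


def patient_sensitivity(config: SimConfig, assessor: Assessor) -> float:
    """P(any site called | non-resectable) implied by the site model."""
    return 1.0 - _truncated_miss_probability(
        np.asarray(config.site_probs_nonresectable),
        config.sensitivity[assessor], config.false_call[assessor],
    )


def patient_specificity(config: SimConfig, assessor: Assessor) -> float:
    """P(no site called | resectable) implied by the site model."""
    q = np.asarray(config.site_probs_resectable, dtype=float)
    se = config.sensitivity[assessor]
    f = config.false_call[assessor]
    return float(np.prod(1 - q * se - (1 - q) * f))


def _solve_site_sensitivity(
    p: np.ndarray, f: float, target_se: float, cap: float = 1.0
) -> float:
    """Uniform per-site sensitivity achieving a patient-level sensitivity."""
    def gap(se):
        return (1.0 - _truncated_miss_probability(p, se, f)) - target_se

    if gap(cap) < -1e-12:
        raise CalibrationError(
            f"patient-level sensitivity {target_se:.3f} unattainable: the site model "
            f"tops out at {gap(cap) + target_se:.3f} (per-site sensitivity cap {cap})"
        )
    if gap(0.0) >= 0:
        logger.warning("target patient-level sensitivity %.3f at or below the "
                       "false-call floor; using per-site sensitivity 0", target_se)
        return 0.0
    if gap(cap) <= 0:
        return float(cap)
    return float(brentq(gap, 0.0, cap, xtol=1e-12))


# ---------------------------------------------------------------------------
# Calibration from published margins

def calibrate_from_margins(
    site_freqs: Sequence[float],
    operating_points: Mapping[Assessor, tuple[float, float]],
    any_freq: Optional[float] = None,
    prevalence: Optional[float] = None,
    n_patients: int = 242,
    inter_modality_rho: float = 0.25,
    inoperable_fraction: float = 18 / 242,
    mri_missing_fraction: float = 60 / 242,
    seed: int = 0,
    max_site_sensitivity: float = 1.0,
) -> SimConfig:
    """Invert marginal site frequencies and operating points to a SimConfig.

    ``site_freqs`` are the surgical-exploration site-involvement fractions
    (the truth anchor); ``operating_points`` maps each assessor to its
    patient-level (Se, Sp).  When ``any_freq`` (the surgical any-criterion
    fraction) is given, the truth prevalence is solved from it; otherwise
    ``prevalence`` (default 48/167) is used directly.

    Raises :class:`CalibrationError` when a requested patient-level
    sensitivity exceeds what the site model can attain.
    """
    site_freqs = np.asarray(list(site_freqs), dtype=float)
    if site_freqs.size != N_CRITERIA:
        raise ValueError(f"need {N_CRITERIA} site frequencies")
    if Assessor.SURG_EXPL not in operating_points:
        raise ValueError("operating_points must include SURG_EXPL (the truth anchor)")
    se_surg, sp_surg = operating_points[Assessor.SURG_EXPL]
    f_surg = 1.0 - sp_surg ** (1.0 / N_CRITERIA)

    if any_freq is not None:
        fpr = 1.0 - sp_surg
        pi = (any_freq - fpr) / (se_surg - fpr)
        if not 0 < pi < 1:
            raise CalibrationError(
                f"any-criterion frequency {any_freq} inconsistent with the surgical "
                f"operating point (implied prevalence {pi:.3f})"
            )
    else:
        pi = 48 / 167 if prevalence is None else prevalence

    # Joint fixed point: truth site probabilities p and the surgical per-site
    # sensitivity depend on each other through the >= 1-site conditioning.
    se_site = min(max(se_surg, f_surg + 1e-6), max_site_sensitivity)
    p = np.clip(site_freqs / max(pi, 1e-9), 1e-4, 0.995)
    for _ in range(60):
        p0 = float(np.prod(1 - p))
        marginal = (site_freqs - f_surg) / (pi * (se_site - f_surg))
        p_new = np.clip(marginal * (1 - p0), 1e-4, 0.995)
        se_new = _solve_site_sensitivity(p_new, f_surg, se_surg, max_site_sensitivity)
        if np.allclose(p_new, p, atol=1e-10) and abs(se_new - se_site) < 1e-10:
            p, se_site = p_new, se_new
            break
        p, se_site = p_new, se_new

    sensitivity, false_call = {}, {}
    for assessor, (target_se, target_sp) in operating_points.items():
        f_a = 1.0 - target_sp ** (1.0 / N_CRITERIA)
        false_call[assessor] = f_a
        sensitivity[assessor] = _solve_site_sensitivity(
            p, f_a, target_se, max_site_sensitivity
        )

    return SimConfig(
        n_patients=n_patients,
        prevalence=pi,
        site_probs_nonresectable=tuple(float(v) for v in p),
        sensitivity=sensitivity,
        false_call=false_call,
        inter_modality_rho=inter_modality_rho,
        inoperable_fraction=inoperable_fraction,
        mri_missing_fraction=mri_missing_fraction,
        seed=seed,
    )


def default_sim_config(n_patients: int = 242, seed: int = 0, **overrides) -> SimConfig:
    """Generator calibrated to the published study margins."""
    site = [c / 242 for c in sc.SITE_COUNTS[Assessor.SURG_EXPL]]
    config = calibrate_from_margins(
        site, sc.OPERATING_POINTS, any_freq=sc.ANY_COUNTS[Assessor.SURG_EXPL] / 242,
        n_patients=n_patients, seed=seed,
    )
    return replace(config, **overrides) if overrides else config


# ---------------------------------------------------------------------------
# Simulation core (vectorized over replicates)

_ASSESSOR_ORDER = tuple(Assessor)


def _simulate_arrays(config: SimConfig, rng: np.random.Generator, reps: int = 1,
                     assessors: Optional[Sequence[Assessor]] = None) -> dict:
    """Vectorized draw of ``reps`` cohorts; returns raw boolean arrays.

    The RNG call order is fixed so the same seed yields the same cohort
    regardless of which assessors the caller consumes.
    """
    if assessors is None:
        assessors = [a for a in _ASSESSOR_ORDER if a in config.sensitivity]
    n = config.n_patients
    p_nr = np.asarray(config.site_probs_nonresectable)
    p_r = np.asarray(config.site_probs_resectable)

    truth = rng.random((reps, n)) < config.prevalence
    base = rng.random((reps, n, N_CRITERIA))
    involved = np.where(truth[..., None], base < p_nr, base < p_r)
    # Non-resectability requires at least one prohibitive site: rejection-redraw
    # all-zero involvement vectors of non-resectable patients.
    if p_nr.max() > 0:
        while True:
            bad = truth & ~involved.any(axis=-1)
            k = int(bad.sum())
            if k == 0:
                break
            involved[bad] = rng.random((k, N_CRITERIA)) < p_nr

    rho = config.inter_modality_rho
    shared = rng.standard_normal((reps, n, N_CRITERIA))
    labels, site_calls = {}, {}
    for assessor in _ASSESSOR_ORDER:
        if assessor not in config.sensitivity:
            continue
        noise = rng.standard_normal((reps, n, N_CRITERIA))
        u = ndtr(math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise)
        p_detect = np.where(involved, config.sensitivity[assessor],
                            config.false_call[assessor])
        if assessor in assessors:
            calls = u < p_detect
            site_calls[assessor] = calls
            labels[assessor] = calls.any(axis=-1)

    inoperable = rng.random((reps, n)) < config.inoperable_fraction
    mri_missing = rng.random((reps, n)) < config.mri_missing_fraction
    outcome_aux = rng.random((reps, n))
    return {
        "truth": truth, "involved": involved, "site_calls": site_calls,
        "labels": labels, "inoperable": inoperable, "mri_missing": mri_missing,
        "outcome_aux": outcome_aux,
    }


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate one cohort; deterministic given (config, config.seed)."""
    rng = np.random.default_rng(config.seed)
    arrays = _simulate_arrays(config, rng, reps=1)
    records = []
    for i in range(config.n_patients):
        truth = bool(arrays["truth"][0, i])
        inoperable = bool(arrays["inoperable"][0, i])
        aux = float(arrays["outcome_aux"][0, i])
        if inoperable:
            outcome = SurgicalOutcome(
                Residual.R2, R2Reason.INOPERABLE,
                Approach.LAPAROSCOPY if aux < 11 / 18 else Approach.LAPAROTOMY)
        elif truth:
            if aux < config.suboptimal_fraction:
                outcome = SurgicalOutcome(Residual.R2,
                                          R2Reason.SUBOPTIMAL_AFTER_MAX_EFFORT,
                                          Approach.LAPAROTOMY)
            else:
                outcome = SurgicalOutcome(Residual.R2,
                                          R2Reason.NOT_FEASIBLE_AT_LAPAROSCOPY,
                                          Approach.LAPAROSCOPY)
        else:
            residual = Residual.R0 if aux < config.r0_fraction else Residual.R1
            outcome = SurgicalOutcome(residual, approach=Approach.LAPAROTOMY)

        mri_available = (Assessor.WB_DWI_MRI in config.sensitivity
                         and not bool(arrays["mri_missing"][0, i]))
        assessments = {}
        for assessor, calls in arrays["site_calls"].items():
            if assessor is Assessor.WB_DWI_MRI and not mri_available:
                continue
            criteria = tuple(int(v) for v in calls[0, i])
            assessments[assessor] = SiteAssessment(assessor, criteria)
        records.append(PatientRecord(
            patient_id=f"S{i + 1:05d}",
            assessments=assessments,
            mri_available=mri_available,
            outcome=outcome,
        ))
    return Cohort(tuple(records),
                  provenance=(f"simulated cohort (n={config.n_patients}, seed={config.seed})",))


# ---------------------------------------------------------------------------
# Calibration experiments for the paired non-inferiority tests

def shifted_config(config: SimConfig, reference: Assessor, shifted: Assessor,
                   true_delta: float) -> SimConfig:
    """Recalibrate ``shifted`` so that AUC(reference) - AUC(shifted) equals
    ``true_delta`` at the patient level, moving sensitivity only (the
    false-call rate is copied from the reference assessor)."""
    se_ref = patient_sensitivity(config, reference)
    target_se = se_ref - 2.0 * true_delta
    if not 0 < target_se < 1:
        raise ValueError(f"true_delta {true_delta} pushes sensitivity to {target_se:.3f}")
    f_ref = config.false_call[reference]
    se_site = _solve_site_sensitivity(
        np.asarray(config.site_probs_nonresectable), f_ref, target_se)
    sensitivity = dict(config.sensitivity)
    false_call = dict(config.false_call)
    sensitivity[shifted] = se_site
    false_call[shifted] = f_ref
    return replace(config, sensitivity=sensitivity, false_call=false_call)


def _vector_paired_auc(labels_a, labels_b, truth, mask, margin, alpha):
    """Vectorized replica of the paired AUC non-inferiority decision,
    one decision per replicate row."""
    xa = np.where(mask, labels_a, False).astype(float)
    xb = np.where(mask, labels_b, False).astype(float)
    d = (truth & mask).astype(float)
    nd = (~truth & mask).astype(float)
    n1 = d.sum(axis=1)
    n2 = nd.sum(axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    n1 = np.maximum(n1, 2)
    n2 = np.maximum(n2, 2)
    diff = xa - xb
    sum_u = (diff * d).sum(axis=1)
    sum_u2 = (diff ** 2 * d).sum(axis=1)
    sum_v = (diff * nd).sum(axis=1)
    sum_v2 = (diff ** 2 * nd).sum(axis=1)
    var_u = (sum_u2 - sum_u ** 2 / n1) / (n1 - 1)
    var_v = (sum_v2 - sum_v ** 2 / n2) / (n2 - 1)
    se = np.sqrt(np.maximum(var_u / n1 + var_v / n2, 0.0)) / 2.0
    delta_hat = (sum_u / n1 - sum_v / n2) / 2.0  # (dSe + dSp)/2; dSp = -mean diff on nd
    z_crit = norm.isf(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (delta_hat + margin) / se
    reject = np.where(se > 0, z > z_crit, delta_hat + margin > 0)
    return reject, valid


def _vector_paired_f1(labels_a, labels_b, truth, mask, margin, alpha):
    """Vectorized analytic (delta-method) paired F1 decision per replicate."""
    z_crit = norm.isf(alpha)
    a = labels_a & mask
    b = labels_b & mask
    r = truth & mask
    n = mask.sum(axis=1).astype(float)

    def f1_parts(x):
        tp = (x & r).sum(axis=1).astype(float)
        fp = (x & ~r & mask).sum(axis=1).astype(float)
        fn = (~x & r & mask).sum(axis=1).astype(float)
        return tp, fp, fn

    tpa, fpa, fna = f1_parts(a)
    tpb, fpb, fnb = f1_parts(b)
    da = 2 * tpa + fpa + fna
    db = 2 * tpb + fpb + fnb
    valid = (da > 0) & (db > 0)
    da = np.where(da > 0, da, 1.0)
    db = np.where(db > 0, db, 1.0)
    delta_hat = 2 * tpa / da - 2 * tpb / db

    # Gradient of F1_A - F1_B in the 8 joint-cell probabilities; the cells
    # are indexed (ia, ib, ir).  dF1/d tp = 2(fp+fn)/D^2, dF1/d fp = dF1/d fn
    # = -2 tp / D^2, with D the F1 denominator.
    ga_tp = 2 * (fpa + fna) / da ** 2
    ga_err = -2 * tpa / da ** 2
    gb_tp = 2 * (fpb + fnb) / db ** 2
    gb_err = -2 * tpb / db ** 2
    mean_g = np.zeros_like(delta_hat)
    mean_g2 = np.zeros_like(delta_hat)
    for ia in (0, 1):
        for ib in (0, 1):
            for ir in (0, 1):
                cell = ((a == bool(ia)) & (b == bool(ib)) & (r == bool(ir)) & mask)
                p_cell = cell.sum(axis=1) / n
                grad_a = np.where(ir, ga_tp if ia else ga_err, ga_err if ia else 0.0)
                grad_b = np.where(ir, gb_tp if ib else gb_err, gb_err if ib else 0.0)
                # scale gradients by n: d/d p of counts-based parts
                g = n * (grad_a - grad_b)
                mean_g = mean_g + p_cell * g
                mean_g2 = mean_g2 + p_cell * g ** 2
    var = np.maximum(mean_g2 - mean_g ** 2, 0.0) / n
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (delta_hat + margin) / se
    reject = np.where(se > 0, z > z_crit, delta_hat + margin > 0)
    return reject, valid


def experiment_type1_power(
    config: SimConfig,
    margin: float = 0.05,
    true_delta_grid: Sequence[float] = (-0.05, -0.025, 0.0, 0.025),
    reps: int = 2000,
    seed: int = 0,
    pair: tuple[Assessor, Assessor] = (Assessor.US, Assessor.CT),
    alpha: float = 0.05,
    include_f1: bool = True,
):
    """Rejection-rate table of the paired non-inferiority tests.

    For each ``true_delta`` (the true AUC deficit of modality A relative to
    modality B; -margin is the null boundary), modality B is recalibrated to
    ``AUC_B = AUC_A - true_delta`` and ``reps`` cohorts are simulated; the
    table reports the fraction of replicates concluding non-inferiority,
    with its Monte-Carlo standard error.  F1 rejection rates (analytic
    variance engine) are included by default.  Deterministic given ``seed``.
    """
    import pandas as pd

    if reps < 500:
        raise ValueError("reps < 500 gives an unusable rejection-rate estimate")
    assessor_a, assessor_b = pair
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=len(true_delta_grid))
    rows = []
    for true_delta, child in zip(true_delta_grid, child_seeds):
        cfg = shifted_config(config, assessor_a, assessor_b, true_delta)
        rng = np.random.default_rng(int(child))
        arrays = _simulate_arrays(cfg, rng, reps=reps, assessors=[assessor_a, assessor_b])
        mask = ~arrays["inoperable"]
        if Assessor.WB_DWI_MRI in (assessor_a, assessor_b):
            mask = mask & ~arrays["mri_missing"]
        la, lb = arrays["labels"][assessor_a], arrays["labels"][assessor_b]
        truth = arrays["truth"]
        reject, valid = _vector_paired_auc(la, lb, truth, mask, margin, alpha)
        rate = float(reject[valid].mean())
        row = {
            "true_delta": true_delta,
            "reps": int(valid.sum()),
            "auc_reject_rate": rate,
            "auc_mc_se": math.sqrt(max(rate * (1 - rate), 1e-12) / max(int(valid.sum()), 1)),
        }
        if include_f1:
            f1_reject, f1_valid = _vector_paired_f1(la, lb, truth, mask, margin, alpha)
            ok = valid & f1_valid
            f1_rate = float(f1_reject[ok].mean())
            row["f1_reject_rate"] = f1_rate
            row["f1_mc_se"] = math.sqrt(max(f1_rate * (1 - f1_rate), 1e-12) / max(int(ok.sum()), 1))
        rows.append(row)
    return pd.DataFrame(rows)
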