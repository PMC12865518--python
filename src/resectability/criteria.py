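"""Patient-level classification rule and reference-standard derivation.

The prediction rule is a logical OR over the eight anatomical criteria: a
patient is predicted *non-resectable* if the assessor saw disease at any one
of the eight sites, and *resectable* only if all eight were scored absent.
A patient with every assessed criterion absent but at least one criterion
not assessed cannot be ruled out and is *indeterminate*; such records are
dropped from metric computation with a logged count.

The reference standard is the surgical outcome: R0/R1 (residuum absent or
<= 1 cm) count as resectable, R2 as non-resectable -- unless the R2 was due
to inoperability (frailty), which carries no information about the tumor
and is excluded upstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import (
    Assessor,
    Cohort,
    CRITERION_SITES,
    N_CRITERIA,
    Residual,
    R2Reason,
    SiteAssessment,
    SurgicalOutcome,
)
from .metrics import round_half_up

logger = logging.getLogger(__name__)


class PredictedLabel(str, Enum):
    RESECTABLE = "resectable"
    NON_RESECTABLE = "non_resectable"
    INDETERMINATE = "indeterminate"


class ReferenceLabel(str, Enum):
    RESECTABLE = "resectable"
    NON_RESECTABLE = "non_resectable"
    EXCLUDED_INOPERABLE = "excluded_inoperable"


def classify_prediction(assessment: SiteAssessment) -> PredictedLabel:
    """OR-aggregate the eight ternary criteria into a patient-level label."""
    if assessment.any_present:
        return PredictedLabel.NON_RESECTABLE
    if assessment.all_absent:
        return PredictedLabel.RESECTABLE
    return PredictedLabel.INDETERMINATE


def derive_reference(outcome: SurgicalOutcome) -> ReferenceLabel:
    """Map the surgical outcome to the reference-standard label."""
    if outcome.residual in (Residual.R0, Residual.R1):
        return ReferenceLabel.RESECTABLE
    if outcome.r2_reason is R2Reason.INOPERABLE:
        return ReferenceLabel.EXCLUDED_INOPERABLE
    return ReferenceLabel.NON_RESECTABLE


@dataclass(frozen=True)
class DropLog:
    """Counts of records a label extraction had to leave out."""

    missing_assessment: int = 0
    missing_outcome: int = 0
    indeterminate: int = 0

    @property
    def total(self) -> int:
        return self.missing_assessment + self.missing_outcome + self.indeterminate


def modality_labels(
    cohort: Cohort, assessor: Assessor, drop_indeterminate: bool = True
) -> tuple[list[PredictedLabel], list[ReferenceLabel], DropLog]:
    """Aligned per-patient prediction and reference labels for one assessor.

    Inoperable patients must have been excluded upstream
    (:func:`~resectability.cohort.exclude_inoperable`); encountering one
    here is an error, because silently dropping it would hide a subsetting
    mistake.
    """
    preds, refs = [], []
    n_missing_a = n_missing_o = n_indet = 0
    for r in cohort:
        if not r.has(assessor):
            n_missing_a += 1
            continue
        if r.outcome is None:
            n_missing_o += 1
            continue
        ref = derive_reference(r.outcome)
        if ref is ReferenceLabel.EXCLUDED_INOPERABLE:
            raise ValueError(
                f"patient {r.patient_id} is inoperable; run exclude_inoperable first"
            )
        pred = classify_prediction(r.assessments[assessor])
        if pred is PredictedLabel.INDETERMINATE:
            if not drop_indeterminate:
                raise ValueError(f"indeterminate prediction for patient {r.patient_id}")
            n_indet += 1
            continue
        preds.append(pred)
        refs.append(ref)
    log = DropLog(n_missing_a, n_missing_o, n_indet)
    if log.total:
        logger.info("%s labels: dropped %d record(s) (%s)", assessor.value, log.total, log)
    return preds, refs, log


#: Derived rows appended to every site-frequency table.
ROW_UNION_12 = "(1) and/or (2)"
ROW_ANY = "any of (1)-(8)"


def site_frequency_table(cohort: Cohort, assessor: Assessor) -> pd.DataFrame:
    """Per-criterion involvement counts for one assessor.

    The denominator is the number of records carrying an assessment by this
    assessor; a criterion counts when scored present (1).  Two derived rows
    give the union of criteria 1-2 (small intestine and/or mesentery, the
    dominant pattern of diffuse carcinomatosis) and of all eight criteria
    (the patient-level non-resectability call).  Percentages are half-up
    rounded to one decimal.
    """
    assessed = [r.assessments[assessor] for r in cohort if r.has(assessor)]
    n = len(assessed)
    if n == 0:
        raise ValueError(f"no record carries a {assessor.value} assessment")
    rows = []
    for i in range(N_CRITERIA):
        count = sum(1 for a in assessed if a.criteria[i] == 1)
        rows.append((f"({i + 1}) {CRITERION_SITES[i]}", count))
    union12 = sum(1 for a in assessed if a.criteria[0] == 1 or a.criteria[1] == 1)
    any_count = sum(1 for a in assessed if a.any_present)
    rows.append((ROW_UNION_12, union12))
    rows.append((ROW_ANY, any_count))
    return pd.DataFrame(
        {
            "site": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "n_assessed": n,
            "percent": [round_half_up(100.0 * r[1] / n, 1) for r in rows],
        }
    )
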