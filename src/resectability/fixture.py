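"""Deterministic example cohort reproducing the published marginal counts.

The motivating study deposited no patient-level data, only marginal
tallies: the cohort flow, per-assessor site-involvement counts and the
confusion matrices of each assessor in two nested subcohorts.  This module
constructs, without randomness, a synthetic 279-record cohort whose
marginals reproduce all of those counts exactly:

- 279 recruited -> 242 after the eligibility screen -> 224 after removing
  the 18 inoperable patients -> 167 complete cases with all three imaging
  modalities;
- surgical outcomes R0/R1/R2 split 145/17/80, with the published R2
  reasons;
- every assessor's per-criterion, union-of-1-2 and any-criterion counts;
- every assessor's (TP, FP, FN, TN) in both the 224- and 167-patient
  subcohorts.

Anything *joint* across assessors (which patients two modalities agree on)
is NOT identified by the published margins; this construction assigns
positives deterministically by stratum order and is therefore a synthetic
stand-in wherever joint structure matters.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import study_counts as sc
from .cohort import (
    Approach,
    Assessor,
    Cohort,
    ExclusionReason,
    N_CRITERIA,
    PatientRecord,
    R2Reason,
    Residual,
    SiteAssessment,
    SurgicalOutcome,
)


@dataclass(frozen=True)
class _Stratum:
    """One block of the analysis cohort: reference class x MRI availability."""

    group: str  # "N" non-resectable, "R" resectable, "I" inoperable
    mri: bool
    size: int


# Block order is fixed; "first k patients of each stratum" below refers to it.
_STRATA = (
    _Stratum("N", True, 48),
    _Stratum("N", False, 14),
    _Stratum("R", True, 119),
    _Stratum("R", False, 43),
    _Stratum("I", True, 15),
    _Stratum("I", False, 3),
)

# Patient-level positives per assessor within each stratum, chosen so the
# stratum sums reproduce the published confusion counts and any-criterion
# tallies (MRI entries apply only to MRI-available strata).
_POSITIVES = {
    Assessor.US: (35, 5, 7, 2, 6, 0),
    Assessor.CT: (30, 8, 14, 2, 4, 0),
    Assessor.WB_DWI_MRI: (26, 0, 12, 0, 6, 0),
    Assessor.SURG_EXPL: (47, 12, 9, 1, 9, 0),
}

# Within-stratum outcome layout (applied to patients in order).
_N_SUBOPTIMAL = {0: 17, 1: 6}     # remainder of N strata: not feasible at laparoscopy
_N_R0 = {2: 107, 3: 38}           # remainder of R strata: R1

# Arbitrary spread of the 37 eligibility exclusions over the seven codes
# (the per-code breakdown was not published).
_EXCLUSION_SPREAD = (6, 6, 6, 5, 5, 5, 4)


def _stratum_offsets():
    offsets, total = [], 0
    for s in _STRATA:
        offsets.append(total)
        total += s.size
    return offsets, total


def _criterion_members(assessor: Assessor) -> list[set[int]]:
    """Global patient indices carrying each criterion for one assessor.

    Criteria 1 and 2 are packed into the first ``union12`` positives from
    opposite ends (fixing their union and overlap); every positive beyond
    the union gets one of criteria 3-8; leftover occurrences of criteria
    3-8 are stacked onto the earliest positives.
    """
    offsets, _ = _stratum_offsets()
    pos: list[int] = []
    for (stratum, offset, k) in zip(_STRATA, offsets, _POSITIVES[assessor]):
        pos.extend(range(offset, offset + k))
    counts = sc.SITE_COUNTS[assessor]
    union12 = sc.UNION12_COUNTS[assessor]
    members: list[set[int]] = [set() for _ in range(N_CRITERIA)]
    members[0] = set(pos[: counts[0]])
    members[1] = set(pos[union12 - counts[1]: union12])
    tail = pos[union12:]
    cursor = 0
    for j in range(2, N_CRITERIA):
        take = min(counts[j], len(tail) - cursor)
        members[j] = set(tail[cursor: cursor + take])
        cursor += take
        leftover = counts[j] - take
        for idx in pos:
            if leftover == 0:
                break
            if idx not in members[j]:
                members[j].add(idx)
                leftover -= 1
    assert len(pos) == sc.ANY_COUNTS[assessor]
    return members


def _outcome_for(stratum_idx: int, within: int) -> SurgicalOutcome:
    stratum = _STRATA[stratum_idx]
    if stratum.group == "N":
        if within < _N_SUBOPTIMAL[stratum_idx]:
            return SurgicalOutcome(Residual.R2, R2Reason.SUBOPTIMAL_AFTER_MAX_EFFORT,
                                   Approach.LAPAROTOMY)
        return SurgicalOutcome(Residual.R2, R2Reason.NOT_FEASIBLE_AT_LAPAROSCOPY,
                               Approach.LAPAROSCOPY)
    if stratum.group == "R":
        if within < _N_R0[stratum_idx]:
            if stratum_idx == 2 and within < 5:
                approach = Approach.LAPAROSCOPY
            elif stratum_idx == 2 and within < 30:
                approach = Approach.COMBINED
            else:
                approach = Approach.LAPAROTOMY
            return SurgicalOutcome(Residual.R0, approach=approach)
        return SurgicalOutcome(Residual.R1, approach=Approach.LAPAROTOMY)
    # Inoperable: 11 of the 18 stopped at diagnostic laparoscopy.
    rank = within if stratum_idx == 4 else 15 + within
    approach = Approach.LAPAROSCOPY if rank < 11 else Approach.LAPAROTOMY
    return SurgicalOutcome(Residual.R2, R2Reason.INOPERABLE, approach)


def example_cohort(include_excluded: bool = True) -> Cohort:
    """Build the deterministic 279-record example cohort (or its 242-record
    post-eligibility core with ``include_excluded=False``)."""
    offsets, n_analysis = _stratum_offsets()
    assert n_analysis == sc.N_ANALYSIS
    members = {a: _criterion_members(a) for a in Assessor}

    records = []
    for stratum_idx, (stratum, offset) in enumerate(zip(_STRATA, offsets)):
        for within in range(stratum.size):
            idx = offset + within
            assessments = {}
            for assessor in Assessor:
                if assessor is Assessor.WB_DWI_MRI and not stratum.mri:
                    continue
                criteria = tuple(
                    1 if idx in members[assessor][j] else 0 for j in range(N_CRITERIA)
                )
                assessments[assessor] = SiteAssessment(assessor, criteria)
            records.append(PatientRecord(
                patient_id=f"P{idx + 1:04d}",
                assessments=assessments,
                mri_available=stratum.mri,
                outcome=_outcome_for(stratum_idx, within),
            ))

    if include_excluded:
        reasons = list(ExclusionReason)
        rank = 0
        for reason, k in zip(reasons, _EXCLUSION_SPREAD):
            for _ in range(k):
                records.append(PatientRecord(
                    patient_id=f"P{n_analysis + rank + 1:04d}",
                    exclusion_flags=frozenset({reason}),
                ))
                rank += 1

    label = "example cohort (published-margin reconstruction)"
    return Cohort(tuple(records), provenance=(f"{label}: {len(records)} records",))


def write_example_cohort(path, include_excluded: bool = True) -> None:
    from .cohort import write_cohort

    write_cohort(example_cohort(include_excluded), path)
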