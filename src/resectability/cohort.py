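"""Patient-level data model, CSV interchange and cohort subsetting rules.

A cohort is one row per patient.  Each patient may carry up to four
site-assessment records -- ultrasound, CT, whole-body DWI/MRI and surgical
exploration -- each scoring the eight anatomical non-resectability criteria
as present (1), absent (0) or not assessed (NA).  The surgical outcome
(residual-disease class R0/R1/R2 plus, for R2, the reason) provides the
reference standard downstream.

The canonical interchange format is a wide CSV with assessor-prefixed
criterion columns; see :data:`CSV_COLUMNS`.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

N_CRITERIA = 8

#: Fixed order of the eight anatomical criteria; presence of any one of them
#: marks the tumor as non-resectable.
CRITERION_SITES = (
    "small intestine",
    "small-bowel mesentery",
    "stomach/duodenum",
    "pancreas",
    "liver",
    "hepatic hilum and celiac trunk",
    "abdominal lymph nodes",
    "extra-abdominal (non-resectable)",
)


class Assessor(str, Enum):
    """Who scored the eight criteria for a patient."""

    US = "US"
    CT = "CT"
    WB_DWI_MRI = "WB_DWI_MRI"
    SURG_EXPL = "SURG_EXPL"


IMAGING_ASSESSORS = (Assessor.US, Assessor.CT, Assessor.WB_DWI_MRI)

#: CSV column prefix per assessor.
ASSESSOR_PREFIX = {
    Assessor.US: "us",
    Assessor.CT: "ct",
    Assessor.WB_DWI_MRI: "mri",
    Assessor.SURG_EXPL: "surg",
}
_PREFIX_TO_ASSESSOR = {v: k for k, v in ASSESSOR_PREFIX.items()}


class Residual(str, Enum):
    """Residual disease at the end of surgery."""

    R0 = "R0"  # no macroscopic residual tumor
    R1 = "R1"  # residual tumor <= 1 cm ("optimal")
    R2 = "R2"  # residual tumor > 1 cm, or cytoreduction not attempted


class R2Reason(str, Enum):
    SUBOPTIMAL_AFTER_MAX_EFFORT = "suboptimal_after_max_effort"
    NOT_FEASIBLE_AT_LAPAROSCOPY = "not_feasible_at_laparoscopy"
    INOPERABLE = "inoperable"  # frailty: patient cannot tolerate the surgery


class Approach(str, Enum):
    LAPAROSCOPY = "laparoscopy"
    LAPAROTOMY = "laparotomy"
    COMBINED = "combined"


class ExclusionReason(str, Enum):
    """Pre-analysis exclusion codes (study eligibility screen)."""

    INDEX_TESTS_NOT_PERFORMED = "index_tests_not_performed"
    NO_REFERENCE_STANDARD = "no_reference_standard"
    IMAGING_TO_SURGERY_OVER_4_WEEKS = "imaging_to_surgery_over_4_weeks"
    NON_PRIMARY_OR_BENIGN_HISTOLOGY = "non_primary_or_benign_histology"
    DEATH_BEFORE_INDEX_TESTS = "death_before_index_tests"
    PROTOCOL_DEVIATION = "protocol_deviation"
    MISSING_DATA = "missing_data"


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; ``.report`` lists every problem."""

    def __init__(self, report: list[dict]):
        self.report = report
        preview = "; ".join(p["message"] for p in report[:3])
        more = f" (+{len(report) - 3} more)" if len(report) > 3 else ""
        super().__init__(f"{len(report)} validation problem(s): {preview}{more}")


def report_to_jsonl(report: Sequence[Mapping]) -> str:
    """Serialize a validation report as JSON lines, one object per problem."""
    return "\n".join(json.dumps(p, sort_keys=True) for p in report)


@dataclass(frozen=True)
class SiteAssessment:
    """One assessor's ternary read of the eight criteria for one patient.

    ``criteria[i]`` is 1 (present), 0 (absent) or None (not assessed) for
    criterion ``i + 1``.  Criterion 8 encodes *judged non-resectable*
    extra-abdominal disease only: resectable extra-abdominal findings
    (e.g. isolated cardiophrenic nodes) must be recorded as 0.
    """

    assessor: Assessor
    criteria: tuple[Optional[int], ...]

    def __post_init__(self):
        if len(self.criteria) != N_CRITERIA:
            raise ValueError(f"expected {N_CRITERIA} criterion slots, got {len(self.criteria)}")
        for v in self.criteria:
            if v not in (0, 1, None):
                raise ValueError(f"criterion values must be 0, 1 or None; got {v!r}")

    @property
    def any_present(self) -> bool:
        return any(v == 1 for v in self.criteria)

    @property
    def all_absent(self) -> bool:
        return all(v == 0 for v in self.criteria)


@dataclass(frozen=True)
class SurgicalOutcome:
    """Residual-disease class described by the surgeon, with R2 reason."""

    residual: Residual
    r2_reason: Optional[R2Reason] = None
    approach: Optional[Approach] = None

    def __post_init__(self):
        if self.residual is Residual.R2 and self.r2_reason is None:
            raise ValueError("R2 outcome requires a reason")
        if self.residual is not Residual.R2 and self.r2_reason is not None:
            raise ValueError("r2_reason only allowed for R2 outcomes")

    @property
    def inoperable(self) -> bool:
        return self.r2_reason is R2Reason.INOPERABLE


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    assessments: Mapping[Assessor, SiteAssessment] = field(default_factory=dict)
    mri_available: bool = False
    outcome: Optional[SurgicalOutcome] = None
    exclusion_flags: frozenset = frozenset()

    def __post_init__(self):
        for assessor, a in self.assessments.items():
            if a.assessor is not assessor:
                raise ValueError(
                    f"assessment keyed {assessor} carries assessor {a.assessor}"
                )

    def has(self, assessor: Assessor) -> bool:
        return assessor in self.assessments

    @property
    def excluded(self) -> bool:
        return bool(self.exclusion_flags)


@dataclass(frozen=True)
class Cohort:
    """Ordered, uniquely identified patient records with subsetting history."""

    records: tuple[PatientRecord, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(
                [{"row": None, "column": "patient_id",
                  "message": f"duplicate patient_id {d!r}"} for d in dup]
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    def derive(self, records: Iterable[PatientRecord], note: str) -> "Cohort":
        return Cohort(tuple(records), self.provenance + (note,))


# ---------------------------------------------------------------------------
# CSV interchange

_META_COLUMNS = [
    "patient_id", "mri_available", "outcome_residual", "outcome_r2_reason",
    "approach", "excl_flags",
]
CSV_COLUMNS = _META_COLUMNS + [
    f"{p}_c{i}" for p in ("us", "ct", "mri", "surg") for i in range(1, N_CRITERIA + 1)
]

_TERNARY = {"0": 0, "1": 1, "NA": None}


def _parse_assessment(row, prefix: str, assessor: Assessor, rownum: int, report: list):
    cells = [str(row[f"{prefix}_c{i}"]) for i in range(1, N_CRITERIA + 1)]
    if all(c == "" for c in cells):
        return None
    values = []
    for i, c in enumerate(cells, start=1):
        if c == "":
            report.append({"row": rownum, "column": f"{prefix}_c{i}",
                           "message": "empty cell inside a recorded assessment"})
            return None
        if c not in _TERNARY:
            report.append({"row": rownum, "column": f"{prefix}_c{i}",
                           "message": f"invalid criterion token {c!r} (expected 0, 1 or NA)"})
            return None
        values.append(_TERNARY[c])
    return SiteAssessment(assessor, tuple(values))


def _parse_enum(enum_cls, token: str, column: str, rownum: int, report: list):
    if token == "":
        return None
    try:
        return enum_cls(token)
    except ValueError:
        report.append({"row": rownum, "column": column,
                       "message": f"unknown token {token!r} for {enum_cls.__name__}"})
        raise


def read_cohort(path, schema_version: str = "1.0", strict: bool = True) -> Cohort:
    """Read a wide-format cohort CSV.

    Parameters
    ----------
    path : str or Path
        UTF-8, comma-delimited file with the mandatory header ``CSV_COLUMNS``.
        Extra columns (e.g. a center identifier) are passed through silently.
    schema_version : str
        Interchange schema version; only ``"1.0"`` is defined.
    strict : bool
        If True (default) raise :class:`CohortValidationError` on any
        malformed row; if False, drop malformed rows with a logged count.

    Raises
    ------
    SchemaError
        If a mandatory column is missing or the schema version is unknown.
    CohortValidationError
        In strict mode, if any row is malformed or a patient_id is duplicated.
    """
    if schema_version != "1.0":
        raise SchemaError(f"unknown schema version {schema_version!r}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report: list[dict] = []
    seen_ids: set[str] = set()
    records: list[PatientRecord] = []
    for rownum, row in enumerate(frame.to_dict("records"), start=2):  # 1 = header
        row_report: list[dict] = []
        pid = str(row["patient_id"])
        if pid == "":
            row_report.append({"row": rownum, "column": "patient_id",
                               "message": "empty patient_id"})
        elif pid in seen_ids:
            row_report.append({"row": rownum, "column": "patient_id",
                               "message": f"duplicate patient_id {pid!r}"})
        assessments: dict[Assessor, SiteAssessment] = {}
        for prefix, assessor in _PREFIX_TO_ASSESSOR.items():
            a = _parse_assessment(row, prefix, assessor, rownum, row_report)
            if a is not None:
                assessments[assessor] = a
        mri_token = str(row["mri_available"])
        if mri_token not in ("0", "1"):
            row_report.append({"row": rownum, "column": "mri_available",
                               "message": f"invalid flag {mri_token!r} (expected 0 or 1)"})
            mri_available = False
        else:
            mri_available = mri_token == "1"
        if not mri_available and Assessor.WB_DWI_MRI in assessments:
            row_report.append({"row": rownum, "column": "mri_available",
                               "message": "WB-DWI/MRI assessment recorded but mri_available=0"})
        outcome = None
        try:
            residual = _parse_enum(Residual, str(row["outcome_residual"]),
                                   "outcome_residual", rownum, row_report)
            reason = _parse_enum(R2Reason, str(row["outcome_r2_reason"]),
                                 "outcome_r2_reason", rownum, row_report)
            approach = _parse_enum(Approach, str(row["approach"]),
                                   "approach", rownum, row_report)
            if residual is not None:
                outcome = SurgicalOutcome(residual, reason, approach)
        except ValueError as exc:
            if not row_report or "unknown token" not in row_report[-1]["message"]:
                row_report.append({"row": rownum, "column": "outcome_residual",
                                   "message": str(exc)})
        flags = set()
        for token in str(row["excl_flags"]).split(";"):
            token = token.strip()
            if not token:
                continue
            try:
                flags.add(_parse_enum(ExclusionReason, token, "excl_flags",
                                      rownum, row_report))
            except ValueError:
                pass
        report.extend(row_report)
        if row_report:
            continue
        seen_ids.add(pid)
        records.append(PatientRecord(
            patient_id=pid, assessments=assessments, mri_available=mri_available,
            outcome=outcome, exclusion_flags=frozenset(flags)))

    if report:
        if strict:
            raise CohortValidationError(report)
        logger.warning("dropped %d malformed row(s) while reading %s", len(report), path)
    return Cohort(tuple(records), provenance=(f"read {path.name} ({len(records)} records)",))


def _format_assessment(a: Optional[SiteAssessment]) -> list[str]:
    if a is None:
        return [""] * N_CRITERIA
    return ["NA" if v is None else str(v) for v in a.criteria]


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Render a cohort as the canonical wide-format DataFrame."""
    rows = []
    for r in cohort:
        row = {
            "patient_id": r.patient_id,
            "mri_available": "1" if r.mri_available else "0",
            "outcome_residual": r.outcome.residual.value if r.outcome else "",
            "outcome_r2_reason": (r.outcome.r2_reason.value
                                  if r.outcome and r.outcome.r2_reason else ""),
            "approach": (r.outcome.approach.value
                         if r.outcome and r.outcome.approach else ""),
            "excl_flags": ";".join(sorted(f.value for f in r.exclusion_flags)),
        }
        for assessor, prefix in ASSESSOR_PREFIX.items():
            cells = _format_assessment(r.assessments.get(assessor))
            for i, c in enumerate(cells, start=1):
                row[f"{prefix}_c{i}"] = c
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS, dtype=str)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical CSV; ``read_cohort`` round-trips it exactly."""
    cohort_frame(cohort).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Subsetting rules

def apply_eligibility(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Drop records carrying any exclusion flag.

    Returns the retained cohort and a per-reason exclusion tally (a record
    flagged for several reasons counts once per reason).
    """
    tally: dict[str, int] = {}
    kept = []
    for r in cohort:
        if r.excluded:
            for f in sorted(r.exclusion_flags, key=lambda f: f.value):
                tally[f.value] = tally.get(f.value, 0) + 1
        else:
            kept.append(r)
    n_removed = len(cohort) - len(kept)
    return (cohort.derive(kept, f"eligibility screen: removed {n_removed}, kept {len(kept)}"),
            tally)


def exclude_inoperable(cohort: Cohort) -> Cohort:
    """Drop patients whose R2 outcome was due to inoperability (frailty).

    These patients carry no information about tumor resectability and are
    excluded from all discrimination analyses.
    """
    kept = [r for r in cohort if not (r.outcome and r.outcome.inoperable)]
    n_removed = len(cohort) - len(kept)
    return cohort.derive(kept, f"excluded {n_removed} inoperable, kept {len(kept)}")


def complete_case_subset(cohort: Cohort, required_assessors: Iterable[Assessor]) -> Cohort:
    """Keep records that carry an assessment for every required assessor."""
    required = tuple(required_assessors)
    kept = [r for r in cohort if all(r.has(a) for a in required)]
    names = "+".join(a.value for a in required)
    return cohort.derive(kept, f"complete cases for {names}: kept {len(kept)}")
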