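"""Percent agreement between an imaging modality and surgical exploration.

Agreement is computed per anatomical site (or on the patient-level OR of
all eight), from a 2x2 cross-tabulation with surgical exploration as the
reference assessor.  Two conventions for positive/negative agreement are
offered:

- ``reference_conditioned``: PPA = a/(a+b), NPA = d/(c+d) -- the fraction of
  reference-positive (resp. -negative) sites the imaging read agrees on;
- ``specific_agreement``: PPA = 2a/(2a+b+c), NPA = 2d/(2d+b+c) -- symmetric
  in the two assessors (PPA then equals the F1 of imaging against the
  reference).

Overall percent agreement OPA = (a+d)/n is identical under both.

:func:`reconstruct_joint_from_margins` inverts the arithmetic: given the
two positive margins, n and the OPA, it recovers the unique integer 2x2
table when one exists.  This is useful for validating published agreement
figures when the joint counts themselves are not reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .cohort import Assessor, Cohort
from .criteria import PredictedLabel, classify_prediction

logger = logging.getLogger(__name__)

CONVENTIONS = ("reference_conditioned", "specific_agreement")


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement counts: a = both positive, b = reference-only positive,
    c = imaging-only positive, d = both negative."""

    a: int
    b: int
    c: int
    d: int
    reference: Assessor = Assessor.SURG_EXPL

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def ref_pos(self) -> int:
        return self.a + self.b

    @property
    def img_pos(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class AgreementMetrics:
    opa: Optional[float]
    ppa: Optional[float]
    npa: Optional[float]
    convention: str


def crosstab_site(
    cohort: Cohort,
    imaging: Assessor,
    criterion: Union[int, str] = "any",
    reference: Assessor = Assessor.SURG_EXPL,
) -> AgreementTable:
    """Cross-tabulate one imaging modality against the reference assessor.

    ``criterion`` is a site index 1-8 or ``"any"`` for the patient-level OR
    of all eight.  Records lacking either assessment, or with a
    not-assessed value at the requested criterion for either assessor, are
    dropped with a logged count.
    """
    a = b = c = d = 0
    dropped = 0
    for r in cohort:
        if not (r.has(imaging) and r.has(reference)):
            dropped += 1
            continue
        if criterion == "any":
            img_label = classify_prediction(r.assessments[imaging])
            ref_label = classify_prediction(r.assessments[reference])
            if PredictedLabel.INDETERMINATE in (img_label, ref_label):
                dropped += 1
                continue
            img = img_label is PredictedLabel.NON_RESECTABLE
            ref = ref_label is PredictedLabel.NON_RESECTABLE
        else:
            if not 1 <= int(criterion) <= 8:
                raise ValueError("criterion must be 1-8 or 'any'")
            iv = r.assessments[imaging].criteria[int(criterion) - 1]
            rv = r.assessments[reference].criteria[int(criterion) - 1]
            if iv is None or rv is None:
                dropped += 1
                continue
            img, ref = bool(iv), bool(rv)
        if img and ref:
            a += 1
        elif ref:
            b += 1
        elif img:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise ValueError(
            f"no overlapping {imaging.value}/{reference.value} records for criterion {criterion!r}"
        )
    if dropped:
        logger.info("agreement crosstab %s criterion %s: dropped %d record(s)",
                    imaging.value, criterion, dropped)
    return AgreementTable(a=a, b=b, c=c, d=d, reference=reference)


def agreement_metrics(
    table: AgreementTable, convention: str = "reference_conditioned"
) -> AgreementMetrics:
    """Overall/positive/negative percent agreement under the chosen convention."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty agreement table")
    opa = (a + d) / n
    if convention == "reference_conditioned":
        ppa = a / (a + b) if a + b else None
        npa = d / (c + d) if c + d else None
    else:
        ppa = 2 * a / (2 * a + b + c) if 2 * a + b + c else None
        npa = 2 * d / (2 * d + b + c) if 2 * d + b + c else None
    return AgreementMetrics(opa=opa, ppa=ppa, npa=npa, convention=convention)


def reconstruct_joint_from_margins(
    n: int, ref_pos: int, img_pos: int, opa: float
) -> AgreementTable:
    """Recover the unique integer 2x2 table from margins, n and OPA.

    With k = round(opa * n) agreeing patients there are n - k disagreements,
    split as b + c; since ref_pos + img_pos = 2a + b + c, the both-positive
    cell is ``a = (ref_pos + img_pos - (n - k)) / 2``.  Raises when no
    consistent non-negative integer table exists.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    agree = int(round_half_up_int(opa * n))
    disagree = n - agree
    twice_a = ref_pos + img_pos - disagree
    if twice_a < 0 or twice_a % 2:
        raise ValueError(
            f"margins ({ref_pos}, {img_pos}) and OPA {opa} admit no integer table at n={n}"
        )
    a = twice_a // 2
    b = ref_pos - a
    c = img_pos - a
    d = n - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"margins ({ref_pos}, {img_pos}) and OPA {opa} admit no integer table at n={n}"
        )
    return AgreementTable(a=a, b=b, c=c, d=d)


def round_half_up_int(x: float) -> int:
    from .metrics import round_half_up

    return int(round_half_up(x, 0))


def agreement_long_table(
    cohort: Cohort,
    imaging_assessors=(Assessor.US, Assessor.CT, Assessor.WB_DWI_MRI),
    convention: str = "reference_conditioned",
) -> pd.DataFrame:
    """Long-format agreement output: one row per (modality, site)."""
    rows = []
    for imaging in imaging_assessors:
        for criterion in list(range(1, 9)) + ["any"]:
            table = crosstab_site(cohort, imaging, criterion)
            m = agreement_metrics(table, convention)
            rows.append({
                "modality": imaging.value,
                "site": str(criterion),
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "OPA": m.opa, "PPA": m.ppa, "NPA": m.npa,
                "convention": convention,
            })
    return pd.DataFrame(rows)
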