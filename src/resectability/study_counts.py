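"""Published marginal counts of the motivating multicenter accuracy study.

These constants drive two things: the deterministic example cohort in
:mod:`resectability.fixture` (constructed so that its marginal tallies
reproduce the published flow, site-frequency and confusion-matrix counts)
and the default calibration of the synthetic-cohort generator.  They are
summary counts only -- the patient-level joint distribution behind them is
not public, so anything joint in the fixture is a constructed stand-in.
"""
from __future__ import annotations

from .cohort import Assessor

# Cohort flow ---------------------------------------------------------------
N_RECRUITED = 279          # enrolled
N_EXCLUDED = 37            # failed the eligibility screen
N_ANALYSIS = 242           # final analysis set
N_INOPERABLE = 18          # R2 because the patient could not tolerate surgery
N_OPERABLE = 224           # discrimination-analysis cohort
N_MRI_AVAILABLE = 182      # patients with WB-DWI/MRI (of the 242)
N_COMPLETE_CASE = 167      # operable patients with all three imaging tests

# Surgical outcome among the 242 --------------------------------------------
OUTCOME_COUNTS = {"R0": 145, "R1": 17, "R2": 80}
R2_REASON_COUNTS = {
    "suboptimal_after_max_effort": 23,
    "not_feasible_at_laparoscopy": 39,
    "inoperable": 18,
}

# Site-involvement counts per assessor (criteria 1-8, fixed order) ----------
SITE_COUNTS = {
    Assessor.US: (32, 33, 3, 2, 3, 6, 9, 7),
    Assessor.CT: (30, 17, 10, 6, 3, 12, 16, 16),
    Assessor.WB_DWI_MRI: (15, 13, 5, 1, 3, 8, 16, 16),
    Assessor.SURG_EXPL: (57, 44, 7, 4, 4, 13, 11, 11),
}
UNION12_COUNTS = {
    Assessor.US: 44, Assessor.CT: 35, Assessor.WB_DWI_MRI: 21, Assessor.SURG_EXPL: 68,
}
ANY_COUNTS = {
    Assessor.US: 55, Assessor.CT: 58, Assessor.WB_DWI_MRI: 44, Assessor.SURG_EXPL: 78,
}
ASSESSED_N = {
    Assessor.US: 242, Assessor.CT: 242,
    Assessor.WB_DWI_MRI: 182, Assessor.SURG_EXPL: 242,
}

# Confusion counts (tp, fp, fn, tn), positive = non-resectable --------------
# 224 operable patients (62 reference non-resectable):
CONFUSION_OPERABLE = {
    Assessor.US: (40, 9, 22, 153),
    Assessor.CT: (38, 16, 24, 146),
    Assessor.SURG_EXPL: (59, 10, 3, 152),
}
# 167 complete-case patients (48 reference non-resectable):
CONFUSION_COMPLETE = {
    Assessor.US: (35, 7, 13, 112),
    Assessor.CT: (30, 14, 18, 105),
    Assessor.WB_DWI_MRI: (26, 12, 22, 107),
    Assessor.SURG_EXPL: (47, 9, 1, 110),
}

# Patient-level operating points implied by the complete-case counts --------
OPERATING_POINTS = {
    assessor: (tp / (tp + fn), tn / (tn + fp))
    for assessor, (tp, fp, fn, tn) in CONFUSION_COMPLETE.items()
}

# Overall percent agreement of imaging vs surgical exploration on the
# patient-level "any criterion" call (fraction scale), with the margins.
AGREEMENT_ANY = {
    Assessor.US: {"n": 242, "ref_pos": 78, "img_pos": 55, "opa": 0.839},
    Assessor.CT: {"n": 242, "ref_pos": 78, "img_pos": 58, "opa": 0.777},
    Assessor.WB_DWI_MRI: {"n": 182, "ref_pos": None, "img_pos": 44, "opa": 0.758},
}

# Sample-size planning anchors ----------------------------------------------
PLANNING_AUC = 0.78
PLANNING_N_US_MRI = 166
PLANNING_N_US_CT = 99
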