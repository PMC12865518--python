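# resectability

Analysis toolkit for paired diagnostic-accuracy studies of **preoperative
resectability assessment in tubo-ovarian (ovarian) carcinoma**.

In advanced ovarian cancer the decision to attempt cytoreductive surgery
hinges on whether the tumor is resectable. A widely used clinical rule
scores eight anatomical sites (small intestine, small-bowel mesentery root,
stomach/duodenum, pancreas, liver, hepatic hilum/celiac trunk, abdominal
lymph nodes, extra-abdominal disease); involvement of **any one** site
predicts non-resectable disease. Several assessors — abdominopelvic
ultrasound, CT, whole-body DWI/MRI and intraoperative surgical exploration —
can each score the same eight criteria in the same patient, and each is
judged against the surgical outcome (residual disease at the end of
surgery: R0/R1 = resectable, R2 = non-resectable, with inoperable-for-frailty
patients excluded).

The package implements the full analysis for such a study:

- **Cohort model** — per-patient ternary site assessments for up to four
  assessors, surgical outcomes, eligibility flags; a canonical wide CSV
  interchange format with strict validation; the study subsetting rules
  (eligibility screen → inoperable exclusion → complete-case subcohort).
- **Classification rule** — OR over the eight criteria; `NA` on a criterion
  with all others absent makes the patient-level call indeterminate.
- **Accuracy metrics** — for a single-operating-point binary test the ROC
  has one interior point and AUC = (Se + Sp)/2 (balanced accuracy). The
  `DiagnosticAccuracy` model computes Se, Sp, PPV, NPV, accuracy,
  F<sub>β</sub> = (1+β²)·PPV·Se / (β²·PPV + Se) for β = 1 and 0.5, and AUC,
  with Wilson score intervals for proportions and a structural-component
  (DeLong-type, binary-score) normal interval for AUC.
- **Agreement** — overall/positive/negative percent agreement of each
  imaging modality against surgical exploration, per site or on the
  patient-level call, plus an exact integer reconstruction of the 2×2 table
  from published margins and OPA.
- **Paired non-inferiority** — one-sided shifted Z tests
  H₀: θ_A − θ_B ≤ −Δ (default margin Δ = 0.05) for AUC (paired
  binary-score DeLong variance) and F1 (multinomial delta method or paired
  patient-level bootstrap).
- **Sample size** — the Obuchowski–McClish binormal design for
  non-inferiority comparison of two correlated AUCs, with its inverse
  (power at n).
- **Synthetic cohorts** — a latent-Gaussian site-level generator calibrated
  to published margins, used for operating-characteristic experiments
  (type-I error at the null boundary, power curves, parameter recovery).

## Worked example

The package ships a deterministic 279-record example cohort whose marginal
tallies reproduce the published counts of the motivating multicenter study
(the patient-level joint structure is synthetic — see
`docs/methods.md`). The full pipeline:

```python
import resectability as rs
from resectability.cohort import Assessor

cohort, exclusions = rs.apply_eligibility(rs.example_cohort())   # 279 -> 242
operable = rs.exclude_inoperable(cohort)                         # 242 -> 224
complete = rs.complete_case_subset(
    operable, [Assessor.US, Assessor.CT, Assessor.WB_DWI_MRI])   # 224 -> 167

res = rs.DiagnosticAccuracy.from_cohort(complete, Assessor.US).fit()
print(res.summary())
```

prints the ultrasound row of the complete-case accuracy table:

```
| US | 0.835 (0.769-0.901) [a] | 112 (67.1) | 13 (7.8) | 7 (4.2) | 35 (21.0)
| 72.9 (59.0-83.4) | 94.1 (88.4-97.1) | 83.3 (69.4-91.7) | 89.6 (83.0-93.8)
| 88.0 (82.2-92.1) | 77.8 | 81.0 |
```

i.e. among 167 patients (48 non-resectable by the surgical reference),
ultrasound detected 35 of 48 non-resectable tumors (sensitivity 72.9%,
Wilson 95% CI 59.0–83.4) with 7 false alarms among 119 resectable ones
(specificity 94.1%), giving a single-operating-point AUC of 0.835 and an F1
of 77.8%. The paired non-inferiority comparison:

```python
res = rs.PairedNoninferiority.from_cohort(
    complete, Assessor.US, Assessor.CT, statistic="auc").fit()
print(res.summary())
# AUC: A=0.835 B=0.754 diff=+0.081 margin=0.05 Z=5.308 p=5.536e-08 -> noninferior
```

so on this cohort ultrasound's AUC is 0.081 above CT's and non-inferiority
at the 5-point margin is concluded (the p-value depends on the
between-modality joint structure, which in the example cohort is a
synthetic stand-in).

The same pipeline is available from the shell:

```bash
resectability simulate --n 242 --seed 1 --out cohort.csv
resectability analyze --input cohort.csv --outdir report/
resectability samplesize --rho 0.5
```

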