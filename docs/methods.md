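# Methods

## The estimation problem

Each patient in a cohort with suspected or proven tubo-ovarian carcinoma is
scored by up to four assessors (ultrasound, CT, whole-body DWI/MRI,
surgical exploration at the start of surgery) on eight anatomical criteria
whose involvement marks the tumor as non-resectable. The patient-level
prediction is the OR of the eight criteria. The reference standard is the
surgical outcome described at the end of surgery: R0 (no macroscopic
residuum) and R1 (residuum ≤ 1 cm) count as resectable; R2 (residuum >
1 cm, or cytoreduction not attempted) counts as non-resectable — unless the
R2 was recorded because the patient could not tolerate the necessary
surgery (inoperable), which says nothing about the tumor and excludes the
patient from discrimination analyses. Criterion 8 (extra-abdominal disease)
encodes *judged non-resectable* extra-abdominal findings only; resectable
extra-abdominal disease (isolated cardiophrenic or axillary nodes, focal
pleural involvement) is scored 0, which is how surgical exploration can
call a patient resectable despite extra-abdominal findings while the same
OR rule is used for every assessor.

### Ternary criteria and the NA rule

Criteria are ternary (present / absent / not assessed). A patient with at
least one criterion present is predicted non-resectable regardless of NAs
(the OR is already decided); a patient with every assessed criterion
absent but ≥ 1 NA cannot be ruled out and is *indeterminate*. Indeterminate
records are dropped from metric computation with a logged count. The
binary-read special case (no NAs anywhere) reduces to the published rule
exactly.

## Accuracy metrics

With non-resectable as the positive class: Se = TP/(TP+FN), Sp = TN/(TN+FP),
PPV, NPV, accuracy, and F_β = (1+β²)·PPV·Se/(β²·PPV+Se) with β = 1 and 0.5
(β = 0.5 up-weights precision: in this clinical setting a false
"non-resectable" call deprives an operable patient of surgery, so precision
matters more than recall). Each assessor is a single binary call, so its
empirical ROC has one interior operating point and the (tie-corrected
trapezoidal) area equals balanced accuracy, AUC = (Se+Sp)/2; the test suite
verifies this identity against a generic empirical-ROC routine.

**Intervals.** Binomial proportions get Wilson score intervals (the
default; Clopper–Pearson is available as an option). The Wilson choice is
not arbitrary: it reproduces the printed sensitivity/specificity CIs of the
motivating study to the decimal, which exact intervals do not. The AUC
interval uses the structural-component (DeLong-type) variance specialized
to two-valued scores, SE² = [Se(1−Se)/n₁ + Sp(1−Sp)/n₂]/4, as a normal
interval truncated to [0,1]; a Hanley–McNeil variant is provided. AUC
intervals for a binary read are method-dependent (the published ones are
not recovered exactly by any standard closed form we checked — Wald,
binary-score DeLong, or Hanley–McNeil), so rendered reports flag the AUC
CI column as method-dependent. F-scores are reported without intervals: no
standard closed form exists for a single F-score of correlated counts, and
inference on F1 *differences* (the quantity of scientific interest here) is
covered by the paired tests below.

**Rounding.** Display rounding is decimal half-up — one decimal for
percentages, three for AUC — applied once, in the metric layer; renderers
never re-round.

## Percent agreement

For each site (or the patient-level OR), imaging vs surgical exploration is
cross-tabulated into (a, b, c, d) = (both positive, reference only,
imaging only, both negative). OPA = (a+d)/n. Two PPA/NPA conventions are
implemented: reference-conditioned (PPA = a/(a+b), NPA = d/(c+d); the
default, with surgical exploration as the comparator) and specific
agreement (PPA = 2a/(2a+b+c), which equals the F1 of imaging against the
reference — an identity the tests assert). No chance-corrected statistic
(kappa) is computed; the motivating study reports raw percent agreement.

`reconstruct_joint_from_margins` recovers the unique integer table from
(n, reference positives, imaging positives, OPA): with k = round(OPA·n)
agreements, a = (ref_pos + img_pos − (n − k))/2 when that is a
non-negative integer consistent with the margins. This validates published
agreement figures whose joint counts were not printed.

## Paired non-inferiority tests

Both tests are one-sided shifted Z tests of H₀: θ_A − θ_B ≤ −Δ with margin
Δ = 0.05 and one-sided α = 0.05 by default; Z = (θ̂_A − θ̂_B + Δ)/SE and
non-inferiority is concluded when the one-sided p < α.

**AUC.** The paired variance comes from the structural components of the
DeLong decomposition. For two-valued scores the placement value of a
diseased patient under modality m is 0.5·(x_m + Sp_m), so placement
*differences* are 0.5·(x_A − x_B) plus a within-class constant and the
variance collapses to a closed form over the 2×2×2 cross-classification:
SE² = [S²_d(x_A − x_B)/n₁ + S²_nd(x_A − x_B)/n₂]/4 with S² the within-class
sample variance (ddof 1). The source study cites a named formula for
correlated single-operating-point AUCs without reprinting it; this
implementation is the paired binary-score DeLong structure, validated two
ways instead of against the unavailable formula: (i) exact agreement with a
brute-force placement-component oracle on small hand-built pairings, and
(ii) a Monte-Carlo calibration suite showing the rejection rate at the null
boundary (true difference exactly −Δ) matches the nominal α within
Monte-Carlo error, and is monotone in the true difference.

**F1.** Two variance engines: an analytic delta method over the multinomial
of the eight joint cells (label_A × label_B × reference), and a paired
patient-level bootstrap (default B = 2000; the default engine, as it is
more robust when joint cells are small). The bootstrap is verified against
exhaustive enumeration of all 6⁶ resamples at n = 6, and the two engines
agree within 15% relative on moderate samples. Degenerate case: identical
predictions give SE = 0 and non-inferiority is declared by the sign of
δ̂ + Δ, with the p-value reported at the machine floor and a logged note.

The two pre-planned comparisons (ultrasound vs CT, ultrasound vs
WB-DWI/MRI) are reported without multiplicity adjustment, matching the
study design. The study's printed P values cannot be reproduced: they
depend on the patient-level pairing, which was not deposited. The
calibration suite plus the small-pairing oracles are the substitute
evidence that the machinery is correct.

## Sample size (correlated AUCs, non-inferiority)

n₁ = (z_{1−α} + z_{1−power})²·2·V(A)·(1−ρ)/Δ² diseased patients, scaled to
total patients by the allocation ratio R (non-diseased per diseased).
V(A) is the Obuchowski–McClish binormal variance
0.0099·e^{−a²/2}·(5a² + 8 + (a² + 8)/R), a = √2·Φ⁻¹(A). Defaults: planning
AUC 0.78 for both tests, Δ = 0.05, one-sided α = 0.05, power 0.90, ρ = 0.5,
R = 119/48 (the study prevalence). ρ and the allocation were not published;
over the documented plausible grid (ρ ∈ [0.3, 0.95]; R ∈ {1, 119/48}) the
required total n spans 87–1608, which brackets the published planning
figures of 166 and 99 — those are reproduced only near the high end of the
correlation range, so they are treated as plausibility anchors, not exact
targets. A binary operating-point variance V = [Se(1−Se) + Sp(1−Sp)/R]/4 is
available for cross-checking the analytic power against Monte-Carlo power
of the paired test in this package (they agree within 5 points at the
study configuration).

## Synthetic cohort generator

Per patient: true non-resectability ~ Bernoulli(prevalence); given
non-resectable, each site involved independently with its conditional
probability, re-drawn until ≥ 1 site is involved (non-resectability *is*
the presence of a prohibitive site); resectable patients use the
(default-zero) resectable-site probabilities. Each assessor reads each
site through a latent-Gaussian threshold with a patient-site latent shared
across assessors: detection occurs when Φ(√ρ·w + √(1−ρ)·ε) falls below the
assessor's per-site detection probability (sensitivity if involved,
false-call rate otherwise). A single ρ ∈ [0,1) spans conditional
independence to near-duplicated reads with correct marginals throughout —
the one-parameter family chosen because the study gives no dependence
information. Surgical exploration is simulated with its own (high but
imperfect) operating point rather than as truth, mirroring its published
error rates. Outcomes follow truth (non-resectable → R2 split between
suboptimal and not-feasible-at-laparoscopy 23:39; resectable → R0:R1 =
145:17); an independent inoperable flag (18/242) overrides to R2/inoperable;
WB-DWI/MRI is dropped at rate 60/242.

**Calibration.** `calibrate_from_margins` inverts published margins by
moment matching of the OR-aggregated detection probability. The
false-call rate is uniform across sites, f = 1 − Sp^{1/8}, which matches
patient-level specificity exactly. The truth prevalence is solved from the
surgical any-criterion margin and the surgical operating point; the truth
site probabilities from the surgical per-site margins (a fixed point with
the ≥ 1-site conditioning); each assessor's uniform per-site sensitivity by
root-finding on the closed-form patient-level sensitivity. Patient-level
operating points are matched exactly in expectation; *imaging* per-site
margins are consequently only approximate (per-site imaging sensitivities
were never published), and the large-sample check targets the surgical
any-criterion frequency (within one percentage point of 32.2%).

**What the generator does not emulate:** center effects, FIGO stage and
histology structure, ascites (which modifies imaging sensitivity in the
source data), correlations between frailty and tumor burden, and any
non-exchangeable per-site error structure. Passing tests therefore show the
*machinery* is correct under the stated model, not that the model captures
every feature of real multicenter data.

## Experiment sizes and numerical choices

The calibration experiment uses 2000 replicates of n = 167 at the study
prevalence and operating points (grid of true AUC differences
−0.075…0.025); parameter recovery uses 200 replicates; the large-sample
margin check uses one 10⁵-patient cohort. These sizes put Monte-Carlo error
well inside the tolerances being asserted while keeping the default suite
fast. Root-finding uses Brent's method with probabilities clipped to
[10⁻⁴, 0.995]; the p/sensitivity fixed point runs to a 10⁻¹⁰ tolerance.
All randomness flows through explicitly seeded `numpy` generators; no
global state is touched. Ties and degenerate inputs: zero-denominator
metrics are None (never NaN) with a logged warning; zero paired SE resolves
by the sign convention above; empty reference classes raise.

## Known limitations

- The example cohort reproduces published *marginal* counts exactly, but
  its joint structure across assessors is a deterministic synthetic
  stand-in; quantities that depend on the joint (paired Z statistics,
  fixture-level OPA) are pipeline outputs, not reconstructions of published
  values.
- AUC confidence intervals for binary reads are method-dependent; the
  published intervals' method is unknown and none of the standard closed
  forms reproduces them exactly.
- The paired-AUC test is mildly liberal at the null boundary in small
  samples (rejection ≈ 0.054 at n = 167 against nominal 0.05, estimated at
  5×10⁴ replicates), the familiar behavior of a Z test with estimated
  variance on discrete data.
- Exact reproduction of the published sample-size figures is out of reach
  because the correlation and allocation behind them were not published.
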