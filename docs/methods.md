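# Methods

`dermtriage` re-implements, as a tested pipeline, the statistical
evaluation of an AI skin-lesion classifier ("the device") used for triage
on an urgent teledermatology skin-cancer pathway, against the remote
consultant dermatologist review that constitutes standard of care (SoC).
This note records the models and procedures implemented, the parameter
choices, what the synthetic-data generator does and does not emulate, and
the numerical decisions made where the design was genuinely open.

## Data model and populations

The unit of analysis is the lesion.  Each lesion row carries an
adjudicated final diagnosis among seven classes — melanoma (MM), squamous
cell carcinoma (SCC), basal cell carcinoma (BCC), intraepidermal
carcinoma (IEC), actinic keratosis (AK), atypical nevus (AN), benign
(with optional subtype) — together with the basis of that diagnosis
(histology, clinical, or a delayed second clinical opinion), the
clinician's management decision, and the device's output label under each
of three threshold settings (A: 91% target sensitivity, B: 92.5%, and the
real-world deployment setting RWS).  Patients can re-attend, so lesions
reference both a patient and an attendance identifier; analyses never
deduplicate by patient because the lesion is the unit throughout.

Adjudication follows a strict rule: histology, when available, overrides
any clinical impression, and a *malignant* diagnosis (MM/SCC/BCC) is only
accepted from histology.  A malignant clinical label without histology is
retained as the final class but flagged `unconfirmed_malignant` and falls
into the **non-malignant denominator** of every accuracy statistic.  This
rule is load-bearing: the trial's specificity denominator (722 = 789 − 67)
is only consistent with histology-unconfirmed suspects being counted
non-malignant.

Two nested analysis populations are derived from the recruited table:
intention-to-treat (ITT) drops ineligible lesions and lesions without a
final diagnosis; per-protocol (PP) additionally drops lesions without a
device result (image not captured, image failed the automated quality
check, or any device label absent).  Filtering is monotone (PP ⊆ ITT ⊆
recruited) and the per-reason exclusion counts partition the dropped set.

## Endpoints

The device resolves multiple plausible classes through a risk hierarchy
(MM ≻ SCC ≻ BCC ≻ IEC ≻ AK ≻ AN ≻ benign): the most serious candidate is
returned.  The order among IEC/AK/AN follows their conventional listing;
only the MM-over-BCC case is externally exemplified, and no computed
statistic depends on the relative order within the premalignant group.

Positivity (referral) rules:

* **AI raters** are positive when the label is malignant.  For
  number-needed-to-refer (NNR) the scope widens to labels in
  {MM, SCC, BCC, IEC, AK}.
* **SoC** is positive when the management decision is urgent biopsy,
  non-urgent biopsy, urgent face-to-face review, or BCC/Mohs clinic.
  Mohs referral counts positive — it is an urgent cancer-pathway referral,
  and the clinician sensitivity of 97.0% (65/67) only reconciles with the
  narrative if the melanoma sent to the Mohs clinic counts as detected.
  Referral to another specialty counts negative by default (the trial
  never classifies it); the sets are configurable on `PositivityRule`.
* The **primary-endpoint event** for a non-malignant lesion is being
  correctly kept off the urgent pathway: not referred for biopsy or
  urgent face-to-face review.

## Accuracy statistics

Confusion counts use the malignant vs premalignant/benign grouping (a
true positive is any malignant lesion referred, whatever the suspected
class).  Sensitivity, specificity, PPV, NPV, FNR and FPR are reported
with binomial confidence intervals; the Wilson score interval is the
default (the trial does not name its CI method; Wilson reproduces the
printed intervals to within about 0.1 percentage point in spot checks),
with Clopper–Pearson and Wald available.  Intervals come from statsmodels'
`proportion_confint`.

NNB (number needed to biopsy per malignancy found) and NNR (per IEC/AK
found) are referred/events ratios; NNB equals 1/PPV on the same referral
scope by construction.  Their CIs invert the Wilson interval of
events/referred as [1/p_high, 1/p_low], which matches the printed
interval patterns to one decimal place; zero events yield an explicitly
infinite ratio rather than an error.  Percentages and ratios are
displayed to one decimal place.

Lesions are treated as independent despite within-patient clustering
(about 1.2–1.3 lesions per patient).  The trial's own analysis does the
same; intervals are therefore mildly anti-conservative, which matters for
the CIs but not for the point estimates or the cost arithmetic.

## Two-stage adaptive group-sequential analysis

The primary comparison is the device's vs the clinician's probability of
correctly keeping a non-malignant lesion off the urgent pathway.  Each
phase k contributes a one-sided two-proportion z-test

    z_k = (p̂_dev − p̂_soc + δ_test) / SE_pooled ,

with pooled variance by default.  A 1% non-inferiority margin enters the
sample-size calculation, but the per-phase statistic defaults to δ_test =
0 (pure superiority): the trial is ambiguous about the margin's role in
the statistic, and with the observed phase counts the conclusion is the
same under either choice (δ_test is configurable).

Phases are combined with the inverse-normal (Lehmacher–Wassmer) rule
using the prespecified weights w = (0.577, 0.82):

    Z = (w₁ z₁ + w₂ z₂) / √(w₁² + w₂²),   p = 1 − Φ(Z).

The internal normalisation makes Z standard normal under the null and
the rule invariant to rescaling the weights; the near-unit norm of the
printed weights (≈ √(1/3), √(2/3)) is consistent with the one-third
interim.  The combined p is compared with the adjusted final one-sided
level 0.0246.  That constant is *taken as configured*, not re-derived:
plausible O'Brien–Fleming configurations (spending vs classical
boundaries, planned vs observed information fractions) give final levels
between 0.024 and 0.025, and the precise configuration behind 0.0246 is
unstated.  For users who want a self-consistent design, `obf_spending`
implements the Lan–DeMets O'Brien–Fleming-type spending function
a(t) = 2(1 − Φ(Φ⁻¹(1 − α/2)/√t)) and `boundary_solve` solves two-look
nominal levels against it by bivariate-normal integration (correlation
√(t₁/t₂)) to 1e-6; for fractions (1/3, 1) at α = 0.025 it yields a final
nominal level of 0.02496.  The combination statistic is computed on the z
scale, which is identical to combining p-values but robust when an
extreme phase p-value underflows to 0 or 1 in floating point.

**Sample size.**  The normal-approximation per-group size is
(z_α + z_β)² · V / (Δ + δ)² with V the pooled or unpooled Bernoulli
variance sum, ceiling-rounded.  The trial's published 634 lesions cannot
be reproduced because the assumed SoC correct-negative rate was never
printed; the function is validated against its own closed form.  The
lesion→patient conversion divides by lesions-per-patient (1.2) and
inflates by the dropout allowance (10%), reproducing 634 → 581.

**Interim assessment.**  At the interim look, conditional power under the
observed effect is computed from the deterministic phase-2 threshold
implied by the combination rule: rejection requires
z₂ ≥ (z_crit√(w₁²+w₂²) − w₁z₁)/w₂, and z₂ has approximate mean
(effect)/SE(n₂).  Futility is declared below a configurable floor
(default 0.20, a conventional choice); otherwise the phase-2 size is
re-solved for the reassessment target (default 95% conditional power).
With the published phase-1 counts the procedure continues (conditional
power ≈ 0.23 at the planned size).  The trial's re-estimate of 700
patients is not reproducible — its reassessment rule is unstated — so the
implementation documents its own rule rather than chasing that number.

## Cost-impact model

Under the triage assumption — a premalignant-or-benign device output ends
the urgent pathway — an attendance's teledermatology review is avoided
iff every lesion at that attendance is device-negative; a
clinician-planned face-to-face assessment or biopsy is avoided iff its
lesion is device-negative.  Unit costs default to £115.44 per review
(10 min), £163.41 per face-to-face (15 min) and £257.43 per biopsy
(32.5 min, a 50:50 mix of 45-min excision and 20-min incisional/punch
bookings).  Money is computed in `Decimal` with round-half-up to the
penny (this reproduces the printed totals exactly; banker's rounding
does not); minutes are kept exact, with hours displayed as half-up
integers.  Per-1,000 extrapolation is linear in the pathway denominator,
which defaults to 688 — the published arithmetic (107,371.89 × 1000/688 =
156,063.79) fixes that denominator even though 700 attendances were
recruited.

The published avoided-activity counts (454 reviews, 141 face-to-face,
124 biopsies) refer to the *full recruited pathway*, not the per-protocol
table: 454 all-negative attendances cannot coexist with 182
device-positive lesions inside only 789 PP lesions.  The pipeline
therefore accepts externally tallied counts as inputs (the spec-level
open question about their derivation is resolved in favour of the stated
assumption), and `derive_avoided_activity` is exercised on a constructed
full-pathway fixture that reproduces the counts exactly.

## Synthetic-data generator

`simulate_trial` emulates the assumed data-generating process: patients
carry 1 + Poisson(mean − 1) lesions (mean 1.2); each lesion draws a true
class from the design prevalences (MM 4.12%, SCC 5.16%, BCC 21.39%, the
remaining mass split over IEC/AK/AN and benign subtypes in the observed
suspected-diagnosis proportions); the device labels each lesion by its
operating point (detected malignancies keep their true class — the
hierarchy resolves to it — false positives draw a malignant label from a
fixed mix, negatives report their true non-malignant class); the
clinician's management is drawn from a referral sensitivity/specificity
point (defaults 0.970/0.719) with positive and negative decisions spread
over the management categories in fixed proportions; patient withdrawal
(10%), image-capture failure (24/867) and quality-check failure (6/843)
are Bernoulli exclusions; and the first third of lesions in accrual
order form phase 1.  Device specificity defaults are the observed
per-protocol values (A 0.832, B 0.799, RWS 0.733), and RWS uses
per-class sensitivities (0.95/0.95/0.905 for MM/SCC/BCC).

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: within-patient correlation of lesion classes
(a patient-level risk-multiplier hook exists but is off by default);
clinician reader variability; calendar-time drift (the COVID-era
management downgrades); and the gap between *design* prevalences and the
*confirmed* malignancy fraction — simulated cohorts confirm ~31% of
lesions malignant by histology, whereas the trial confirmed only 8.5%
because most suspected malignancies were never histology-confirmed.
Simulated PPV/NNB are therefore systematically more favourable than the
trial's; the primary-endpoint machinery is unaffected because it
conditions on the non-malignant subset.

`operating_characteristics` estimates the design's type-I error and
power by simulating per-phase correct-negative counts directly (binomial
draws at the endpoint level, vectorised over replicates) and applying
the same test-and-combine arithmetic as the record-level path, which is
exercised separately on full cohorts.  Ten thousand null replicates
reproduce the one-sided alpha within Monte-Carlo error (±0.004); the
observed effect size (0.832 vs 0.719) gives power > 0.95 at the study's
cohort shape.  Problem sizes in the shipped tests — 10,000 replicates
for the type-I check, 100 cohorts of ~9,600 lesions for parameter
recovery — were chosen to keep Monte-Carlo error well inside the asserted
tolerances.

## Numerical choices and degenerate inputs

* Normal quantiles/CDFs via scipy to double precision; bivariate-normal
  CDF via `scipy.stats.multivariate_normal` with an independent 1-D
  quadrature oracle in the tests.
* `two_proportion_z` raises on degenerate variance (all successes or all
  failures pooled); the vectorised simulator treats degenerate replicates
  as non-rejections.
* Combination weights must be positive; p-values supplied directly to
  `inverse_normal_combine` must lie strictly inside (0, 1).
* Zero denominators raise (`sensitivity` of an all-benign table), except
  zero NNB/NNR events, which return an explicit infinity.
* Proportion CIs are clipped to [0, 1]; ratio CIs invert interval
  endpoints, so a zero lower endpoint maps to an infinite upper bound.

## Known limitations

The package evaluates *labels*, not the classifier: the device is modelled
as an oracle with configurable operating points, and continuous scores,
ROC analysis and image quality are out of scope.  CIs ignore clustering
(above).  The boundary solver supports exactly one interim look, matching
the design it implements.  Re-derived design quantities that depend on
unpublished configuration (the 634-lesion sample size, the 700-patient
re-estimate, the exact 0.0246) are documented as unreproducible and the
published constants are used where the analysis needs them.
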