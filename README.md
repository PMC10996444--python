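# dermtriage

Diagnostic-accuracy and adaptive group-sequential evaluation of an AI
skin-lesion triage device against teledermatology standard of care.

Urgent skin-cancer pathways refer far more lesions than turn out to be
malignant.  An AI classifier that returns one of seven lesion classes —
melanoma (MM), squamous cell carcinoma (SCC), basal cell carcinoma (BCC),
intraepidermal carcinoma (IEC), actinic keratosis (AK), atypical nevus
(AN), benign — can triage lesions off the urgent pathway if it keeps
premalignant/benign lesions out of biopsy and urgent face-to-face review
at least as well as the remote consultant dermatologist (standard of
care, SoC) while matching their sensitivity for malignancy.  This package
implements the full evaluation pipeline for that question, for
biostatisticians and health-data analysts working with lesion-level
trial tables:

* **study_data / populations** — a validated lesion-level data model
  (CSV in/out with configurable column mapping) and the recruited →
  intention-to-treat → per-protocol population filters;
* **endpoints** — risk-hierarchy label resolution, histology-first truth
  adjudication (malignancy accepted only from histology), and
  configurable positivity rules for device and clinician;
* **accuracy** — confusion counts, sensitivity/specificity/PPV/NPV with
  Wilson (or Clopper–Pearson/Wald) intervals, number needed to biopsy
  (NNB = referred/malignancies = 1/PPV) and number needed to refer
  (NNR, for IEC/AK);
* **sequential** — the two-stage adaptive analysis: per-phase one-sided
  two-proportion z-tests z = (p̂₁ − p̂₂ + δ)/SE, inverse-normal
  (Lehmacher–Wassmer) combination Z = Σwᵢzᵢ/√Σwᵢ² with prespecified
  weights (0.577, 0.82), O'Brien–Fleming-type alpha spending and
  two-look boundary solving, non-inferiority sample size, and
  conditional-power interim assessment;
* **cost** — avoided reviews/face-to-face/biopsies under the triage
  assumption, priced with published unit costs and extrapolated per
  1,000 pathway patients;
* **simulate** — a synthetic trial generator with configurable
  prevalences and operating points, plus Monte-Carlo operating
  characteristics of the whole design.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

The published phase-level counts are the inputs; everything below is
computed by the package (`analysis/03_sequential_analysis.py` prints the
same numbers).  In phase 1 the device (setting A) correctly kept 138 of
178 non-malignant lesions off the urgent pathway vs 131/178 for SoC; in
phase 2, 463/544 vs 388/544:

```python
from dermtriage import DesignSpec, run_two_stage_from_counts

result = run_two_stage_from_counts((138, 178, 131, 178),
                                   (463, 544, 388, 544), DesignSpec())
print(result.phase1.z, result.phase2.z, result.combined_p, result.decision)
# 0.8634  5.5085  2.839e-07  reject
```

The per-phase z-statistics (0.86, 5.51) combine through the weighted
inverse-normal rule to a one-sided p of 2.8 × 10⁻⁷, below the adjusted
final-look level 0.0246, so the device's correct-negative rate is
significantly higher than the clinician's.  Accuracy statistics from a
lesion table reconstructed to match every published per-protocol count:

```text
 rater  sensitivity_fmt  specificity_fmt          ppv_fmt       nnb_fmt        nnr_fmt
   soc 97.0 (89.8-99.2) 71.9 (68.5-75.0) 24.3 (19.5-29.7) 4.2 (3.4-5.4) 8.6 (6.3-12.1)
  ai_a 91.0 (81.8-95.8) 83.2 (80.3-85.8) 33.5 (27.1-40.7) 3.0 (2.5-3.7)  4.5 (3.6-5.8)
ai_rws 94.0 (85.6-97.7) 73.3 (69.9-76.4) 24.6 (19.7-30.2) 4.1 (3.3-5.1)  5.2 (4.1-6.6)
```

i.e. the device trades ~6 points of sensitivity for ~11 points of
specificity against SoC: one malignancy per 3 biopsied lesions instead
of one per 4.2.  And the cost model (`analysis/04_cost_impact.py`): 454
avoided reviews, 141 avoided face-to-face assessments and 124 avoided
biopsies across 688 pathway patients price out at £52,409.76 +
£23,040.81 + £31,921.32 = £107,371.89 and 178 specialist hours saved —
£156,063.79 and 259 hours per 1,000 patients entering the pathway.

The numbered scripts under `analysis/` run the pipeline end to end
(simulated cohort, accuracy tables, sequential analysis, cost impact,
operating characteristics) and write their tables to `results/`.  A
`dermtriage` CLI wraps the same steps (`simulate`, `evaluate`,
`sequential-test`, `cost-impact`, `report`, `fixture`).

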