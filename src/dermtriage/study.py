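"""Published summary counts of the teledermatology triage trial.

These are the study's printed inputs — phase-level endpoint counts,
per-protocol accuracy marginals, avoided-activity totals and unit costs —
used by the study-marginals fixture, the analysis drivers and the
reproduction script.  Everything downstream is recomputed from them at run
time; nothing here is a result of this package.
"""

from __future__ import annotations

# ---------------------------------------------------------------- populations
RECRUITED_LESIONS = 867
ITT_LESIONS = 834
PP_LESIONS = 789
RECRUITED_PATIENTS = 688  # 700 attendances: 12 patients re-consented
RECRUITED_ATTENDANCES = 700
ITT_PATIENTS = 662
PP_PATIENTS = 622

# ------------------------------------------------------- primary endpoint data
# Correct classification of premalignant/benign lesions as not needing a
# biopsy or urgent face-to-face review (per phase; denominators are the
# non-malignant lesions in that phase).
PHASE1_N = 178
PHASE2_N = 544
PHASE1_CORRECT = {"ai_a": 138, "ai_b": 133, "soc": 131}
PHASE2_CORRECT = {"ai_a": 463, "ai_b": 444, "soc": 388}
PHASE1_MALIGNANT = 21
PHASE2_MALIGNANT = 46

# -------------------------------------------------------------- trial design
WEIGHTS = (0.577, 0.82)
INFORMATION_FRACTIONS = (1.0 / 3.0, 1.0)
OVERALL_ALPHA_ONE_SIDED = 0.025
FINAL_NOMINAL_ALPHA = 0.0246
NI_MARGIN = 0.01
DESIGN_POWER = 0.99
REASSESSMENT_POWER = 0.95
EXPECTED_DEVICE_SPECIFICITY = 0.54
EXPECTED_PREVALENCES = {"MM": 0.0412, "SCC": 0.0516, "BCC": 0.2139}
LESIONS_PER_PATIENT = 1.2
DROPOUT = 0.10
PLANNED_LESIONS = 634
PLANNED_PATIENTS = 581

# --------------------------------------------------- per-protocol accuracy (T4/5)
PP_MALIGNANT = 67          # 8 MM, 13 SCC, 46 BCC (all histology-confirmed)
PP_NON_MALIGNANT = PP_LESIONS - PP_MALIGNANT  # 722
PP_MALIGNANT_BY_CLASS = {"MM": 8, "SCC": 13, "BCC": 46}

AI_A_POSITIVE = 182
AI_A_TRUE_POSITIVE = 61
SOC_BIOPSY_REFERRED = 216
SOC_BIOPSY_MALIGNANT = 51
SOC_URGENT_REFERRED = 268
SOC_TRUE_POSITIVE = 65
SOC_URGENT_IEC_AK = 31
AI_A_REFERRAL_INCL_PREMALIGNANT = 249
AI_A_REFERRED_IEC_AK = 55
AI_RWS_POSITIVE = 256
AI_RWS_TRUE_POSITIVE = 63
AI_RWS_REFERRAL_INCL_PREMALIGNANT = 300
AI_RWS_REFERRED_IEC_AK = 58

# --------------------------------------------------------------- cost impact
COST_REVIEW = "115.44"    # GBP per teledermatology review
COST_F2F = "163.41"       # GBP per face-to-face assessment
COST_BIOPSY = "257.43"    # GBP per biopsy
MINUTES_REVIEW = 10.0
MINUTES_F2F = 15.0
MINUTES_BIOPSY = 32.5
AVOIDED_REVIEWS = 454
AVOIDED_F2F = 141
AVOIDED_BIOPSIES = 124
PATHWAY_PATIENTS = 688
SOC_F2F_TOTAL = 221
SOC_BIOPSY_TOTAL = 299

# ----------------------------------------------- image capture / quality check
CAPTURE_FAILURES = 24      # of 867 lesions
CAPTURED = 843
QC_FAILURES = 6            # of 843 captured
QC_PASSED = 837
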