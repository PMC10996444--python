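"""Programmatic lesion-table fixtures.

``study_marginals`` reconstructs a per-protocol lesion table consistent
with every printed summary count of the trial (789 lesions, 67
histology-confirmed malignancies, per-phase correct-negative counts,
referral and event counts behind every NNB/NNR).  The joint lesion-level
data were never deposited, so any table reproducing the marginals is
equally valid for the arithmetic this package checks; the construction is
deterministic and asserts all marginals before returning.

``study_cost`` is a full-pathway (recruited-population) cohort shaped so
the triage rule recovers the printed avoided-activity counts.  ``tiny``
is a 10-row hand-checkable table, and ``null_cohort`` is seed-fixed
simulated data with the device matched to the clinician.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import study
from .records import LESION_COLUMNS

FIXTURES = ("study_marginals", "study_cost", "tiny", "null_cohort")


def make_fixture(name: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Return (lesions, patients) for a named fixture."""
    if name == "study_marginals":
        return _study_marginals()
    if name == "study_cost":
        return _study_cost()
    if name == "tiny":
        return _tiny()
    if name == "null_cohort":
        from .simulate import SimulationConfig, simulate_trial, DEFAULT_SOC_OP

        config = SimulationConfig(
            n_patients=600,
            device_operating_points=(
                ("ai_a", DEFAULT_SOC_OP),
                ("ai_b", DEFAULT_SOC_OP),
                ("ai_rws", DEFAULT_SOC_OP),
            ),
            seed=20240322,
        )
        return simulate_trial(config)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")


class _Builder:
    def __init__(self):
        self.rows = []

    def add(self, n, **kw):
        defaults = dict(
            final_dx=None,
            dx_basis="clinical",
            unconfirmed_malignant=False,
            benign_subtype="",
            soc_management="DISCHARGE",
            soc_suspected_dx=None,
            ai_label_a="BENIGN",
            ai_label_b="BENIGN",
            ai_label_rws="BENIGN",
            image_captured=True,
            image_qc_passed=True,
            eligible=True,
            ineligible_reason="",
            phase=2,
        )
        defaults.update(kw)
        self.rows.extend(dict(defaults) for _ in range(n))

    def frame(self, prefix="L"):
        frame = pd.DataFrame(self.rows)
        frame.insert(0, "lesion_id", [f"{prefix}{i:04d}" for i in range(len(frame))])
        return frame


def _study_marginals() -> Tuple[pd.DataFrame, pd.DataFrame]:
    b = _Builder()

    # ---- malignant lesions (67, all histology-confirmed) -------------------
    # MM: 7 urgent biopsy + 1 Mohs; device-A misses one (labelled benign),
    # RWS finds all eight.
    b.add(6, final_dx="MM", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="MM", ai_label_b="MM", ai_label_rws="MM", phase=1)
    b.add(1, final_dx="MM", dx_basis="histology", soc_management="MOHS",
          ai_label_a="MM", ai_label_b="MM", ai_label_rws="MM")
    b.add(1, final_dx="MM", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="BENIGN", ai_label_b="BENIGN", ai_label_rws="MM")
    # SCC: 10 biopsy + 3 urgent F2F; all found by every device setting.
    b.add(4, final_dx="SCC", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="SCC", ai_label_b="SCC", ai_label_rws="SCC", phase=1)
    b.add(6, final_dx="SCC", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="SCC", ai_label_b="SCC", ai_label_rws="SCC")
    b.add(3, final_dx="SCC", dx_basis="histology", soc_management="URGENT_F2F",
          ai_label_a="SCC", ai_label_b="SCC", ai_label_rws="SCC")
    # BCC: 34 biopsy, 9 Mohs, 1 urgent F2F, 2 routine F2F.  Device-A finds
    # 41 of 46; setting B finds 42; RWS finds 42.
    b.add(11, final_dx="BCC", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="BCC", ai_label_b="BCC", ai_label_rws="BCC", phase=1)
    b.add(20, final_dx="BCC", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="BCC", ai_label_b="BCC", ai_label_rws="BCC")
    b.add(2, final_dx="BCC", dx_basis="histology", soc_management="NON_URGENT_BIOPSY",
          ai_label_a="BCC", ai_label_b="BCC", ai_label_rws="BCC")
    b.add(7, final_dx="BCC", dx_basis="histology", soc_management="MOHS",
          ai_label_a="BCC", ai_label_b="BCC", ai_label_rws="BCC")
    b.add(1, final_dx="BCC", dx_basis="histology", soc_management="URGENT_F2F",
          ai_label_a="BCC", ai_label_b="BCC", ai_label_rws="BCC")
    b.add(1, final_dx="BCC", dx_basis="histology", soc_management="MOHS",
          ai_label_a="BENIGN", ai_label_b="BCC", ai_label_rws="BCC")
    b.add(1, final_dx="BCC", dx_basis="histology", soc_management="MOHS",
          ai_label_a="BENIGN", ai_label_b="BENIGN", ai_label_rws="BENIGN")
    b.add(2, final_dx="BCC", dx_basis="histology", soc_management="ROUTINE_F2F",
          ai_label_a="BENIGN", ai_label_b="BENIGN", ai_label_rws="BENIGN")
    b.add(1, final_dx="BCC", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="BENIGN", ai_label_b="BENIGN", ai_label_rws="BENIGN")
    # assertions below confirm: SoC sens 65/67, biopsy-scope 51 malignant;
    # device TP: A=61, B=62, RWS=63.

    # ---- premalignant lesions: 25 IEC + 35 AK ------------------------------
    # Referral coverage: SoC refers 31; device-A refers 55 (as IEC/AK
    # labels); RWS refers 58 (14 via malignant false-positive labels, 44
    # via premalignant labels).
    def premal(n, dx, soc, a, rws, phase=2):
        b.add(n, final_dx=dx, soc_management=soc, ai_label_a=a,
              ai_label_b=a, ai_label_rws=rws, phase=phase)

    # 25 IEC: SoC refers 13 (11 biopsy + 2 urgent F2F)
    premal(8, "IEC", "URGENT_BIOPSY", "IEC", "SCC")       # RWS fp on IEC
    premal(3, "IEC", "NON_URGENT_BIOPSY", "IEC", "IEC")
    premal(2, "IEC", "URGENT_F2F", "IEC", "IEC")
    premal(10, "IEC", "ROUTINE_F2F", "IEC", "IEC")
    premal(2, "IEC", "DISCHARGE", "BENIGN", "BENIGN")     # missed by both
    # 35 AK: SoC refers 18 (14 biopsy + 4 urgent F2F)
    premal(6, "AK", "URGENT_BIOPSY", "AK", "BCC", phase=1)  # RWS fp on AK
    premal(8, "AK", "NON_URGENT_BIOPSY", "AK", "AK", phase=1)
    premal(4, "AK", "URGENT_F2F", "AK", "AK")
    premal(14, "AK", "ROUTINE_F2F", "AK", "AK")
    premal(3, "AK", "DISCHARGE", "BENIGN", "AK")          # missed by device A

    # ---- unconfirmed malignant suspects (non-malignant denominators) -------
    # 18 suspect-MM, 28 suspect-SCC, 5 suspect-BCC: clinical labels only.
    b.add(18, final_dx="MM", unconfirmed_malignant=True,
          soc_management="URGENT_BIOPSY", ai_label_a="MM", ai_label_b="MM",
          ai_label_rws="MM")
    b.add(28, final_dx="SCC", unconfirmed_malignant=True,
          soc_management="URGENT_BIOPSY", ai_label_a="SCC", ai_label_b="SCC",
          ai_label_rws="SCC")
    b.add(5, final_dx="BCC", unconfirmed_malignant=True,
          soc_management="NON_URGENT_BIOPSY", ai_label_a="BCC", ai_label_b="BCC",
          ai_label_rws="BCC")

    # ---- benign lesions ----------------------------------------------------
    # Non-malignant totals per phase: phase 1 = 178 (14 AK + 164 benign),
    # phase 2 = 544 (46 premalignant + 29 AN + 51 suspects + 418 benign).
    # Device false positives (malignant labels on non-malignant lesions):
    #   A: 121 = 40 phase-1 benign + 30 phase-2 benign + 51 suspects;
    #   B: 145 = A's plus 5 phase-1 and 19 phase-2 extras;
    #   RWS: 193 = 14 premalignant + 51 suspects + 128 benign (40+30+19+39).
    # SoC urgent-pathway referrals on non-malignant lesions: 203 = 31
    # premalignant + 51 suspects + 121 benign, split 47 phase 1 / 156
    # phase 2; the biopsy-scope subset is 165 = 25 + 51 + 89.

    def benign(n, subtype, soc, a, bb, rws, phase=2):
        b.add(n, final_dx="BENIGN", benign_subtype=subtype, soc_management=soc,
              ai_label_a=a, ai_label_b=bb, ai_label_rws=rws, phase=phase)

    # phase 1 benign rows (164)
    benign(33, "seborrheic_keratosis", "URGENT_BIOPSY", "MM", "MM", "MM", phase=1)
    benign(7, "seborrheic_keratosis", "DISCHARGE", "MM", "MM", "MM", phase=1)
    benign(5, "melanocytic_nevus", "ROUTINE_F2F", "BENIGN", "BCC", "BENIGN", phase=1)
    benign(30, "melanocytic_nevus", "DISCHARGE", "BENIGN", "BENIGN", "BENIGN",
           phase=1)
    benign(89, "melanocytic_nevus", "DISCHARGE", "BENIGN", "BENIGN", "BENIGN",
           phase=1)

    # phase 2 benign rows (418)
    benign(30, "seborrheic_keratosis", "URGENT_BIOPSY", "SCC", "SCC", "SCC")
    benign(7, "seborrheic_keratosis", "URGENT_BIOPSY", "BENIGN", "BENIGN", "BENIGN")
    benign(19, "seborrheic_keratosis", "ROUTINE_F2F", "BENIGN", "BCC", "BCC")
    benign(39, "lentigo", "ROUTINE_F2F", "BENIGN", "BENIGN", "BCC")
    benign(40, "lentigo", "ROUTINE_F2F", "BENIGN", "BENIGN", "BENIGN")
    # device-A premalignant labels on benign lesions (NNR referral set):
    # 249 - 182 = 67 IEC/AK labels, 55 on true IEC/AK -> 12 on benign.
    benign(12, "seborrheic_keratosis", "DISCHARGE", "AK", "AK", "BENIGN")
    benign(19, "dermatofibroma", "NON_URGENT_BIOPSY", "BENIGN", "BENIGN", "BENIGN")
    benign(32, "vascular", "URGENT_F2F", "BENIGN", "BENIGN", "BENIGN")
    b.add(29, final_dx="AN", soc_management="DISCHARGE", ai_label_a="AN",
          ai_label_b="AN", ai_label_rws="AN")
    benign(220, "melanocytic_nevus", "DISCHARGE", "BENIGN", "BENIGN", "BENIGN")

    lesions = b.frame()
    assert len(lesions) == study.PP_LESIONS, len(lesions)

    # patient / attendance structure: 622 patients, multi-lesion patients first
    n_extra = study.PP_LESIONS - study.PP_PATIENTS
    pat_idx = np.concatenate(
        [np.arange(study.PP_PATIENTS), np.arange(n_extra)]
    )
    pids = np.array([f"P{i:04d}" for i in pat_idx])
    lesions["patient_id"] = pids
    lesions["attendance_id"] = pids

    rng = np.random.default_rng(789)
    n_pat = study.PP_PATIENTS
    n_female = round(0.633 * n_pat)  # 394
    sex = np.array(["female"] * n_female + ["male"] * (n_pat - n_female))
    age = np.clip(rng.normal(51.5, 19.6, size=n_pat), 18, 95).round(0)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_pat)],
            "age": age,
            "sex": sex,
            "ethnic_group": "white",
            "fitzpatrick": 2,
            "history_skin_cancer": "none",
        }
    )
    _check_study_marginals(lesions)
    return lesions[LESION_COLUMNS], patients


def _check_study_marginals(frame: pd.DataFrame) -> None:
    from .accuracy import confusion_counts
    from .endpoints import (
        PositivityRule,
        correct_negative_counts,
        positive_mask,
        truth_malignant_mask,
    )
    from .records import PREMALIGNANT_CLASSES

    mal = truth_malignant_mask(frame)
    assert int(mal.sum()) == study.PP_MALIGNANT
    for phase, n_expect, correct in (
        (1, study.PHASE1_N, study.PHASE1_CORRECT),
        (2, study.PHASE2_N, study.PHASE2_CORRECT),
    ):
        sub = frame[frame["phase"] == phase]
        for rater, k_expect in correct.items():
            k, n = correct_negative_counts(sub, rater)
            assert (k, n) == (k_expect, n_expect), (phase, rater, k, n)
    c_a = confusion_counts(frame, PositivityRule("ai_a", "urgent_referral"))
    assert (c_a.tp, c_a.tp + c_a.fp) == (
        study.AI_A_TRUE_POSITIVE,
        study.AI_A_POSITIVE,
    ), c_a
    c_rws = confusion_counts(frame, PositivityRule("ai_rws", "urgent_referral"))
    assert (c_rws.tp, c_rws.tp + c_rws.fp) == (
        study.AI_RWS_TRUE_POSITIVE,
        study.AI_RWS_POSITIVE,
    ), c_rws
    c_soc = confusion_counts(frame, PositivityRule("soc", "urgent_referral"))
    assert c_soc.tp == study.SOC_TRUE_POSITIVE
    assert c_soc.tp + c_soc.fp == study.SOC_URGENT_REFERRED
    soc_biopsy = positive_mask(frame, PositivityRule("soc", "biopsy"))
    assert int(soc_biopsy.sum()) == study.SOC_BIOPSY_REFERRED
    assert int((soc_biopsy & mal).sum()) == study.SOC_BIOPSY_MALIGNANT
    premal = frame["final_dx"].isin(PREMALIGNANT_CLASSES).to_numpy()
    soc_ref = positive_mask(frame, PositivityRule("soc", "urgent_referral"))
    assert int((soc_ref & premal).sum()) == study.SOC_URGENT_IEC_AK
    for rater, n_ref, n_ev in (
        ("ai_a", study.AI_A_REFERRAL_INCL_PREMALIGNANT, study.AI_A_REFERRED_IEC_AK),
        (
            "ai_rws",
            study.AI_RWS_REFERRAL_INCL_PREMALIGNANT,
            study.AI_RWS_REFERRED_IEC_AK,
        ),
    ):
        ref = positive_mask(frame, PositivityRule(rater, "referral_incl_premalignant"))
        assert int(ref.sum()) == n_ref, (rater, int(ref.sum()))
        assert int((ref & premal).sum()) == n_ev, (rater, int((ref & premal).sum()))


def _study_cost() -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full-pathway cohort: 688 attendances / 867 lesions shaped so the
    triage rule yields the printed avoided-activity counts."""
    b = _Builder()
    # 454 single-lesion attendances, all device-negative:
    #   124 with a planned biopsy, 141 with a planned face-to-face,
    #   189 review-only.  (The first two groups accrued in phase 1 so the
    #   cohort supports a two-stage analysis end to end.)
    b.add(124, final_dx="BENIGN", soc_management="NON_URGENT_BIOPSY", phase=1)
    b.add(141, final_dx="BENIGN", soc_management="ROUTINE_F2F", phase=1)
    b.add(189, final_dx="BENIGN", soc_management="DISCHARGE")
    # 234 attendances with at least one device-positive lesion (413 lesions:
    # 179 attendances carry a second lesion).  SoC planned 299 biopsies and
    # 221 face-to-face assessments overall: 175 biopsies and 80 F2F sit on
    # positive lesions, so none of these are avoided.
    b.add(175, final_dx="BCC", dx_basis="histology",
          soc_management="URGENT_BIOPSY", ai_label_a="BCC", ai_label_b="BCC",
          ai_label_rws="BCC")
    b.add(80, final_dx="BENIGN", soc_management="URGENT_F2F", ai_label_a="MM",
          ai_label_b="MM", ai_label_rws="MM")
    b.add(158, final_dx="BENIGN", soc_management="DISCHARGE", ai_label_a="SCC",
          ai_label_b="SCC", ai_label_rws="SCC")
    lesions = b.frame(prefix="C")
    assert len(lesions) == study.RECRUITED_LESIONS

    # attendance ids: 454 negatives alone; 413 positive-attendance lesions
    # packed into 234 attendances (first 179 take two lesions).
    att = [f"A{i:04d}" for i in range(454)]
    pos_att = [f"A{454 + i:04d}" for i in range(234)]
    att += pos_att + pos_att[:179]
    assert len(att) == study.RECRUITED_LESIONS
    lesions["attendance_id"] = att
    lesions["patient_id"] = att
    n_att = lesions["attendance_id"].nunique()
    assert n_att == study.PATHWAY_PATIENTS, n_att
    patients = pd.DataFrame(
        {
            "patient_id": sorted(set(att)),
            "age": 50.0,
            "sex": "female",
            "ethnic_group": "white",
            "fitzpatrick": 2,
            "history_skin_cancer": "none",
        }
    )
    return lesions[LESION_COLUMNS], patients


def _tiny() -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Ten hand-checkable lesions: 2 confirmed malignant, 8 non-malignant;
    device-A refers 3 (2 TP, 1 FP), SoC refers 4 (2 TP, 2 FP)."""
    b = _Builder()
    b.add(1, final_dx="MM", dx_basis="histology", soc_management="URGENT_BIOPSY",
          ai_label_a="MM", ai_label_b="MM", ai_label_rws="MM", phase=1)
    b.add(1, final_dx="BCC", dx_basis="histology", soc_management="MOHS",
          ai_label_a="BCC", ai_label_b="BCC", ai_label_rws="BCC", phase=1)
    b.add(1, final_dx="AK", soc_management="URGENT_BIOPSY", ai_label_a="AK",
          ai_label_b="AK", ai_label_rws="AK", phase=1)
    b.add(1, final_dx="IEC", soc_management="ROUTINE_F2F", ai_label_a="IEC",
          ai_label_b="IEC", ai_label_rws="SCC", phase=1)
    b.add(1, final_dx="BENIGN", benign_subtype="seborrheic_keratosis",
          soc_management="URGENT_F2F", ai_label_a="MM", ai_label_b="MM",
          ai_label_rws="MM", phase=1)
    b.add(1, final_dx="BENIGN", benign_subtype="melanocytic_nevus",
          soc_management="DISCHARGE", ai_label_a="BENIGN", ai_label_b="BENIGN",
          ai_label_rws="BENIGN")
    b.add(1, final_dx="AN", soc_management="DISCHARGE", ai_label_a="AN",
          ai_label_b="AN", ai_label_rws="AN")
    b.add(1, final_dx="SCC", unconfirmed_malignant=True,
          soc_management="NON_URGENT_BIOPSY", ai_label_a="BENIGN",
          ai_label_b="SCC", ai_label_rws="SCC")
    b.add(1, final_dx="BENIGN", benign_subtype="lentigo",
          soc_management="DISCHARGE", ai_label_a="BENIGN", ai_label_b="BENIGN",
          ai_label_rws="BENIGN")
    b.add(1, final_dx="BENIGN", benign_subtype="vascular",
          soc_management="ROUTINE_F2F", ai_label_a="BENIGN", ai_label_b="BENIGN",
          ai_label_rws="BENIGN")
    lesions = b.frame(prefix="T")
    lesions["patient_id"] = [f"P{i:02d}" for i in range(10)]
    lesions["attendance_id"] = lesions["patient_id"]
    patients = pd.DataFrame(
        {
            "patient_id": lesions["patient_id"],
            "age": np.linspace(25, 80, 10).round(0),
            "sex": ["female"] * 6 + ["male"] * 4,
            "ethnic_group": "white",
            "fitzpatrick": 2,
            "history_skin_cancer": "none",
        }
    )
    return lesions[LESION_COLUMNS], patients
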