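"""Population filtering (recruited -> ITT -> PP) and cohort summaries.

The intention-to-treat (ITT) population drops ineligible lesions and
lesions without a final diagnosis; the per-protocol (PP) population
additionally drops lesions without a device result (image not captured,
image failed the quality check, or any device label absent).
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .records import PopulationStage

AI_LABEL_COLUMNS = ("ai_label_a", "ai_label_b", "ai_label_rws")


def _absent(series: pd.Series) -> pd.Series:
    return series.isna() | (series.astype(object) == "")


def apply_population_filter(
    lesions: pd.DataFrame, stage
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Filter the lesion table to an analysis population.

    Returns ``(filtered, exclusions)`` where ``exclusions`` counts dropped
    lesions per reason.  Reasons partition the dropped set (a lesion is
    charged to the first reason that applies), so the counts sum to
    ``len(recruited) - len(filtered)``.
    """
    stage = PopulationStage(stage)
    exclusions: Dict[str, int] = {}
    if stage is PopulationStage.RECRUITED:
        return lesions.copy(), exclusions

    ineligible = ~lesions["eligible"].astype(bool)
    no_dx = _absent(lesions["final_dx"]) & ~ineligible
    exclusions["ineligible"] = int(ineligible.sum())
    exclusions["no_final_diagnosis"] = int(no_dx.sum())
    keep = ~(ineligible | no_dx)
    if stage is PopulationStage.ITT:
        return lesions.loc[keep].copy(), exclusions

    no_image = keep & ~lesions["image_captured"].astype(bool)
    qc_failed = (
        keep & lesions["image_captured"].astype(bool)
        & ~lesions["image_qc_passed"].astype(bool)
    )
    label_absent = keep & ~no_image & ~qc_failed
    any_absent = np.zeros(len(lesions), dtype=bool)
    for col in AI_LABEL_COLUMNS:
        any_absent |= _absent(lesions[col]).to_numpy()
    label_absent &= any_absent
    exclusions["no_image"] = int(no_image.sum())
    exclusions["image_qc_failed"] = int(qc_failed.sum())
    exclusions["no_ai_label"] = int(label_absent.sum())
    keep &= ~(no_image | qc_failed | label_absent)
    return lesions.loc[keep].copy(), exclusions


def summarize_cohort(
    lesions: pd.DataFrame, patients: pd.DataFrame
) -> Dict[str, object]:
    """Counts and percentages by demographic strata, plus lesion counts.

    Percentages are of the non-missing patients in each breakdown and sum
    to 100 up to rounding.
    """
    summary: Dict[str, object] = {
        "n_lesions": int(len(lesions)),
        "n_patients": int(len(patients)),
        "n_attendances": int(lesions["attendance_id"].nunique()) if len(lesions) else 0,
    }
    if len(patients) == 0:
        return summary

    def breakdown(series: pd.Series) -> Dict[str, Dict[str, float]]:
        counts = series.value_counts(dropna=False)
        total = int(counts.sum())
        return {
            str(k): {"n": int(v), "pct": round(100.0 * v / total, 1)}
            for k, v in counts.items()
        }

    if "sex" in patients.columns:
        summary["sex"] = breakdown(patients["sex"])
    if "ethnic_group" in patients.columns:
        summary["ethnic_group"] = breakdown(patients["ethnic_group"])
    if "fitzpatrick" in patients.columns:
        summary["fitzpatrick"] = breakdown(patients["fitzpatrick"])
    if "history_skin_cancer" in patients.columns:
        summary["history_skin_cancer"] = breakdown(patients["history_skin_cancer"])
    if "age" in patients.columns:
        age = pd.to_numeric(patients["age"])
        summary["age"] = {
            "mean": float(age.mean()),
            "sd": float(age.std(ddof=1)) if len(age) > 1 else 0.0,
            "min": float(age.min()),
            "max": float(age.max()),
        }
        bins = [18, 30, 40, 50, 60, 70, 80, np.inf]
        labels = ["18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"]
        groups = pd.cut(age, bins=bins, labels=labels, right=False)
        summary["age_group"] = breakdown(groups.astype(str))
    if "final_dx" in lesions.columns and len(lesions):
        summary["final_dx"] = {
            str(k): int(v)
            for k, v in lesions["final_dx"].value_counts(dropna=False).items()
        }
    return summary
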