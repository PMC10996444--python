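"""Analysis endpoints: risk hierarchy, truth adjudication and positivity rules.

The device returns a single label resolved through a risk-based hierarchy
(the most serious plausible class wins).  Ground truth is adjudicated from
histology where available, otherwise the clinical diagnosis; a malignant
diagnosis is only accepted from histology, so a malignant clinical label
without histology is flagged unconfirmed and counted non-malignant in every
accuracy denominator.

Positivity rules translate a rater's output into a referral decision:

* AI raters are positive when the label is malignant (MM/SCC/BCC); for the
  number-needed-to-refer analysis the scope widens to include the
  premalignant labels IEC and AK.
* The teledermatologist (standard of care, SoC) is positive when the
  management decision puts the lesion on the urgent cancer pathway (urgent
  or non-urgent biopsy, urgent face-to-face review, or the BCC/Mohs
  clinic); routine review and discharge are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import (
    DiagnosisClass,
    DxBasis,
    MALIGNANT_CLASSES,
    ManagementDecision,
    PREMALIGNANT_CLASSES,
)

#: Default seriousness order, most serious first.
DEFAULT_HIERARCHY: Tuple[str, ...] = ("MM", "SCC", "BCC", "IEC", "AK", "AN", "BENIGN")

#: Managements that put a lesion on the urgent cancer pathway (SoC positive).
SOC_POSITIVE_MANAGEMENTS = frozenset(
    {"URGENT_BIOPSY", "NON_URGENT_BIOPSY", "URGENT_F2F", "MOHS"}
)
#: Managements that send a lesion directly to biopsy (SoC NNB scope).
SOC_BIOPSY_MANAGEMENTS = frozenset({"URGENT_BIOPSY", "NON_URGENT_BIOPSY"})

RATER_LABEL_COLUMNS = {
    "ai_a": "ai_label_a",
    "ai_b": "ai_label_b",
    "ai_rws": "ai_label_rws",
}

SCOPES = ("biopsy", "urgent_referral", "referral_incl_premalignant")


@dataclass(frozen=True)
class RiskHierarchy:
    """A total seriousness order over the seven top-level classes."""

    order: Tuple[str, ...] = DEFAULT_HIERARCHY

    def __post_init__(self):
        if sorted(self.order) != sorted(DEFAULT_HIERARCHY):
            raise ValueError(
                "hierarchy must be a permutation of the seven classes, got "
                f"{self.order!r}"
            )

    def rank(self, dx: str) -> int:
        return self.order.index(str(DiagnosisClass(dx).value))


@dataclass(frozen=True)
class PositivityRule:
    """Which rater is consulted and which outputs count as 'refer'.

    ``positive_classes`` / ``positive_managements`` may be overridden (for
    instance to count OTHER_SPECIALTY as a referral); by default they
    follow the scope.
    """

    rater: str  # "soc" | "ai_a" | "ai_b" | "ai_rws"
    scope: str = "urgent_referral"
    positive_classes: Optional[frozenset] = None
    positive_managements: Optional[frozenset] = None

    def __post_init__(self):
        if self.rater not in ("soc", *RATER_LABEL_COLUMNS):
            raise ValueError(f"unknown rater {self.rater!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def classes(self) -> frozenset:
        if self.positive_classes is not None:
            return self.positive_classes
        if self.scope == "referral_incl_premalignant":
            return frozenset(MALIGNANT_CLASSES | PREMALIGNANT_CLASSES)
        return frozenset(MALIGNANT_CLASSES)

    @property
    def managements(self) -> frozenset:
        if self.positive_managements is not None:
            return self.positive_managements
        if self.scope == "biopsy":
            return SOC_BIOPSY_MANAGEMENTS
        return SOC_POSITIVE_MANAGEMENTS


def resolve_hierarchy(
    candidates: Iterable, hierarchy: RiskHierarchy = RiskHierarchy()
) -> DiagnosisClass:
    """Return the most serious class among ``candidates``.

    This is the device's label-resolution rule: a lesion plausibly either
    BCC or melanoma is reported as melanoma.
    """
    cands = {DiagnosisClass(c) for c in candidates}
    if not cands:
        raise ValueError("resolve_hierarchy requires a non-empty candidate set")
    return min(cands, key=lambda c: hierarchy.rank(c.value))


def adjudicate_truth(
    histology_dx: Optional[DiagnosisClass],
    clinical_dx: Optional[DiagnosisClass],
    second_opinion: Optional[DiagnosisClass] = None,
) -> Tuple[DiagnosisClass, DxBasis, bool]:
    """Adjudicate the final diagnosis.

    Returns ``(final_dx, dx_basis, unconfirmed_malignant)``.  Histology,
    when present, overrides everything.  Without histology a malignant
    clinical label cannot be confirmed: the class is kept but flagged
    unconfirmed, and downstream accuracy denominators treat the lesion as
    non-malignant.
    """
    if histology_dx is not None:
        return DiagnosisClass(histology_dx), DxBasis.HISTOLOGY, False
    if clinical_dx is None:
        raise ValueError("adjudicate_truth requires a clinical diagnosis")
    if second_opinion is not None:
        dx = DiagnosisClass(second_opinion)
        basis = DxBasis.CLINICAL_SECOND_OPINION
    else:
        dx = DiagnosisClass(clinical_dx)
        basis = DxBasis.CLINICAL
    return dx, basis, dx.value in MALIGNANT_CLASSES


def is_malignant(dx) -> bool:
    """True iff the class is MM, SCC or BCC."""
    return DiagnosisClass(dx).value in MALIGNANT_CLASSES


def truth_malignant_mask(frame: pd.DataFrame) -> pd.Series:
    """Analysis truth: malignant iff histology-confirmed MM/SCC/BCC.

    Unconfirmed-malignant clinical labels fall into the non-malignant
    denominator (the study's specificity denominators require this).
    """
    dx_mal = frame["final_dx"].isin(MALIGNANT_CLASSES)
    confirmed = frame["dx_basis"] == DxBasis.HISTOLOGY.value
    return (dx_mal & confirmed).to_numpy(dtype=bool)


def positive_mask(frame: pd.DataFrame, rule: PositivityRule) -> np.ndarray:
    """Vectorised referral decision for every lesion in ``frame``."""
    if rule.rater == "soc":
        return frame["soc_management"].isin(rule.managements).to_numpy(dtype=bool)
    col = RATER_LABEL_COLUMNS[rule.rater]
    labels = frame[col]
    missing = labels.isna() | (labels == "")
    if missing.any():
        idx = frame.loc[missing, "lesion_id"].iloc[0]
        raise ValueError(
            f"rater {rule.rater!r} has no label for lesion {idx!r} "
            f"({int(missing.sum())} lesions affected)"
        )
    return labels.isin(rule.classes).to_numpy(dtype=bool)


def rater_positive(record, rule: PositivityRule) -> bool:
    """Referral decision for a single lesion record (row or dataclass)."""
    frame = _one_row_frame(record)
    return bool(positive_mask(frame, rule)[0])


def correct_negative(record, rater: str) -> bool:
    """Primary-endpoint event: a non-malignant lesion kept off the urgent
    pathway (not referred for biopsy or urgent face-to-face review)."""
    frame = _one_row_frame(record)
    if truth_malignant_mask(frame)[0]:
        lid = frame["lesion_id"].iloc[0]
        raise ValueError(
            f"correct_negative is undefined for malignant lesion {lid!r}"
        )
    return not bool(
        positive_mask(frame, PositivityRule(rater, "urgent_referral"))[0]
    )


def correct_negative_counts(frame: pd.DataFrame, rater: str) -> Tuple[int, int]:
    """(correct negatives, non-malignant total) for one rater."""
    nonmal = frame.loc[~truth_malignant_mask(frame)]
    if len(nonmal) == 0:
        return 0, 0
    pos = positive_mask(nonmal, PositivityRule(rater, "urgent_referral"))
    return int((~pos).sum()), int(len(nonmal))


def _one_row_frame(record) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, pd.Series):
        return record.to_frame().T
    # dataclass LesionRecord
    from dataclasses import asdict

    row = {
        k: (v.value if hasattr(v, "value") else v)
        for k, v in asdict(record).items()
    }
    return pd.DataFrame([row])
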