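"""Core data model for a lesion-level teledermatology triage trial.

The atomic analysis unit is a lesion.  Each lesion carries a final
(adjudicated) diagnosis, the teledermatologist's management decision, and
the AI device's output label under each threshold setting.  Patients may
attend more than once (re-consent), so lesions reference both a patient id
and an attendance id; all analyses are lesion-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class DiagnosisClass(str, Enum):
    """The seven top-level lesion classes, most to least serious.

    MM, SCC and BCC are the malignant classes; IEC (Bowen's disease),
    AK and AN are premalignant/equivocal and are grouped with benign for
    specificity.
    """

    MM = "MM"
    SCC = "SCC"
    BCC = "BCC"
    IEC = "IEC"
    AK = "AK"
    AN = "AN"
    BENIGN = "BENIGN"


#: Benign subtype tags (optional refinement of BENIGN).
BENIGN_SUBTYPES = (
    "seborrheic_keratosis",
    "dermatofibroma",
    "vascular",
    "lentigo",
    "melanocytic_nevus",
    "other",
)

MALIGNANT_CLASSES = frozenset({"MM", "SCC", "BCC"})
PREMALIGNANT_CLASSES = frozenset({"IEC", "AK"})
NON_MALIGNANT_CLASSES = frozenset({"IEC", "AK", "AN", "BENIGN"})


class ManagementDecision(str, Enum):
    """Teledermatology triage outcomes for a lesion."""

    URGENT_BIOPSY = "URGENT_BIOPSY"
    NON_URGENT_BIOPSY = "NON_URGENT_BIOPSY"
    URGENT_F2F = "URGENT_F2F"
    MOHS = "MOHS"
    OTHER_SPECIALTY = "OTHER_SPECIALTY"
    ROUTINE_F2F = "ROUTINE_F2F"
    DISCHARGE = "DISCHARGE"


#: Short tokens used in figures/exports; accepted on input alongside full names.
MANAGEMENT_TOKENS = {
    "UB": ManagementDecision.URGENT_BIOPSY,
    "NUB": ManagementDecision.NON_URGENT_BIOPSY,
    "UF2F": ManagementDecision.URGENT_F2F,
    "MOHS": ManagementDecision.MOHS,
    "OS": ManagementDecision.OTHER_SPECIALTY,
    "RF2F": ManagementDecision.ROUTINE_F2F,
    "D": ManagementDecision.DISCHARGE,
}


class DxBasis(str, Enum):
    """How the final diagnosis was reached."""

    HISTOLOGY = "histology"
    CLINICAL = "clinical"
    CLINICAL_SECOND_OPINION = "clinical_second_opinion"


class PopulationStage(str, Enum):
    RECRUITED = "recruited"
    ITT = "itt"
    PP = "pp"


@dataclass
class LesionRecord:
    """One lesion's truth, clinician assessment, and device labels.

    ``final_dx`` may be None for lesions excluded before adjudication
    (withdrawals); such lesions drop out at the intention-to-treat filter.
    ``unconfirmed_malignant`` marks a malignant *clinical* label without
    histological confirmation; those lesions count in the non-malignant
    denominator of every accuracy statistic.
    """

    lesion_id: str
    patient_id: str
    attendance_id: str
    final_dx: Optional[DiagnosisClass]
    dx_basis: Optional[DxBasis]
    soc_management: ManagementDecision
    soc_suspected_dx: Optional[DiagnosisClass] = None
    ai_label_a: Optional[DiagnosisClass] = None
    ai_label_b: Optional[DiagnosisClass] = None
    ai_label_rws: Optional[DiagnosisClass] = None
    image_captured: bool = True
    image_qc_passed: bool = True
    eligible: bool = True
    ineligible_reason: str = ""
    unconfirmed_malignant: bool = False
    benign_subtype: str = ""
    phase: int = 1

    def validate(self) -> None:
        if self.phase not in (1, 2):
            raise ValueError(f"phase must be 1 or 2, got {self.phase!r}")
        if (
            self.dx_basis is not None
            and DxBasis(self.dx_basis) is DxBasis.HISTOLOGY
            and self.final_dx is None
        ):
            raise ValueError(
                f"lesion {self.lesion_id}: histology basis requires final_dx"
            )
        if not (self.image_captured and self.image_qc_passed):
            if any(
                lab is not None
                for lab in (self.ai_label_a, self.ai_label_b, self.ai_label_rws)
            ):
                raise ValueError(
                    f"lesion {self.lesion_id}: AI labels present without a "
                    "captured, quality-checked image"
                )
        if self.benign_subtype and self.benign_subtype not in BENIGN_SUBTYPES:
            raise ValueError(
                f"lesion {self.lesion_id}: unknown benign subtype "
                f"{self.benign_subtype!r}"
            )


@dataclass
class PatientRecord:
    """Per-patient covariates (Fitzpatrick phototype I..VI as 1..6)."""

    patient_id: str
    age: float
    sex: str  # "female" | "male"
    ethnic_group: str = "unknown"
    fitzpatrick: int = 2
    history_skin_cancer: str = "none"

    def validate(self) -> None:
        if self.age < 18:
            raise ValueError(f"patient {self.patient_id}: age must be >= 18")
        if self.fitzpatrick not in range(1, 7):
            raise ValueError(
                f"patient {self.patient_id}: fitzpatrick must be 1..6"
            )


#: Canonical lesion-table columns (in serialisation order).
LESION_COLUMNS = [
    "lesion_id",
    "patient_id",
    "attendance_id",
    "final_dx",
    "dx_basis",
    "unconfirmed_malignant",
    "benign_subtype",
    "soc_management",
    "soc_suspected_dx",
    "ai_label_a",
    "ai_label_b",
    "ai_label_rws",
    "image_captured",
    "image_qc_passed",
    "eligible",
    "ineligible_reason",
    "phase",
]

MANDATORY_LESION_COLUMNS = [
    "lesion_id",
    "patient_id",
    "attendance_id",
    "final_dx",
    "dx_basis",
    "soc_management",
    "ai_label_a",
    "ai_label_b",
    "ai_label_rws",
    "image_captured",
    "image_qc_passed",
    "eligible",
    "phase",
]

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "ethnic_group",
    "fitzpatrick",
    "history_skin_cancer",
]
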