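"""Cost-impact arithmetic for AI-based triage.

If the device keeps an attendance entirely premalignant/benign, its
teledermatology review is assumed avoidable; face-to-face assessments and
biopsies planned by the clinician are avoided for device-negative lesions.
Component savings are unit cost x count, rounded half-up to the penny;
specialist minutes are kept exact with hours displayed as rounded
integers; totals extrapolate linearly per 1,000 patients entering the
pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Optional

import pandas as pd

from . import study
from .endpoints import RATER_LABEL_COLUMNS
from .records import NON_MALIGNANT_CLASSES

_PENNY = Decimal("0.01")

#: Managements that imply a face-to-face assessment / a biopsy.
F2F_MANAGEMENTS = frozenset({"URGENT_F2F", "ROUTINE_F2F", "MOHS"})
BIOPSY_MANAGEMENTS = frozenset({"URGENT_BIOPSY", "NON_URGENT_BIOPSY"})


def _money(x) -> Decimal:
    return Decimal(str(x)).quantize(_PENNY, rounding=ROUND_HALF_UP)


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CostParams:
    """Unit costs (currency) and specialist minutes per activity."""

    review_cost: Decimal = Decimal(study.COST_REVIEW)
    review_minutes: float = study.MINUTES_REVIEW
    f2f_cost: Decimal = Decimal(study.COST_F2F)
    f2f_minutes: float = study.MINUTES_F2F
    biopsy_cost: Decimal = Decimal(study.COST_BIOPSY)
    biopsy_minutes: float = study.MINUTES_BIOPSY

    def __post_init__(self):
        for name in ("review_cost", "f2f_cost", "biopsy_cost"):
            object.__setattr__(self, name, Decimal(str(getattr(self, name))))
        if min(
            self.review_cost, self.f2f_cost, self.biopsy_cost
        ) < 0 or min(self.review_minutes, self.f2f_minutes, self.biopsy_minutes) < 0:
            raise ValueError("costs and minutes must be non-negative")


@dataclass(frozen=True)
class AvoidedActivity:
    """Counts of activities the device's triage would have removed."""

    reviews_avoided: int
    f2f_avoided: int
    biopsies_avoided: int
    pathway_patients: int

    def __post_init__(self):
        if min(
            self.reviews_avoided,
            self.f2f_avoided,
            self.biopsies_avoided,
            self.pathway_patients,
        ) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CostImpact:
    review_saving: Decimal
    f2f_saving: Decimal
    biopsy_saving: Decimal
    total_saving: Decimal
    review_minutes: float
    f2f_minutes: float
    biopsy_minutes: float
    total_minutes: float
    total_hours: int  # display value, rounded half-up
    per_1000_saving: Optional[Decimal]
    per_1000_minutes: Optional[float]
    per_1000_hours: Optional[int]

    def component_hours(self) -> Dict[str, int]:
        return {
            "review": _round_half_up(self.review_minutes / 60),
            "f2f": _round_half_up(self.f2f_minutes / 60),
            "biopsy": _round_half_up(self.biopsy_minutes / 60),
        }

    def as_dict(self) -> Dict[str, object]:
        d = {
            "review_saving": str(self.review_saving),
            "f2f_saving": str(self.f2f_saving),
            "biopsy_saving": str(self.biopsy_saving),
            "total_saving": str(self.total_saving),
            "total_minutes": self.total_minutes,
            "total_hours": self.total_hours,
            "component_hours": self.component_hours(),
        }
        if self.per_1000_saving is not None:
            d["per_1000_saving"] = str(self.per_1000_saving)
            d["per_1000_hours"] = self.per_1000_hours
        return d


def derive_avoided_activity(
    frame: pd.DataFrame, ai_rater: str = "ai_a"
) -> AvoidedActivity:
    """Apply the triage assumption lesion-by-lesion.

    A review is avoided iff every lesion at that attendance carries a
    premalignant-or-benign device label; a clinician-planned face-to-face
    assessment or biopsy is avoided iff its lesion is device-negative.
    """
    col = RATER_LABEL_COLUMNS[ai_rater]
    labels = frame[col]
    if (labels.isna() | (labels == "")).any():
        raise ValueError(f"rater {ai_rater!r} labels absent on some lesions")
    negative = labels.isin(NON_MALIGNANT_CLASSES)
    reviews_avoided = int(negative.groupby(frame["attendance_id"]).all().sum())
    f2f_avoided = int(
        (negative & frame["soc_management"].isin(F2F_MANAGEMENTS)).sum()
    )
    biopsies_avoided = int(
        (negative & frame["soc_management"].isin(BIOPSY_MANAGEMENTS)).sum()
    )
    return AvoidedActivity(
        reviews_avoided=reviews_avoided,
        f2f_avoided=f2f_avoided,
        biopsies_avoided=biopsies_avoided,
        pathway_patients=int(frame["attendance_id"].nunique()),
    )


def cost_impact(
    avoided: AvoidedActivity,
    params: CostParams = CostParams(),
    per_1000: bool = True,
) -> CostImpact:
    """Turn avoided-activity counts into money and specialist time."""
    review_saving = _money(params.review_cost * avoided.reviews_avoided)
    f2f_saving = _money(params.f2f_cost * avoided.f2f_avoided)
    biopsy_saving = _money(params.biopsy_cost * avoided.biopsies_avoided)
    total_saving = review_saving + f2f_saving + biopsy_saving
    review_minutes = params.review_minutes * avoided.reviews_avoided
    f2f_minutes = params.f2f_minutes * avoided.f2f_avoided
    biopsy_minutes = params.biopsy_minutes * avoided.biopsies_avoided
    total_minutes = review_minutes + f2f_minutes + biopsy_minutes

    per_1000_saving = per_1000_minutes = per_1000_hours = None
    if per_1000:
        if avoided.pathway_patients == 0:
            raise ValueError(
                "per-1000 extrapolation requires pathway_patients > 0"
            )
        scale = Decimal(1000) / Decimal(avoided.pathway_patients)
        per_1000_saving = _money(total_saving * scale)
        per_1000_minutes = total_minutes * 1000.0 / avoided.pathway_patients
        per_1000_hours = _round_half_up(per_1000_minutes / 60)

    return CostImpact(
        review_saving=review_saving,
        f2f_saving=f2f_saving,
        biopsy_saving=biopsy_saving,
        total_saving=total_saving,
        review_minutes=review_minutes,
        f2f_minutes=f2f_minutes,
        biopsy_minutes=biopsy_minutes,
        total_minutes=total_minutes,
        total_hours=_round_half_up(total_minutes / 60),
        per_1000_saving=per_1000_saving,
        per_1000_minutes=per_1000_minutes,
        per_1000_hours=per_1000_hours,
    )
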