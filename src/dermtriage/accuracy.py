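"""Diagnostic accuracy: confusion counts, proportion metrics with CIs,
and the number-needed-to-biopsy / number-needed-to-refer statistics.

All metrics are computed on the malignant vs premalignant/benign grouping:
a lesion is a case iff its final diagnosis is histology-confirmed MM, SCC
or BCC.  Lesions are treated as independent despite within-patient
clustering, matching the trial's own analysis; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .endpoints import (
    PositivityRule,
    positive_mask,
    truth_malignant_mask,
)
from .records import PREMALIGNANT_CLASSES

CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta", "wald": "normal"}


@dataclass(frozen=True)
class ConfusionCounts:
    """Lesion-level TP/FP/TN/FN under one rater and positivity rule."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_malignant(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Estimate:
    """A proportion with its confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "wilson"

    def pct(self, dp: int = 1) -> str:
        return (
            f"{100 * self.point:.{dp}f} "
            f"({100 * self.ci_low:.{dp}f}-{100 * self.ci_high:.{dp}f})"
        )


@dataclass(frozen=True)
class RatioEstimate:
    """Referred-per-event ratio (NNB/NNR) with an inverted proportion CI."""

    referred: int
    events: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def formatted(self, dp: int = 1) -> str:
        if math.isinf(self.point):
            return "inf"
        return f"{self.point:.{dp}f} ({self.ci_low:.{dp}f}-{self.ci_high:.{dp}f})"


def proportion_ci(
    k: int, n: int, method: str = "wilson", level: float = 0.95
) -> Tuple[float, float]:
    """Two-sided binomial CI for k successes in n trials."""
    if n <= 0:
        raise ValueError("proportion_ci requires n > 0")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=CI_METHODS[method])
    return max(0.0, float(lo)), min(1.0, float(hi))


def confusion_counts(frame: pd.DataFrame, rule: PositivityRule) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for one rater; counts partition the lesions."""
    truth = truth_malignant_mask(frame)
    pos = positive_mask(frame, rule)
    return ConfusionCounts(
        tp=int((truth & pos).sum()),
        fp=int((~truth & pos).sum()),
        tn=int((~truth & ~pos).sum()),
        fn=int((truth & ~pos).sum()),
    )


def _proportion_estimate(
    k: int, n: int, method: str, level: float, name: str
) -> Estimate:
    if n == 0:
        raise ZeroDivisionError(f"{name} undefined: zero denominator")
    lo, hi = proportion_ci(k, n, method=method, level=level)
    return Estimate(point=k / n, ci_low=lo, ci_high=hi, level=level, method=method)


def sensitivity(c: ConfusionCounts, method="wilson", level=0.95) -> Estimate:
    return _proportion_estimate(c.tp, c.tp + c.fn, method, level, "sensitivity")


def specificity(c: ConfusionCounts, method="wilson", level=0.95) -> Estimate:
    return _proportion_estimate(c.tn, c.tn + c.fp, method, level, "specificity")


def ppv(c: ConfusionCounts, method="wilson", level=0.95) -> Estimate:
    return _proportion_estimate(c.tp, c.tp + c.fp, method, level, "PPV")


def npv(c: ConfusionCounts, method="wilson", level=0.95) -> Estimate:
    return _proportion_estimate(c.tn, c.tn + c.fn, method, level, "NPV")


def fnr(c: ConfusionCounts, method="wilson", level=0.95) -> Estimate:
    e = _proportion_estimate(c.fn, c.tp + c.fn, method, level, "FNR")
    return e


def fpr(c: ConfusionCounts, method="wilson", level=0.95) -> Estimate:
    return _proportion_estimate(c.fp, c.tn + c.fp, method, level, "FPR")


def ratio_from_counts(
    referred: int, events: int, method="wilson", level=0.95
) -> RatioEstimate:
    """Referred/events with CI from inverting the events/referred CI.

    The CI for 1/p is taken as [1/p_high, 1/p_low].  Zero events signal an
    infinite ratio explicitly rather than raising.
    """
    if referred < events:
        raise ValueError("events cannot exceed referred lesions")
    if events == 0:
        return RatioEstimate(referred, 0, math.inf, math.inf, math.inf, level)
    lo, hi = proportion_ci(events, referred, method=method, level=level)
    ci_low = 1.0 / hi if hi > 0 else math.inf
    ci_high = 1.0 / lo if lo > 0 else math.inf
    return RatioEstimate(referred, events, referred / events, ci_low, ci_high, level)


def nnb(frame: pd.DataFrame, rule: PositivityRule, method="wilson") -> RatioEstimate:
    """Number needed to biopsy: referred lesions per malignancy found.

    For AI raters the referral set is the malignant-labelled lesions; for
    SoC it is the biopsy-referred lesions (rule scope decides).
    """
    pos = positive_mask(frame, rule)
    truth = truth_malignant_mask(frame)
    return ratio_from_counts(int(pos.sum()), int((pos & truth).sum()), method)


def nnr(frame: pd.DataFrame, rule: PositivityRule, method="wilson") -> RatioEstimate:
    """Number needed to refer per premalignancy (IEC or AK) found."""
    pos = positive_mask(frame, rule)
    premal = frame["final_dx"].isin(PREMALIGNANT_CLASSES).to_numpy(dtype=bool)
    return ratio_from_counts(int(pos.sum()), int((pos & premal).sum()), method)


_NNB_SCOPE = {"soc": "biopsy", "ai_a": "biopsy", "ai_b": "biopsy", "ai_rws": "biopsy"}


def accuracy_report(
    frame: pd.DataFrame,
    raters: Sequence[str] = ("soc", "ai_a", "ai_b", "ai_rws"),
    method: str = "wilson",
) -> pd.DataFrame:
    """One row per rater with the eight headline statistics.

    Numeric columns hold the raw values; ``*_fmt`` columns carry the
    1-decimal-place presentation.  A failing cell (zero denominator,
    absent labels) is reported as NaN without aborting the other cells.
    """
    rows = []
    for rater in raters:
        row: Dict[str, object] = {"rater": rater}
        try:
            c = confusion_counts(frame, PositivityRule(rater, "urgent_referral"))
            for name, fn_ in (
                ("sensitivity", sensitivity),
                ("specificity", specificity),
                ("ppv", ppv),
                ("npv", npv),
                ("fnr", fnr),
                ("fpr", fpr),
            ):
                try:
                    e = fn_(c, method=method)
                    row[name] = e.point
                    row[f"{name}_fmt"] = e.pct()
                except ZeroDivisionError:
                    row[name] = float("nan")
                    row[f"{name}_fmt"] = "NA"
            nnb_scope = "biopsy" if rater == "soc" else "urgent_referral"
            r_nnb = nnb(frame, PositivityRule(rater, nnb_scope), method)
            r_nnr = nnr(
                frame, PositivityRule(rater, "referral_incl_premalignant"), method
            )
            row["nnb"] = r_nnb.point
            row["nnb_fmt"] = r_nnb.formatted()
            row["nnr"] = r_nnr.point
            row["nnr_fmt"] = r_nnr.formatted()
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
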