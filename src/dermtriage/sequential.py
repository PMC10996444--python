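"""Two-stage adaptive group-sequential inference for the primary endpoint.

The primary endpoint compares the device's and the teledermatologist's
rates of correctly keeping premalignant/benign lesions off the urgent
pathway.  Each phase is analysed with a one-sided two-proportion z-test;
the phase-wise p-values are combined with the inverse-normal
(Lehmacher–Wassmer) rule using prespecified weights, and the combined
p-value is compared with an O'Brien–Fleming-adjusted final-look level.

The module also provides the surrounding design machinery: Lan–DeMets
O'Brien–Fleming-type alpha spending, boundary solving for two looks via
bivariate-normal integration, the normal-approximation non-inferiority
sample size, and conditional-power interim assessment with sample-size
reassessment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from . import study


@dataclass(frozen=True)
class DesignSpec:
    """The sequential design: levels, weights, margin, power, expectations.

    ``margin`` is the non-inferiority margin on the proportion scale used
    for the sample-size calculation; ``test_margin`` is the shift applied
    inside the per-phase test statistic (0 by default: pure superiority,
    the headline conclusion is insensitive to this choice).
    """

    overall_alpha: float = study.OVERALL_ALPHA_ONE_SIDED
    final_nominal_alpha: float = study.FINAL_NOMINAL_ALPHA
    information_fractions: Tuple[float, ...] = study.INFORMATION_FRACTIONS
    weights: Tuple[float, ...] = study.WEIGHTS
    margin: float = study.NI_MARGIN
    test_margin: float = 0.0
    power: float = study.DESIGN_POWER
    reassessment_power: float = study.REASSESSMENT_POWER
    futility_floor: float = 0.20
    expected_device_spec: float = study.EXPECTED_DEVICE_SPECIFICITY
    expected_prevalences: Tuple[Tuple[str, float], ...] = tuple(
        study.EXPECTED_PREVALENCES.items()
    )
    lesions_per_patient: float = study.LESIONS_PER_PATIENT
    dropout: float = study.DROPOUT
    planned_n_lesions: int = study.PLANNED_LESIONS

    def __post_init__(self):
        if not 0 < self.overall_alpha < 1 or not 0 < self.final_nominal_alpha < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        fr = self.information_fractions
        if any(b <= a for a, b in zip(fr, fr[1:])) or abs(fr[-1] - 1.0) > 1e-12:
            raise ValueError("information fractions must increase and end at 1")
        if any(w <= 0 for w in self.weights):
            raise ValueError("combination weights must be positive")
        if not 0 <= self.margin < 1:
            raise ValueError("margin must lie in [0, 1)")

    @property
    def malignant_prevalence(self) -> float:
        return sum(p for _, p in self.expected_prevalences)

    @property
    def planned_endpoint_n(self) -> int:
        """Planned non-malignant (endpoint) lesions."""
        return round(self.planned_n_lesions * (1 - self.malignant_prevalence))


@dataclass(frozen=True)
class ZResult:
    """One-sided two-proportion z-test (greater alternative)."""

    z: float
    p_one_sided: float
    p_a: float
    p_b: float
    k_a: int
    n_a: int
    k_b: int
    n_b: int
    margin: float
    variant: str


@dataclass(frozen=True)
class TrialResult:
    phase1: ZResult
    phase2: ZResult
    combined_z: float
    combined_p: float
    threshold: float
    decision: str  # "reject" | "fail_to_reject"


def two_proportion_z(
    k_a: int,
    n_a: int,
    k_b: int,
    n_b: int,
    margin: float = 0.0,
    variant: str = "pooled",
) -> ZResult:
    """z = (p_a - p_b + margin) / SE, one-sided p for p_a > p_b - margin."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both trial sizes must be positive")
    if variant not in ("pooled", "unpooled"):
        raise ValueError(f"unknown variant {variant!r}")
    p_a, p_b = k_a / n_a, k_b / n_b
    if variant == "pooled":
        p_bar = (k_a + k_b) / (n_a + n_b)
        se = math.sqrt(p_bar * (1 - p_bar) * (1 / n_a + 1 / n_b))
    else:
        se = math.sqrt(p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b)
    if se == 0:
        raise ValueError("degenerate variance: all successes or all failures")
    z = (p_a - p_b + margin) / se
    return ZResult(
        z=z,
        p_one_sided=float(stats.norm.sf(z)),
        p_a=p_a,
        p_b=p_b,
        k_a=k_a,
        n_a=n_a,
        k_b=k_b,
        n_b=n_b,
        margin=margin,
        variant=variant,
    )


def inverse_normal_combine(
    p_values: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted inverse-normal combination of stage-wise p-values.

    Combined z = sum(w_i * Phi^-1(1 - p_i)) / sqrt(sum(w_i^2)); the weight
    normalisation makes the statistic standard normal under the null, so
    the returned value 1 - Phi(z) is a valid combined p-value and is
    invariant to rescaling all weights by a positive constant.
    """
    return float(stats.norm.sf(combine_z(p_values, weights)))


def combine_z(p_values: Sequence[float], weights: Sequence[float]) -> float:
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("p_values and weights must have equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with at least one positive")
    z = stats.norm.isf(p)
    return float(np.dot(w, z) / math.sqrt(np.dot(w, w)))


def obf_spending(t: float, alpha: float) -> float:
    """Lan–DeMets O'Brien–Fleming-type cumulative alpha spent at fraction t.

    a(t) = 2 * (1 - Phi(Phi^-1(1 - alpha/2) / sqrt(t))); equals alpha at
    t = 1 and is increasing in t, heavily conservative early.
    """
    if t <= 0:
        raise ValueError("information fraction must be positive")
    t = min(t, 1.0)
    return float(2.0 * stats.norm.sf(stats.norm.isf(alpha / 2.0) / math.sqrt(t)))


def _bvn_cdf(a: float, b: float, rho: float) -> float:
    """P(Z1 < a, Z2 < b) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([a, b]))


def boundary_solve(
    fractions: Sequence[float],
    alpha: float,
    spending: Callable[[float, float], float] = obf_spending,
    tol: float = 1e-6,
) -> Tuple[float, ...]:
    """Per-look nominal one-sided levels matching a spending schedule.

    Successive look statistics have correlation sqrt(t_i / t_j); for two
    looks the final boundary is solved by bivariate-normal integration to
    absolute tolerance ``tol``.  The study had exactly two looks; more are
    out of scope.
    """
    fractions = tuple(float(t) for t in fractions)
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    if abs(fractions[-1] - 1.0) > 1e-12:
        raise ValueError("last information fraction must be 1")
    if len(fractions) == 1:
        return (alpha,)
    if len(fractions) > 2:
        raise NotImplementedError("only one interim look is supported")

    t1, _ = fractions
    a1 = spending(t1, alpha)
    z1 = float(stats.norm.isf(a1))
    rho = math.sqrt(t1)
    # P(Z1 >= z1) + P(Z1 < z1, Z2 >= z2) = alpha
    target = alpha - a1

    def residual(z2: float) -> float:
        crossed = stats.norm.cdf(z1) - _bvn_cdf(z1, z2, rho)
        return crossed - target

    sol = optimize.brentq(residual, 0.0, 8.0, xtol=tol)
    if abs(residual(sol)) > 10 * tol:
        raise RuntimeError(f"boundary solve did not converge: residual {residual(sol)}")
    return (a1, float(stats.norm.sf(sol)))


def crossing_probabilities(
    nominal_levels: Sequence[float], fractions: Sequence[float]
) -> Tuple[float, ...]:
    """Cumulative null crossing probabilities of a two-look boundary.

    Used to verify that solved boundaries reproduce their spending
    schedule.
    """
    if len(nominal_levels) == 1:
        return (float(nominal_levels[0]),)
    a1, a2 = nominal_levels
    t1 = fractions[0]
    z1, z2 = float(stats.norm.isf(a1)), float(stats.norm.isf(a2))
    rho = math.sqrt(t1)
    cum2 = a1 + (stats.norm.cdf(z1) - _bvn_cdf(z1, z2, rho))
    return (float(a1), float(cum2))


def required_sample_size_lesions(
    p_device: float,
    p_soc: float,
    margin: float,
    alpha_one_sided: float,
    power: float,
    variant: str = "pooled",
) -> int:
    """Per-group lesion count for a one-sided non-inferiority comparison.

    Normal approximation: n = (z_a + z_b)^2 * V / (p_device - p_soc +
    margin)^2 with V the (pooled or unpooled) Bernoulli variance sum,
    ceiling-rounded.
    """
    if not (0 < p_device < 1 and 0 < p_soc < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    effect = p_device - p_soc + margin
    if effect <= 0:
        raise ValueError("infeasible design: effect + margin must be positive")
    z_a = float(stats.norm.isf(alpha_one_sided))
    z_b = float(stats.norm.isf(1 - power))
    if variant == "pooled":
        p_bar = (p_device + p_soc) / 2
        v = 2 * p_bar * (1 - p_bar)
    elif variant == "unpooled":
        v = p_device * (1 - p_device) + p_soc * (1 - p_soc)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return math.ceil((z_a + z_b) ** 2 * v / effect**2)


def lesions_to_patients(
    n_lesions: int, lesions_per_patient: float, dropout: float
) -> int:
    """Convert a lesion sample size to recruited patients, inflating for dropout."""
    if lesions_per_patient <= 0:
        raise ValueError("lesions_per_patient must be positive")
    return round(n_lesions / lesions_per_patient * (1 + dropout))


@dataclass(frozen=True)
class InterimDecision:
    decision: str  # "continue" | "stop_futility"
    conditional_power: float
    updated_endpoint_n: Optional[int]  # total endpoint lesons per arm, both phases
    updated_n_lesions: Optional[int]
    updated_n_patients: Optional[int]


def interim_assessment(
    phase1_counts: Tuple[int, int, int, int], design: DesignSpec
) -> InterimDecision:
    """Futility check and sample-size reassessment at the interim look.

    ``phase1_counts`` is (k_device, n_device, k_soc, n_soc) of correct
    negatives.  Conditional power is evaluated under the observed effect:
    given the interim z, the final combined statistic rejects iff the
    phase-2 z exceeds a deterministic threshold, and the phase-2 z is
    approximately normal with mean (effect + test_margin)/SE(n2).
    Futility is declared when the conditional power at the planned
    phase-2 size falls below ``design.futility_floor``; otherwise the
    phase-2 size is re-solved for ``design.reassessment_power``.
    """
    k_d, n_d, k_s, n_s = phase1_counts
    z1 = two_proportion_z(k_d, n_d, k_s, n_s, design.test_margin).z
    p_d, p_s = k_d / n_d, k_s / n_s
    p_bar = (k_d + k_s) / (n_d + n_s)
    v = 2 * p_bar * (1 - p_bar)
    if v == 0:
        raise ValueError("zero-variance phase-1 data")
    effect = p_d - p_s + design.test_margin

    w1, w2 = design.weights
    norm_ = math.sqrt(w1**2 + w2**2)
    z_crit = float(stats.norm.isf(design.final_nominal_alpha))
    z2_required = (z_crit * norm_ - w1 * z1) / w2

    n2_planned = max(design.planned_endpoint_n - n_d, 1)
    mean_z2 = effect / math.sqrt(v / n2_planned)
    cp = float(stats.norm.sf(z2_required - mean_z2))
    if cp < design.futility_floor:
        return InterimDecision("stop_futility", cp, None, None, None)

    if effect <= 0:
        n2_new = n2_planned
    else:
        z_b = float(stats.norm.isf(1 - design.reassessment_power))
        n2_new = math.ceil((z2_required + z_b) ** 2 * v / effect**2)
    endpoint_total = n_d + n2_new
    n_lesions = math.ceil(endpoint_total / (1 - design.malignant_prevalence))
    n_patients = lesions_to_patients(
        n_lesions, design.lesions_per_patient, design.dropout
    )
    return InterimDecision("continue", cp, endpoint_total, n_lesions, n_patients)


def run_two_stage_from_counts(
    phase1_counts: Tuple[int, int, int, int],
    phase2_counts: Tuple[int, int, int, int],
    design: DesignSpec = DesignSpec(),
) -> TrialResult:
    """Two-stage combination test from per-phase correct-negative counts."""
    z_results = []
    for counts in (phase1_counts, phase2_counts):
        k_a, n_a, k_b, n_b = counts
        z_results.append(
            two_proportion_z(k_a, n_a, k_b, n_b, design.test_margin)
        )
    # combine on the z scale (identical to the inverse-normal rule on the
    # p scale, but robust when an extreme phase p underflows to 0 or 1)
    w = np.asarray(design.weights, dtype=float)
    zs = np.array([r.z for r in z_results])
    cz = float(np.dot(w, zs) / math.sqrt(np.dot(w, w)))
    cp = float(stats.norm.sf(cz))
    decision = "reject" if cp <= design.final_nominal_alpha else "fail_to_reject"
    return TrialResult(
        phase1=z_results[0],
        phase2=z_results[1],
        combined_z=cz,
        combined_p=cp,
        threshold=design.final_nominal_alpha,
        decision=decision,
    )


def run_two_stage_analysis(
    phase1_frame,
    phase2_frame,
    design: DesignSpec = DesignSpec(),
    rater: str = "ai_a",
) -> TrialResult:
    """Full primary analysis from lesion records.

    Builds correct-negative counts per phase for the device and for SoC,
    runs per-phase one-sided pooled z-tests, combines with the design
    weights, and compares to the final nominal level.
    """
    from .endpoints import correct_negative_counts

    if len(phase1_frame) == 0 or len(phase2_frame) == 0:
        raise ValueError("both phases must be non-empty")
    counts = []
    for frame in (phase1_frame, phase2_frame):
        k_dev, n = correct_negative_counts(frame, rater)
        k_soc, n_soc = correct_negative_counts(frame, "soc")
        assert n == n_soc
        counts.append((k_dev, n, k_soc, n_soc))
    return run_two_stage_from_counts(counts[0], counts[1], design)
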