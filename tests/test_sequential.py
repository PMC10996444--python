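"""Two-proportion tests, inverse-normal combination, spending boundaries,
sample size and interim reassessment."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from statsmodels.stats.proportion import proportions_ztest

from dermtriage.sequential import (
    DesignSpec,
    boundary_solve,
    combine_z,
    crossing_probabilities,
    interim_assessment,
    inverse_normal_combine,
    lesions_to_patients,
    obf_spending,
    required_sample_size_lesions,
    run_two_stage_analysis,
    run_two_stage_from_counts,
    two_proportion_z,
)

PHASE1 = (138, 178, 131, 178)
PHASE2 = (463, 544, 388, 544)


def z_oracle(k_a, n_a, k_b, n_b, margin=0.0):
    """Direct formula evaluation (pooled variance)."""
    pa, pb = k_a / n_a, k_b / n_b
    pbar = (k_a + k_b) / (n_a + n_b)
    se = math.sqrt(pbar * (1 - pbar) * (1 / n_a + 1 / n_b))
    return (pa - pb + margin) / se


class TestTwoProportionZ:
    def test_phase2_study_counts_match_oracle(self):
        res = two_proportion_z(*PHASE2)
        assert res.z == pytest.approx(z_oracle(*PHASE2), abs=1e-12)
        assert res.z == pytest.approx(5.51, abs=0.01)
        assert res.p_one_sided == pytest.approx(stats.norm.sf(res.z))

    def test_agrees_with_statsmodels(self):
        for counts in (PHASE1, PHASE2):
            k_a, n_a, k_b, n_b = counts
            stat, p = proportions_ztest(
                [k_a, k_b], [n_a, n_b], alternative="larger"
            )
            res = two_proportion_z(*counts)
            assert res.z == pytest.approx(stat, abs=1e-10)
            assert res.p_one_sided == pytest.approx(p, abs=1e-12)

    def test_equal_proportions_centre(self):
        res = two_proportion_z(50, 100, 50, 100)
        assert res.z == 0.0
        assert res.p_one_sided == pytest.approx(0.5)

    def test_margin_strictly_increases_z(self):
        base = two_proportion_z(*PHASE1, margin=0.0)
        shifted = two_proportion_z(*PHASE1, margin=0.01)
        assert shifted.z > base.z

    def test_unpooled_variant(self):
        res = two_proportion_z(*PHASE2, variant="unpooled")
        pa, pb = 463 / 544, 388 / 544
        se = math.sqrt(pa * (1 - pa) / 544 + pb * (1 - pb) / 544)
        assert res.z == pytest.approx((pa - pb) / se)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_proportion_z(10, 10, 10, 10)


class TestInverseNormalCombine:
    def test_null_centre(self):
        assert inverse_normal_combine([0.5, 0.5], [0.577, 0.82]) == pytest.approx(0.5)

    def test_degenerate_weight_returns_first_p(self):
        for p1 in (0.01, 0.3, 0.9):
            assert inverse_normal_combine([p1, 0.7], [2.5, 0.0]) == pytest.approx(p1)

    def test_weight_rescaling_invariance(self):
        ps = [0.04, 0.2]
        a = inverse_normal_combine(ps, [0.577, 0.82])
        b = inverse_normal_combine(ps, [5.77, 8.2])
        assert a == pytest.approx(b, rel=1e-12)

    def test_study_counts_cross_final_level(self):
        p1 = two_proportion_z(*PHASE1).p_one_sided
        p2 = two_proportion_z(*PHASE2).p_one_sided
        assert inverse_normal_combine([p1, p2], [0.577, 0.82]) <= 0.0246

    def test_monotone_in_each_phase_effect(self):
        base = inverse_normal_combine([0.2, 0.1], [0.577, 0.82])
        better1 = inverse_normal_combine([0.1, 0.1], [0.577, 0.82])
        better2 = inverse_normal_combine([0.2, 0.05], [0.577, 0.82])
        assert better1 < base and better2 < base

    def test_boundary_p_values_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_combine([0.0, 0.5], [1, 1])
        with pytest.raises(ValueError):
            inverse_normal_combine([0.5, 1.0], [1, 1])


class TestSpending:
    def test_full_information_spends_alpha(self):
        assert obf_spending(1.0, 0.025) == pytest.approx(0.025, abs=1e-12)

    def test_one_third_value(self):
        # direct evaluation: 2 * (1 - Phi(Phi^-1(1 - a/2) / sqrt(t)))
        expected = 2 * stats.norm.sf(stats.norm.isf(0.0125) / math.sqrt(1 / 3))
        got = obf_spending(1 / 3, 0.025)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.03e-4, rel=0.01)

    def test_monotone_on_grid(self):
        grid = np.linspace(0.05, 1.0, 20)
        values = [obf_spending(t, 0.025) for t in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            obf_spending(0.0, 0.025)


def bvn_upper_oracle(a, b, rho):
    """P(Z1 < a, Z2 < b) via 1-D quadrature, independent of mvn.cdf."""

    def integrand(x):
        return stats.norm.pdf(x) * stats.norm.cdf(
            (b - rho * x) / math.sqrt(1 - rho**2)
        )

    val, _ = integrate.quad(integrand, -10, a, epsabs=1e-12)
    return val


class TestBoundarySolve:
    def test_single_look_is_alpha(self):
        assert boundary_solve([1.0], 0.025) == (0.025,)

    def test_two_equal_looks_against_quadrature_oracle(self):
        a1, a2 = boundary_solve([0.5, 1.0], 0.025)
        # interim nominal level is the cumulative spend at t = 0.5
        assert a1 == pytest.approx(obf_spending(0.5, 0.025), abs=1e-12)
        assert a1 == pytest.approx(0.0015, abs=2e-4)
        # oracle: total crossing probability equals alpha
        z1, z2 = stats.norm.isf(a1), stats.norm.isf(a2)
        rho = math.sqrt(0.5)
        crossed = a1 + (stats.norm.cdf(z1) - bvn_upper_oracle(z1, z2, rho))
        assert crossed == pytest.approx(0.025, abs=1e-6)

    def test_study_configuration_final_level(self):
        a1, a2 = boundary_solve([1 / 3, 1.0], 0.025)
        assert 0.024 < a2 < 0.025
        cum = crossing_probabilities((a1, a2), (1 / 3, 1.0))
        assert cum[-1] == pytest.approx(0.025, abs=1e-6)

    def test_final_boundary_below_alpha(self):
        _, a2 = boundary_solve([0.5, 1.0], 0.025)
        assert a2 < 0.025


class TestSampleSize:
    def test_closed_form_example(self):
        # (z_a + z_b)^2 * 2 p (1-p) / delta^2 = 525.37 -> ceil 526
        z = stats.norm.isf(0.025) + stats.norm.isf(0.1)
        expected = math.ceil(z**2 * 2 * 0.5 * 0.5 / 0.1**2)
        assert required_sample_size_lesions(0.5, 0.5, 0.1, 0.025, 0.9) == expected
        assert expected == 526

    def test_monotone_in_power(self):
        lo = required_sample_size_lesions(0.66, 0.54, 0.01, 0.025, 0.8)
        hi = required_sample_size_lesions(0.66, 0.54, 0.01, 0.025, 0.99)
        assert hi > lo

    def test_monotone_in_margin(self):
        narrow = required_sample_size_lesions(0.66, 0.54, 0.01, 0.025, 0.99)
        wide = required_sample_size_lesions(0.66, 0.54, 0.05, 0.025, 0.99)
        assert wide < narrow

    def test_infeasible_design(self):
        with pytest.raises(ValueError, match="infeasible"):
            required_sample_size_lesions(0.5, 0.6, 0.05, 0.025, 0.9)

    @pytest.mark.parametrize(
        "n_lesions, lpp, dropout, expected",
        [(634, 1.2, 0.10, 581), (100, 1.0, 0.0, 100), (100, 2.0, 0.5, 75)],
    )
    def test_lesions_to_patients(self, n_lesions, lpp, dropout, expected):
        assert lesions_to_patients(n_lesions, lpp, dropout) == expected


class TestInterimAssessment:
    def test_null_effect_is_futile_with_high_floor(self):
        design = DesignSpec(futility_floor=0.5)
        decision = interim_assessment((120, 178, 120, 178), design)
        assert decision.decision == "stop_futility"

    def test_study_phase1_continues(self):
        decision = interim_assessment(PHASE1, DesignSpec())
        assert decision.decision == "continue"
        assert decision.conditional_power > 0.20

    def test_strong_effect_shrinks_required_n(self):
        design = DesignSpec()
        decision = interim_assessment((170, 178, 120, 178), design)
        assert decision.decision == "continue"
        assert decision.updated_endpoint_n <= design.planned_endpoint_n

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            interim_assessment((178, 178, 178, 178), DesignSpec())


class TestTwoStageAnalysis:
    def test_study_counts_reject(self):
        result = run_two_stage_from_counts(PHASE1, PHASE2)
        assert result.decision == "reject"
        assert result.combined_p <= 0.0246

    def test_record_level_matches_count_level(self, study_lesions):
        from_records = run_two_stage_analysis(
            study_lesions[study_lesions.phase == 1],
            study_lesions[study_lesions.phase == 2],
        )
        from_counts = run_two_stage_from_counts(PHASE1, PHASE2)
        assert from_records.combined_p == pytest.approx(from_counts.combined_p)

    def test_phase2_weight_zero_equals_phase1_test(self):
        design = DesignSpec(weights=(0.577, 1e-12))
        result = run_two_stage_from_counts(PHASE1, PHASE2, design)
        assert result.combined_p == pytest.approx(
            two_proportion_z(*PHASE1).p_one_sided, rel=1e-6
        )

    def test_empty_phase_rejected(self, study_lesions):
        with pytest.raises(ValueError):
            run_two_stage_analysis(
                study_lesions.iloc[0:0], study_lesions
            )

    def test_setting_b_also_rejects(self):
        result = run_two_stage_from_counts(
            (133, 178, 131, 178), (444, 544, 388, 544)
        )
        assert result.decision == "reject"
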