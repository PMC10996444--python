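"""Confusion counts, proportion metrics with CIs, NNB/NNR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dermtriage.accuracy import (
    ConfusionCounts,
    accuracy_report,
    confusion_counts,
    fnr,
    fpr,
    nnb,
    nnr,
    npv,
    ppv,
    proportion_ci,
    ratio_from_counts,
    sensitivity,
    specificity,
)
from dermtriage.endpoints import PositivityRule, positive_mask, truth_malignant_mask


def wilson_interval(k, n, level=0.95):
    """Independent evaluation of the Wilson score formula."""
    z = stats.norm.isf((1 - level) / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


class TestConfusionCounts:
    def test_study_device_a_counts(self, study_lesions):
        c = confusion_counts(study_lesions, PositivityRule("ai_a"))
        assert (c.tp, c.fp, c.tn, c.fn) == (61, 121, 601, 6)

    def test_partition_and_brute_force(self, study_lesions, rng):
        sample = study_lesions.sample(60, random_state=7)
        rule = PositivityRule("ai_rws")
        c = confusion_counts(sample, rule)
        # exhaustive per-record tally
        tp = fp = tn = fn = 0
        truth = truth_malignant_mask(sample)
        pos = positive_mask(sample, rule)
        for t, p in zip(truth, pos):
            if t and p:
                tp += 1
            elif t and not p:
                fn += 1
            elif not t and p:
                fp += 1
            else:
                tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.n == len(sample)

    def test_all_negative_rater_on_benign_set(self, study_lesions):
        benign = study_lesions[
            (study_lesions.final_dx == "BENIGN")
            & (study_lesions.ai_label_a == "BENIGN")
        ]
        c = confusion_counts(benign, PositivityRule("ai_a"))
        assert (c.tp, c.fp, c.fn) == (0, 0, 0)
        assert c.tn == len(benign)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_permutation_invariance(self, study_lesions):
        shuffled = study_lesions.sample(frac=1, random_state=3)
        c1 = confusion_counts(study_lesions, PositivityRule("soc"))
        c2 = confusion_counts(shuffled, PositivityRule("soc"))
        assert c1 == c2


class TestMetrics:
    def test_study_device_a_metrics(self):
        c = ConfusionCounts(tp=61, fp=121, tn=601, fn=6)
        assert round(100 * sensitivity(c).point, 1) == 91.0
        assert round(100 * specificity(c).point, 1) == 83.2
        assert round(100 * ppv(c).point, 1) == 33.5

    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=10, fp=0, tn=20, fn=0)
        for metric in (sensitivity, specificity, ppv, npv):
            assert metric(c).point == 1.0

    @settings(deadline=None, max_examples=50)
    @given(
        st.integers(0, 50), st.integers(0, 50),
        st.integers(0, 50), st.integers(0, 50),
    )
    def test_rate_complements(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fn > 0:
            assert fnr(c).point + sensitivity(c).point == pytest.approx(1.0)
        if tn + fp > 0:
            assert fpr(c).point + specificity(c).point == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        c = ConfusionCounts(tp=0, fp=0, tn=5, fn=0)
        with pytest.raises(ZeroDivisionError):
            sensitivity(c)


class TestProportionCI:
    def test_wilson_phase2_interval(self):
        lo, hi = proportion_ci(463, 544, method="wilson")
        exp_lo, exp_hi = wilson_interval(463, 544)
        assert lo == pytest.approx(exp_lo, abs=1e-10)
        assert hi == pytest.approx(exp_hi, abs=1e-10)
        assert (round(lo, 4), round(hi, 4)) == (0.8187, 0.8786)

    def test_k_zero_lower_bounds(self):
        lo_wald, _ = proportion_ci(0, 20, method="wald")
        assert lo_wald == 0.0
        for method in ("wilson", "clopper_pearson"):
            lo, _ = proportion_ci(0, 20, method=method)
            assert lo >= 0.0

    @pytest.mark.parametrize("method", ["wilson", "clopper_pearson"])
    @pytest.mark.parametrize("k,n", [(1, 10), (25, 50), (49, 50)])
    def test_interval_contains_point(self, method, k, n):
        lo, hi = proportion_ci(k, n, method=method)
        assert lo <= k / n <= hi

    def test_wilson_coverage_monte_carlo(self, rng):
        n, p, reps = 50, 0.2, 10_000
        ks = rng.binomial(n, p, size=reps)
        covered = 0
        for k in np.unique(ks):
            lo, hi = proportion_ci(int(k), n, method="wilson")
            if lo <= p <= hi:
                covered += int((ks == k).sum())
        assert covered / reps == pytest.approx(0.95, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 3)


class TestNNBAndNNR:
    @pytest.mark.parametrize(
        "referred, events, expected",
        [(216, 51, 4.2), (182, 61, 3.0), (268, 31, 8.6),
         (249, 55, 4.5), (300, 58, 5.2), (256, 63, 4.1), (10, 10, 1.0)],
    )
    def test_printed_ratios(self, referred, events, expected):
        est = ratio_from_counts(referred, events)
        assert round(est.point, 1) == expected

    def test_zero_events_signalled_as_infinite(self):
        est = ratio_from_counts(25, 0)
        assert math.isinf(est.point)

    def test_events_bounded_by_referred(self):
        with pytest.raises(ValueError):
            ratio_from_counts(5, 6)

    def test_study_nnb_from_records(self, study_lesions):
        soc = nnb(study_lesions, PositivityRule("soc", "biopsy"))
        dev = nnb(study_lesions, PositivityRule("ai_a", "urgent_referral"))
        assert (soc.referred, soc.events) == (216, 51)
        assert (dev.referred, dev.events) == (182, 61)

    def test_study_nnr_from_records(self, study_lesions):
        soc = nnr(study_lesions, PositivityRule("soc", "urgent_referral"))
        dev = nnr(
            study_lesions, PositivityRule("ai_a", "referral_incl_premalignant")
        )
        rws = nnr(
            study_lesions, PositivityRule("ai_rws", "referral_incl_premalignant")
        )
        assert (soc.referred, soc.events) == (268, 31)
        assert (dev.referred, dev.events) == (249, 55)
        assert (rws.referred, rws.events) == (300, 58)

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_nnb_is_reciprocal_ppv(self, data):
        referred = data.draw(st.integers(1, 500))
        events = data.draw(st.integers(1, referred))
        est = ratio_from_counts(referred, events)
        ppv_value = events / referred
        assert est.point == pytest.approx(1.0 / ppv_value)


class TestAccuracyReport:
    def test_study_table_shape_and_formatting(self, study_lesions):
        report = accuracy_report(study_lesions)
        assert list(report["rater"]) == ["soc", "ai_a", "ai_b", "ai_rws"]
        by_rater = report.set_index("rater")
        assert by_rater.loc["ai_a", "specificity_fmt"].startswith("83.2")
        assert by_rater.loc["ai_rws", "specificity_fmt"].startswith("73.3")
        assert by_rater.loc["soc", "nnb_fmt"].startswith("4.2")

    def test_empty_record_set(self, study_lesions):
        report = accuracy_report(study_lesions.iloc[0:0], raters=("soc",))
        assert len(report) == 1  # row present, metrics unavailable

    def test_single_rater(self, study_lesions):
        report = accuracy_report(study_lesions, raters=("ai_a",))
        assert len(report) == 1
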