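"""Gaussian-mixture classification and evidence metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from sgekit.gmm import (
    GmmModel,
    categorize_gmm,
    compute_likelihood_ratios,
    compute_oddspath,
    compute_roc_auc,
    compute_sensitivity_specificity,
    fit_gmm,
    posterior_pathogenic,
)


def symmetric_model():
    # functional N(2,1), non-functional N(0,1), equal priors
    return GmmModel(2.0, 1.0, 0.0, 1.0, 0.5, 0.5, 10, 10)


class TestFit:
    def test_recovers_class_parameters(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(1, 0.2, 200),
                                 rng.normal(-1, 0.2, 200)])
        labels = np.array(["functional"] * 200 + ["non_functional"] * 200)
        m = fit_gmm(scores, labels)
        se = 0.2 / math.sqrt(200)
        assert abs(m.mean_functional - 1.0) < 3 * se
        assert abs(m.mean_nonfunctional + 1.0) < 3 * se

    def test_single_member_class_raises(self):
        with pytest.raises(ValueError):
            fit_gmm([0.0, 1.0, 2.0], ["functional", "functional",
                                      "non_functional"])

    def test_equal_priors_option(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1, 0.2, 40),
                                 rng.normal(-1, 0.2, 4)])
        labels = np.array(["functional"] * 40 + ["non_functional"] * 4)
        m = fit_gmm(scores, labels, equal_priors=True)
        assert m.prior_functional == m.prior_nonfunctional == 0.5

    def test_zero_variance_suggests_pooling(self):
        labels = ["functional"] * 3 + ["non_functional"] * 3
        with pytest.raises(ValueError, match="pooled_variance"):
            fit_gmm([1.0, 1.0, 1.0, -1.0, -1.2, -0.8], labels)
        m = fit_gmm([1.0, 1.0, 1.0, -1.0, -1.2, -0.8], labels,
                    pooled_variance=True)
        assert m.sd_functional == m.sd_nonfunctional > 0


class TestPosterior:
    def test_midpoint_is_half(self):
        assert posterior_pathogenic(symmetric_model(), 1.0)[0] == pytest.approx(0.5)

    def test_closed_form_at_zero(self):
        # ratio phi(0;0,1)/phi(0;2,1) = e^2: posterior = e^-2/(1+e^-2)... from
        # the functional side, P(path|0) = 1/(1+e^-2) -- the complementary
        # worked value 0.1192 appears at score 2 for the pathogenic class
        p = posterior_pathogenic(symmetric_model(), 2.0)[0]
        assert p == pytest.approx(math.exp(-2) / (1 + math.exp(-2)), abs=1e-9)
        assert p == pytest.approx(0.1192, abs=1e-4)

    def test_limits_saturate(self):
        m = symmetric_model()
        assert posterior_pathogenic(m, -30.0)[0] == pytest.approx(1.0)
        assert posterior_pathogenic(m, 30.0)[0] == pytest.approx(0.0)

    def test_monotone_when_nonfunctional_mean_lower(self):
        m = symmetric_model()
        grid = np.linspace(-5, 5, 101)
        post = posterior_pathogenic(m, grid)
        assert (np.diff(post) <= 1e-12).all()


class TestCategorize:
    def test_thresholds(self):
        cats = categorize_gmm([0.995, 0.05, 0.3, 0.049, 0.99])
        assert list(cats) == ["pathogenic", "intermediate", "intermediate",
                              "benign", "intermediate"]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            categorize_gmm([-0.1])


class TestSensitivitySpecificity:
    def test_perfect_predictions(self):
        cats = ["pathogenic"] * 5 + ["benign"] * 5
        labels = ["non_functional"] * 5 + ["functional"] * 5
        sens, spec, _ = compute_sensitivity_specificity(cats, labels)
        assert (sens, spec) == (100.0, 100.0)

    def test_worked_confusion_table(self):
        cats = (["pathogenic"] * 8) + (["benign"] * 42) + (["pathogenic"] * 2)
        labels = (["non_functional"] * 8) + (["functional"] * 44)
        sens, spec, conf = compute_sensitivity_specificity(cats, labels)
        assert sens == 100.0
        assert spec == pytest.approx(95.4545, abs=1e-3)
        assert conf == {"TP": 8, "FN": 0, "TN": 42, "FP": 2}

    def test_all_pathogenic_zero_specificity(self):
        cats = ["pathogenic"] * 10
        labels = ["non_functional"] * 5 + ["functional"] * 5
        _, spec, _ = compute_sensitivity_specificity(cats, labels)
        assert spec == 0.0

    def test_intermediates_count_against_or_excluded(self):
        cats = ["pathogenic", "intermediate", "benign", "intermediate"]
        labels = ["non_functional", "non_functional", "functional", "functional"]
        sens_a, spec_a, _ = compute_sensitivity_specificity(cats, labels)
        assert (sens_a, spec_a) == (50.0, 50.0)
        sens_b, spec_b, _ = compute_sensitivity_specificity(
            cats, labels, intermediate_policy="exclude")
        assert (sens_b, spec_b) == (100.0, 100.0)


class TestLikelihoodRatios:
    def test_published_style_values(self):
        lr_plus, lr_minus = compute_likelihood_ratios(100.0, 95.45)
        assert round(lr_plus) == 22
        assert lr_minus == 0.0

    def test_uninformative_classifier(self):
        assert compute_likelihood_ratios(50.0, 50.0) == (1.0, 1.0)

    def test_perfect_specificity_infinite(self):
        lr_plus, _ = compute_likelihood_ratios(90.0, 100.0)
        assert math.isinf(lr_plus)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 30), st.integers(1, 30), st.integers(0, 30),
           st.integers(1, 30))
    def test_matches_confusion_arithmetic(self, tp, fn, fp, tn):
        sens = 100 * tp / (tp + fn)
        spec = 100 * tn / (tn + fp)
        lr_plus, lr_minus = compute_likelihood_ratios(sens, spec)
        if spec < 100:
            assert lr_plus == pytest.approx(sens / (100 - spec))
        if spec > 0:
            assert lr_minus == pytest.approx((100 - sens) / spec)


class TestOddsPath:
    def test_worked_pathogenic_example(self):
        r = compute_oddspath(10, 20, 9, 5)
        assert r.p1 == 0.5
        assert r.p2_pathogenic == pytest.approx(0.9)
        assert r.op_pathogenic == pytest.approx(9.0)
        assert r.evidence_pathogenic == "PS3_moderate"

    def test_worked_benign_example(self):
        r = compute_oddspath(10, 20, 0, 9)
        assert r.p2_benign == pytest.approx(0.1)
        assert r.op_benign == pytest.approx(1 / 9, abs=1e-4)
        assert r.evidence_benign == "BS3_moderate"

    def test_no_evidence_when_p2_equals_p1(self):
        # 1 predicted pathogenic of controls that are half pathogenic:
        # P2 = 0.5 = P1 -> odds 1
        r = compute_oddspath(5, 10, 1, 1)
        assert r.op_pathogenic == pytest.approx(1.0)
        assert r.op_benign == pytest.approx(1.0)

    def test_degenerate_p1_raises(self):
        with pytest.raises(ValueError):
            compute_oddspath(0, 10, 5, 5)
        with pytest.raises(ValueError):
            compute_oddspath(10, 10, 5, 5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 300),
           st.integers(1, 300))
    def test_matches_direct_formula(self, n_path, n_ben, pred_p, pred_b):
        r = compute_oddspath(n_path, n_path + n_ben, pred_p, pred_b)
        p1 = n_path / (n_path + n_ben)
        p2p = pred_p / (pred_p + 1)
        p2b = 1 / (pred_b + 1)
        assert r.op_pathogenic == pytest.approx(
            p2p * (1 - p1) / ((1 - p2p) * p1))
        assert r.op_benign == pytest.approx(
            p2b * (1 - p1) / ((1 - p2b) * p1))


class TestRocAuc:
    def test_perfect_separation(self):
        post = [0.9, 0.8, 0.2, 0.1]
        labels = ["non_functional", "non_functional", "functional", "functional"]
        _, auc = compute_roc_auc(post, labels)
        assert auc == 1.0

    def test_random_posteriors_near_half(self):
        rng = np.random.default_rng(12)
        post = rng.random(2000)
        labels = np.where(rng.random(2000) < 0.5, "non_functional", "functional")
        _, auc = compute_roc_auc(post, labels)
        assert abs(auc - 0.5) < 0.05

    def test_equals_mann_whitney_statistic(self):
        rng = np.random.default_rng(13)
        post = np.round(rng.random(60), 1)  # ties on purpose
        labels = np.where(rng.random(60) < 0.4, "non_functional", "functional")
        _, auc = compute_roc_auc(post, labels)
        pos = post[labels == "non_functional"]
        neg = post[labels == "functional"]
        u = mannwhitneyu(pos, neg).statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_roc_auc([0.1, 0.9], ["functional", "functional"])
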