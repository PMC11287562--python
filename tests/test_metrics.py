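"""Validation-metric tests: frozen hand-computed examples, brute-force
pair-enumeration oracles, independent library cross-checks and the
weighted/unweighted and monotone-transform invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

import brcaval as bv


def brute_auc(pred, outcome, weights):
    """O(n^2) pair enumeration: P(case outranks non-case), ties half."""
    num = den = 0.0
    for i in range(len(pred)):
        for j in range(len(pred)):
            if outcome[i] == 1 and outcome[j] == 0:
                wij = weights[i] * weights[j]
                den += wij
                if pred[i] > pred[j]:
                    num += wij
                elif pred[i] == pred[j]:
                    num += 0.5 * wij
    return num / den


def brute_c(pred, time, event, weights):
    """O(n^2) comparable-pair enumeration for Harrell's C."""
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                wij = weights[i] * weights[j]
                den += wij
                if pred[i] > pred[j]:
                    num += wij
                elif pred[i] == pred[j]:
                    num += 0.5 * wij
    return num / den


class TestExpectedObserved:
    def test_hand_arithmetic_unit_weights(self):
        r = bv.expected_observed_ratio([0.1, 0.2, 0.3], [0, 1, 1])
        assert (r.expected, r.observed) == (pytest.approx(0.6), 2.0)
        assert r.ratio == pytest.approx(0.3)

    def test_hand_arithmetic_weighted(self):
        r = bv.expected_observed_ratio([0.1, 0.2, 0.3], [0, 1, 1],
                                       [2, 1, 1])
        assert (r.expected, r.observed) == (pytest.approx(0.7), 2.0)
        assert r.ratio == pytest.approx(0.35)

    def test_perfect_predictions_ratio_one(self):
        y = [0, 1, 0, 1, 1]
        r = bv.expected_observed_ratio(y, y, [1.0, 2.0, 0.5, 3.0, 1.0])
        assert r.ratio == pytest.approx(1.0)

    def test_no_cases_raises(self):
        with pytest.raises(bv.DegenerateDataError):
            bv.expected_observed_ratio([0.1, 0.2], [0, 0])

    def test_ci_covers_under_self_consistency(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.3, size=20_000)
        y = rng.uniform(size=p.size) < p
        r = bv.expected_observed_ratio(p, y)
        assert r.ci[0] < 1.0 < r.ci[1]


class TestCalibrationSlope:
    def test_slope_one_under_self_consistency(self):
        rng = np.random.default_rng(1)
        p = 1 / (1 + np.exp(-rng.normal(-2.5, 1.0, size=50_000)))
        y = rng.uniform(size=p.size) < p
        slope, ci = bv.calibration_slope(p, y)
        se = (ci[1] - ci[0]) / (2 * 1.959964)
        assert abs(slope - 1.0) < 3 * se

    def test_overdispersed_predictions_give_half(self):
        # outcomes follow logit^-1(eta); predictions logit^-1(2 eta)
        rng = np.random.default_rng(2)
        eta = rng.normal(-2.0, 1.0, size=50_000)
        y = rng.uniform(size=eta.size) < 1 / (1 + np.exp(-eta))
        p = 1 / (1 + np.exp(-2 * eta))
        slope, ci = bv.calibration_slope(p, y)
        se = (ci[1] - ci[0]) / (2 * 1.959964)
        assert abs(slope - 0.5) < 3 * se

    def test_constant_predictions_raise(self):
        with pytest.raises(bv.DegenerateDataError):
            bv.calibration_slope([0.2, 0.2, 0.2], [0, 1, 0])


class TestQuintileCalibration:
    def test_bins_near_one_under_self_consistency(self):
        """Outcomes drawn from the predictions: every bin's E/O sits
        near 1 and the 95% CIs cover 1 in all but at most one bin (the
        joint all-bins coverage event itself only has ~0.95^5 ~ 77%
        probability, so a single marginal miss is within expectation)."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.4, size=50_000)
        y = rng.uniform(size=p.size) < p
        table = bv.quintile_calibration(p, y)
        assert table["eo_ratio"].between(0.9, 1.1).all()
        covers = (table["ci_low"] < 1.0) & (1.0 < table["ci_high"])
        assert covers.sum() >= 4

    def test_equal_sizes_with_unique_ranks(self):
        rng = np.random.default_rng(4)
        p = rng.permutation(np.linspace(0.01, 0.5, 103))
        y = rng.uniform(size=p.size) < p
        table = bv.quintile_calibration(p, y)
        assert table["n"].max() - table["n"].min() <= 1

    def test_expected_partition_conservation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 0.4, size=5_000)
        y = rng.uniform(size=p.size) < p
        w = rng.uniform(0.5, 3.0, size=p.size)
        table = bv.quintile_calibration(p, y, w)
        overall = bv.expected_observed_ratio(p, y, w)
        assert table["expected"].sum() == pytest.approx(
            overall.expected, abs=1e-9)
        assert table["observed"].sum() == pytest.approx(
            overall.observed, abs=1e-9)


class TestAuc:
    def test_perfect_separation(self):
        v, _ = bv.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=0)
        assert v == 1.0

    def test_all_ties_is_half(self):
        v, _ = bv.auc([0.3] * 6, [1, 0, 1, 0, 0, 1], n_boot=0)
        assert v == 0.5

    def test_four_point_example(self):
        v, _ = bv.auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0], n_boot=0)
        assert v == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(bv.DegenerateDataError):
            bv.auc([0.1, 0.2], [1, 1], n_boot=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        p = rng.choice([0.1, 0.2, 0.2, 0.5, 0.9], size=n)  # with ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            return
        w = rng.uniform(0.5, 3.0, size=n)
        v, _ = bv.auc(p, y, w, n_boot=0)
        assert v == pytest.approx(brute_auc(p, y, w), abs=1e-12)

    def test_matches_sklearn_weighted(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        y = rng.integers(0, 2, size=500)
        w = rng.uniform(0.5, 4.0, size=500)
        v, _ = bv.auc(p, y, w, n_boot=0)
        assert v == pytest.approx(roc_auc_score(y, p, sample_weight=w),
                                  abs=1e-10)


class TestHarrellC:
    def test_perfect_concordance(self):
        v, _ = bv.harrell_c([0.9, 0.5, 0.2], [1, 2, 3],
                            [True, True, True], n_groups=0)
        assert v == 1.0

    def test_worked_censored_example(self):
        # comparable pairs: (t=1 event vs t=2) discordant, (t=1 vs t=3)
        # concordant -> C = 0.5
        v, _ = bv.harrell_c([0.5, 0.4, 0.3], [2, 1, 3],
                            [False, True, True], n_groups=0)
        assert v == 0.5

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(bv.DegenerateDataError):
            bv.harrell_c([0.1, 0.2], [1.0, 2.0], [False, False],
                         n_groups=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 80)
        p = rng.choice([0.1, 0.2, 0.2, 0.5, 0.9], size=n)
        t = rng.choice([0.5, 1.0, 1.5, 2.0, 3.0, 5.0], size=n)  # time ties
        e = rng.uniform(size=n) < 0.5
        w = rng.uniform(0.5, 3.0, size=n)
        if not np.any(e[t < t.max()]):
            return
        v, _ = bv.harrell_c(p, t, e, w, n_groups=0)
        assert v == pytest.approx(brute_c(p, t, e, w), abs=1e-12)

    def test_matches_lifelines_unit_weights(self):
        rng = np.random.default_rng(7)
        n = 400
        p = rng.uniform(size=n)
        t = rng.uniform(0.1, 6.0, size=n)
        e = rng.uniform(size=n) < 0.3
        v, _ = bv.harrell_c(p, t, e, n_groups=0)
        # lifelines scores low-risk-long-life; pass -pred
        assert v == pytest.approx(concordance_index(t, -p, e), abs=1e-12)


class TestStratification:
    def test_threshold_proportions(self):
        out = bv.risk_stratification([0.01, 0.02, 0.04, 0.06],
                                     [0, 0, 0, 1])
        np.testing.assert_allclose(out["table"]["prop_below"],
                                   [0.25, 0.5, 0.75])

    def test_npv_one_without_cases(self):
        out = bv.risk_stratification([0.01, 0.02, 0.04, 0.06],
                                     [0, 0, 0, 0])
        np.testing.assert_allclose(out["table"]["npv"], 1.0)

    def test_empty_stratum_npv_undefined(self):
        out = bv.risk_stratification([0.5, 0.6, 0.7], [0, 1, 1])
        assert np.isnan(out["table"]["npv"]).all()
        np.testing.assert_allclose(out["table"]["prop_below"], 0.0)

    def test_top_half_capture(self):
        assert bv.top_fraction_capture([0.9, 0.8, 0.2, 0.1],
                                       [1, 1, 0, 0]) == 1.0

    def test_bad_thresholds_raise(self):
        with pytest.raises(bv.InvalidParameterError):
            bv.risk_stratification([0.1], [1], thresholds=(0.05, 0.03))


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(8)
    n = 300
    p = rng.uniform(0.01, 0.5, size=n)
    y = (rng.uniform(size=n) < p).astype(float)
    t = rng.uniform(0.2, 6.0, size=n)
    e = y.astype(bool)
    w = rng.uniform(0.5, 3.0, size=n)
    return p, y, t, e, w


class TestInvariances:

    def test_unit_weights_equal_unweighted(self, data):
        p, y, t, e, _ = data
        ones = np.ones_like(p)
        assert bv.expected_observed_ratio(p, y).ratio == pytest.approx(
            bv.expected_observed_ratio(p, y, ones).ratio, abs=1e-12)
        assert bv.auc(p, y, n_boot=0)[0] == pytest.approx(
            bv.auc(p, y, ones, n_boot=0)[0], abs=1e-12)
        assert bv.harrell_c(p, t, e, n_groups=0)[0] == pytest.approx(
            bv.harrell_c(p, t, e, ones, n_groups=0)[0], abs=1e-12)
        assert bv.top_fraction_capture(p, y) == pytest.approx(
            bv.top_fraction_capture(p, y, ones), abs=1e-12)

    def test_rank_metrics_invariant_under_monotone_transform(self, data):
        p, y, t, e, w = data
        q = np.sqrt(p) * 0.9  # strictly monotone into (0,1)
        assert bv.auc(q, y, w, n_boot=0)[0] == pytest.approx(
            bv.auc(p, y, w, n_boot=0)[0], abs=1e-12)
        assert bv.harrell_c(q, t, e, w, n_groups=0)[0] == pytest.approx(
            bv.harrell_c(p, t, e, w, n_groups=0)[0], abs=1e-12)
        assert bv.top_fraction_capture(q, y, w) == pytest.approx(
            bv.top_fraction_capture(p, y, w), abs=1e-12)

    def test_calibration_metrics_not_transform_invariant(self, data):
        p, y, _, _, w = data
        q = np.sqrt(p) * 0.9
        assert bv.expected_observed_ratio(q, y, w).ratio != pytest.approx(
            bv.expected_observed_ratio(p, y, w).ratio, rel=1e-3)
        assert bv.calibration_slope(q, y, w)[0] != pytest.approx(
            bv.calibration_slope(p, y, w)[0], rel=1e-3)
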