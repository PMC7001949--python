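import numpy as np
import pandas as pd
import pytest
from scipy import stats

from absrisk import (
    absolute_risk_calibration,
    auc,
    categorize_risk,
    fit_selection_model,
    observed_proportion_variance,
    relative_risk_calibration,
)
from absrisk.validation import COLUMNS


class TestCategorizeRisk:
    def test_uniform_weights_are_ordinary_deciles(self, rng):
        scores = rng.normal(0, 1, 1000)
        cats = categorize_risk(scores, 10, sampling_weights=np.ones(1000))
        plain = categorize_risk(scores, 10)
        np.testing.assert_array_equal(cats, plain)
        assert np.bincount(plain).tolist() == [100] * 10

    def test_single_category(self, rng):
        assert set(categorize_risk(rng.normal(0, 1, 20), 1)) == {0}

    def test_weights_match_row_duplication(self, rng):
        scores = rng.normal(0, 1, 200)
        pi = np.ones(200)
        pi[:40] = 0.5  # IPW weight 2 == duplicating those rows
        dup = np.concatenate([scores[:40], scores])
        a = categorize_risk(scores, 5, sampling_weights=pi)
        b = categorize_risk(dup, 5)
        np.testing.assert_array_equal(a, b[40:])

    def test_categories_ordered_by_score(self, rng):
        scores = rng.normal(0, 1, 500)
        cats = categorize_risk(scores, 4)
        means = [scores[cats == c].mean() for c in range(4)]
        assert means == sorted(means)


class TestObservedProportionVariance:
    def test_full_cohort_reduces_to_binomial(self):
        y = np.array([1.0] * 20 + [0.0] * 80)
        p, v = observed_proportion_variance(y)
        assert p == pytest.approx(0.2)
        assert v == pytest.approx(0.2 * 0.8 / 100, abs=1e-15)

    def test_half_sampling_hand_formula(self):
        # pi = 0.5 everywhere: correction term equals E[(Y-p)^2], so
        # Var = (p(1-p) + E[(Y-p)^2]) / (N Pr[c]) with N Pr[c] = sum(1/pi)
        y = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        pi = np.full(5, 0.5)
        p, v = observed_proportion_variance(y, pi)
        assert p == pytest.approx(0.4)
        mass = 10.0
        e_term = np.mean((y - 0.4) ** 2)
        assert v == pytest.approx((0.4 * 0.6 + e_term) / mass, abs=1e-15)

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            observed_proportion_variance(np.array([]))

    def test_weights_above_one_rejected(self):
        with pytest.raises(ValueError):
            observed_proportion_variance(np.array([1.0]), np.array([1.5]))


class TestAbsoluteRiskCalibration:
    def test_perfect_calibration_gives_zero_statistic(self):
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        cats = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.full(8, 0.5)
        res = absolute_risk_calibration(y, pred, cats)
        assert res.statistic == pytest.approx(0.0, abs=1e-14)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_two_category_hand_computation(self):
        # category A: 2/4 observed vs 0.4 predicted; B: 1/4 vs 0.3
        y = np.array([1, 1, 0, 0, 1, 0, 0, 0], dtype=float)
        cats = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0.4] * 4 + [0.3] * 4)
        res = absolute_risk_calibration(y, pred, cats)
        v_a = 0.5 * 0.5 / 4
        v_b = 0.25 * 0.75 / 4
        expected = (0.5 - 0.4) ** 2 / v_a + (0.25 - 0.3) ** 2 / v_b
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 2), abs=1e-12)

    def test_expected_observed_ratio_and_ci(self):
        y = np.array([1, 0, 0, 0] * 25, dtype=float)
        pred = np.full(100, 0.30)
        res = absolute_risk_calibration(y, pred, np.zeros(100, dtype=int))
        assert res.expected_by_observed == pytest.approx(0.3 / 0.25)
        assert res.eo_ci[0] < res.expected_by_observed < res.eo_ci[1]

    def test_degenerate_zero_variance_category(self):
        y = np.zeros(10)
        y[5:] = 1  # second category all cases -> zero variance there
        cats = np.array([0] * 5 + [1] * 5)
        pred = np.array([0.2] * 5 + [0.9] * 5)
        with pytest.raises(ValueError, match="zero variance"):
            absolute_risk_calibration(y, pred, cats)


class TestRelativeRiskCalibration:
    def test_perfect_relative_calibration(self):
        y = np.array([1, 0, 0, 0, 1, 1, 0, 0], dtype=float)  # 25% vs 50%
        cats = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0.1] * 4 + [0.2] * 4)  # same 1:2 ratio
        res = relative_risk_calibration(y, pred, cats)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_two_category_delta_method_hand_check(self):
        y = np.array([1, 1, 0, 0, 1, 0, 0, 0], dtype=float)
        cats = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0.4] * 4 + [0.1] * 4)
        res = relative_risk_calibration(y, pred, cats)
        p = np.array([0.5, 0.25])
        v = np.array([0.5 * 0.5 / 4, 0.25 * 0.75 / 4])
        mu = p.mean()
        J = np.eye(2) / mu - np.outer(p, np.ones(2)) / (2 * mu**2)
        sigma = J @ np.diag(v) @ J.T
        rr_o = p / (3 / 8)
        rr_e = pred.reshape(2, 4).mean(1) / 0.25
        d = (rr_o - rr_e)[:1]
        expected = float(d @ np.linalg.solve(sigma[:1, :1], d))
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_needs_two_categories(self):
        with pytest.raises(ValueError, match="2 categories"):
            relative_risk_calibration(
                np.array([1.0, 0.0]), np.array([0.5, 0.5]), np.zeros(2, dtype=int)
            )


class TestAuc:
    def test_perfect_separation(self):
        res = auc(np.array([3.0, 4.0]), np.array([1.0, 2.0]))
        assert res.auc == 1.0

    def test_enumerated_pairs(self):
        res = auc(np.array([1.0, 3.0]), np.array([2.0]))
        assert res.auc == pytest.approx(0.5)

    def test_ties_count_half(self):
        res = auc(np.array([1.0]), np.array([1.0, 0.0]))
        assert res.auc == pytest.approx(0.75)

    def test_unit_weights_match_unweighted(self, rng):
        r1 = rng.normal(0.5, 1, 60)
        r0 = rng.normal(0, 1, 140)
        a = auc(r1, r0)
        b = auc(r1, r0, np.ones(60), np.ones(140))
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-15)

    def test_integer_weights_match_duplication(self, rng):
        r1 = rng.normal(0.5, 1, 30)
        r0 = rng.normal(0, 1, 50)
        pi1 = np.ones(30)
        pi1[:10] = 0.5
        dup1 = np.concatenate([r1[:10], r1])
        a = auc(r1, r0, case_weights=pi1)
        b = auc(dup1, r0)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_score_reversal_maps_to_complement(self, rng):
        r1 = rng.normal(0.5, 1, 40)
        r0 = rng.normal(0, 1, 60)
        a = auc(r1, r0)
        b = auc(-r1, -r0)
        assert b.auc == pytest.approx(1 - a.auc, abs=1e-12)

    def test_all_tied_scores_degenerate(self):
        res = auc(np.ones(3), np.ones(5))
        assert res.auc == 0.5 and res.degenerate

    def test_needs_cases_and_controls(self):
        with pytest.raises(ValueError):
            auc(np.array([]), np.array([1.0]))


class TestSelectionModel:
    def test_intercept_only_inclusion_probability(self, rng):
        n = 30_000
        cohort = pd.DataFrame(
            {
                COLUMNS["outcome"]: np.zeros(n, dtype=int),
                COLUMNS["entry"]: rng.integers(50, 73, n),
                COLUMNS["exit"]: 0,
            }
        )
        cohort[COLUMNS["exit"]] = cohort[COLUMNS["entry"]] + rng.integers(5, 14, n)
        cohort[COLUMNS["inclusion"]] = (rng.random(n) < 0.1).astype(int)
        sel = fit_selection_model(cohort)
        fitted = sel.fitted
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(fitted.mean() - 0.1) < 3 * se

    def test_weights_indexing_contract(self, rng):
        n = 500
        cohort = pd.DataFrame(
            {
                COLUMNS["outcome"]: rng.integers(0, 2, n),
                COLUMNS["entry"]: rng.integers(50, 73, n),
            }
        )
        cohort[COLUMNS["exit"]] = cohort[COLUMNS["entry"]] + rng.integers(5, 14, n)
        cohort[COLUMNS["inclusion"]] = rng.integers(0, 2, n)
        sel = fit_selection_model(cohort)
        w = sel.weights_for_included(cohort[COLUMNS["inclusion"]].to_numpy())
        assert w.size == cohort[COLUMNS["inclusion"]].sum()
        np.testing.assert_array_equal(
            w, sel.fitted[cohort[COLUMNS["inclusion"]].to_numpy() == 1]
        )
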