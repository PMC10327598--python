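"""Kaplan–Meier, logistic and Cox factor recovery, and group-comparison tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rxpathways import (
    compare_groups,
    fit_duration_factors,
    fit_monotherapy_factors,
    km_estimate,
)
from rxpathways.outcome_stats import choose_categorical_test

from oracles import oracle_km


class TestKaplanMeier:
    def test_two_events_hand_curve(self):
        curve = km_estimate([5, 10], [True, True])
        assert curve.survival_at(0) == 1.0
        assert curve.survival_at(5) == pytest.approx(0.5)
        assert curve.survival_at(10) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3, 8, 12], [False, False, False])
        assert np.all(curve.survival == 1.0)
        assert curve.median is None

    def test_censoring_between_events(self):
        # events at 2 and 6, censor at 4: S = 1, 2/3, 2/3 * (1 - 1/1) = 0
        curve = km_estimate([2, 4, 6], [True, False, True])
        assert curve.survival_at(2) == pytest.approx(2 / 3)
        assert curve.survival_at(6) == pytest.approx(0.0)

    def test_tied_events_and_censorings(self):
        # convention: at a tied time, events occur before censorings
        durations = [5, 5, 5, 9]
        events = [True, False, True, True]
        curve = km_estimate(durations, events)
        assert curve.survival_at(5) == pytest.approx(oracle_km(durations, events, 5))
        assert curve.survival_at(9) == pytest.approx(oracle_km(durations, events, 9))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_product_limit_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            n = int(rng.integers(1, 50))
            durations = rng.integers(0, 15, size=n).tolist()  # heavy ties
            events = (rng.random(n) < 0.7).tolist()
            curve = km_estimate(durations, events)
            for t in range(16):
                assert curve.survival_at(t) == pytest.approx(oracle_km(durations, events, t))

    def test_exponential_limit(self):
        rng = np.random.default_rng(42)
        lam = 1 / 200.0
        durations = rng.exponential(1 / lam, size=4000)
        curve = km_estimate(durations, np.ones(4000, dtype=bool))
        grid = np.linspace(0, 800, 81)
        dev = max(abs(curve.survival_at(t) - np.exp(-lam * t)) for t in grid)
        assert dev <= 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def logistic_cohort(rng, n=2000, beta_x=np.log(2.0)):
    x = (rng.random(n) < 0.4).astype(float)
    age = rng.normal(70, 10, n)
    logit = -0.5 + beta_x * x + 0.03 * (age - 70)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return pd.DataFrame({"y": y, "x": x, "age": age})


class TestLogisticFactors:
    def test_recovers_known_odds_ratio(self):
        table = logistic_cohort(np.random.default_rng(0), n=4000)
        estimates = {e.variable: e for e in fit_monotherapy_factors(table, "y", ["x", "age"])}
        assert abs(np.log(estimates["x"].estimate) - np.log(2.0)) < 0.25
        assert estimates["x"].ci_low < estimates["x"].estimate < estimates["x"].ci_high

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(1)
        covered = 0
        for _ in range(40):
            table = logistic_cohort(rng, n=400, beta_x=0.0)
            est = {e.variable: e for e in fit_monotherapy_factors(table, "y", ["x", "age"])}["x"]
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered >= 33  # ~95% nominal; loose binomial bound at 40 reps

    def test_degenerate_outcome_rejected(self):
        table = pd.DataFrame({"y": [1, 1, 1], "x": [0, 1, 0]})
        with pytest.raises(ValueError):
            fit_monotherapy_factors(table, "y", ["x"])

    def test_separation_flagged_not_raised(self):
        table = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0.0] * 20 + [1.0] * 20})
        est = fit_monotherapy_factors(table, "y", ["x"])[0]
        assert est.flag != ""


class TestCoxFactors:
    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(2)
        n = 4000
        age = rng.normal(70, 10, n)
        beta = np.log(1.03)
        t = rng.exponential(1 / (0.002 * np.exp(beta * (age - 70))), n)
        censor_at = 1500.0
        table = pd.DataFrame(
            {"duration": np.minimum(t, censor_at), "event": (t <= censor_at).astype(int), "age": age}
        )
        est = fit_duration_factors(table, "duration", "event", ["age"])[0]
        assert abs(est.estimate - 1.03) < 0.02

    def test_no_events_rejected(self):
        table = pd.DataFrame({"duration": [5.0, 8.0], "event": [0, 0], "age": [60.0, 70.0]})
        with pytest.raises(ValueError):
            fit_duration_factors(table, "duration", "event", ["age"])

    def test_single_patient_rejected(self):
        table = pd.DataFrame({"duration": [5.0], "event": [1], "age": [60.0]})
        with pytest.raises(ValueError):
            fit_duration_factors(table, "duration", "event", ["age"])


class TestGroupComparisons:
    def test_identical_groups_rank_sum_null(self):
        table = pd.DataFrame({"v": list(range(10)) * 2, "g": ["a"] * 10 + ["b"] * 10})
        result = compare_groups(table, "v", "g", "continuous")
        assert result.test_name == "wilcoxon_rank_sum"
        assert result.p_value > 0.9

    def test_chi_square_selected_and_matches_textbook(self):
        # 2x2 table [[20,10],[10,20]]: all expected counts are 15
        table = pd.DataFrame(
            {
                "g": ["a"] * 30 + ["b"] * 30,
                "v": [0] * 20 + [1] * 10 + [0] * 10 + [1] * 20,
            }
        )
        result = compare_groups(table, "v", "g", "categorical")
        assert result.test_name == "chi_square"
        expected_stat, expected_p, _, _ = stats.chi2_contingency([[20, 10], [10, 20]])
        assert result.statistic == pytest.approx(expected_stat)
        assert result.p_value == pytest.approx(expected_p)

    def test_fisher_selected_for_small_expected_counts(self):
        table = pd.DataFrame({"g": ["a", "b"], "v": [0, 1]})
        result = compare_groups(table, "v", "g", "categorical")
        assert result.test_name == "fisher_exact"

    def test_selection_rule_is_pure_function_of_expected_counts(self):
        assert choose_categorical_test(np.array([[20, 10], [10, 20]])) == "chi_square"
        assert choose_categorical_test(np.array([[1, 0], [0, 1]])) == "fisher_exact"
        assert choose_categorical_test(np.array([[2, 8], [10, 2]])) == "fisher_exact"

    def test_constant_variable_diagnostic(self):
        table = pd.DataFrame({"v": [1.0] * 10, "g": ["a"] * 5 + ["b"] * 5})
        result = compare_groups(table, "v", "g", "continuous")
        assert result.note == "constant variable"

    def test_more_than_two_groups_rejected(self):
        table = pd.DataFrame({"v": [1, 2, 3], "g": ["a", "b", "c"]})
        with pytest.raises(ValueError):
            compare_groups(table, "v", "g", "continuous")
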