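import numpy as np
import pandas as pd
import pytest

from _oracles import breslow_partial_loglik, cox_grid_oracle
from conftest import survival_frame
from irsurv.errors import DataError, DegenerateInputError
from irsurv.survstats import cox_fit, greenwood_ci, km_estimate, reverse_analysis


class TestKaplanMeier:
    def test_five_patient_worked_example(self):
        # events at months 2 and 4 among 5 patients, no censoring
        curve = km_estimate([2.0, 4.0, 6.0, 7.0, 9.0], [1, 1, 0, 0, 0])
        assert curve.survival_at(2.0) == pytest.approx(0.8, abs=1e-15)
        assert curve.survival_at(4.0) == pytest.approx(0.6, abs=1e-15)
        assert curve.survival_at(1.0) == 1.0

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3.0, 6.0, 9.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_duplicating_cohort_leaves_curve_unchanged(self):
        times = [1.0, 3.0, 5.0, 8.0]
        events = [1, 0, 1, 1]
        single = km_estimate(times, events)
        double = km_estimate(times * 2, events * 2)
        np.testing.assert_allclose(single.survival, double.survival, atol=1e-15)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40)
        curve = km_estimate(times, np.ones(40, int))
        for t in curve.event_times:
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_censoring_at_event_time_stays_at_risk_through_it(self):
        # censored patient at t=2 is in the risk set for the t=2 event
        curve = km_estimate([2.0, 2.0, 5.0], [1, 0, 0])
        assert curve.at_risk[0] == 3
        assert curve.survival_at(2.0) == pytest.approx(2 / 3)

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        times = rng.exponential(12, 30) + 0.1
        events = rng.integers(0, 2, 30)
        curve = km_estimate(times, events)
        km = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(km.predict(t), abs=1e-10)


class TestGreenwoodBands:
    def test_band_is_degenerate_before_first_event(self):
        curve = greenwood_ci(km_estimate([2.0, 4.0, 6.0, 7.0, 9.0], [1, 1, 0, 0, 0]))
        # Ŝ = 1 never occurs at an event time here, but survival_at(<2) = 1
        # with the [1, 1] convention exercised through an event at Ŝ = 1:
        flat = greenwood_ci(km_estimate([5.0, 5.0], [0, 0]))
        assert flat.event_times.size == 0
        assert np.all((curve.ci_lower <= curve.survival + 1e-15))
        assert np.all((curve.ci_upper >= curve.survival - 1e-15))

    def test_worked_example_matches_closed_form(self):
        curve = greenwood_ci(km_estimate([2.0, 4.0, 6.0, 7.0, 9.0], [1, 1, 0, 0, 0]))
        z = 1.959963984540054
        c2 = 1 / (5 * 4)
        v2 = c2 / np.log(0.8) ** 2
        assert curve.ci_lower[0] == pytest.approx(0.8 ** np.exp(z * np.sqrt(v2)), abs=1e-12)
        assert curve.ci_upper[0] == pytest.approx(0.8 ** np.exp(-z * np.sqrt(v2)), abs=1e-12)
        c4 = c2 + 1 / (4 * 3)
        v4 = c4 / np.log(0.6) ** 2
        assert curve.ci_lower[1] == pytest.approx(0.6 ** np.exp(z * np.sqrt(v4)), abs=1e-12)
        assert curve.ci_upper[1] == pytest.approx(0.6 ** np.exp(-z * np.sqrt(v4)), abs=1e-12)
        assert 0 < curve.ci_lower[0] < 0.8 < curve.ci_upper[0] < 1

    def test_bands_stay_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            times = rng.exponential(15, n) + 0.05
            events = rng.integers(0, 2, n)
            curve = greenwood_ci(km_estimate(times, events))
            finite_lower = curve.ci_lower[np.isfinite(curve.ci_lower)]
            finite_upper = curve.ci_upper[np.isfinite(curve.ci_upper)]
            assert np.all(finite_lower >= 0) and np.all(finite_upper <= 1)

    def test_band_omitted_when_curve_reaches_zero(self):
        curve = greenwood_ci(km_estimate([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.isnan(curve.ci_lower[-1]) and np.isnan(curve.ci_upper[-1])

    def test_invalid_alpha_rejected(self):
        curve = km_estimate([1.0, 2.0], [1, 0])
        with pytest.raises(DataError):
            greenwood_ci(curve, alpha=1.5)


class TestCoxFit:
    def test_ten_patient_toy_matches_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.2, 0.8, 0.3, 0.9, -0.2, -0.5, -1.0, 0.1, -0.8, -1.5])
        fit = cox_fit(x, times, events)
        oracle_beta = cox_grid_oracle(x, times, events)
        assert fit.beta == pytest.approx(oracle_beta, abs=1e-4)
        # the returned beta is a maximum of the partial likelihood
        ll = breslow_partial_loglik(fit.beta, x, times, events)
        assert ll >= breslow_partial_loglik(fit.beta + 0.01, x, times, events)
        assert ll >= breslow_partial_loglik(fit.beta - 0.01, x, times, events)

    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 200)
        events = np.ones(200, int)
        x = rng.permutation(np.repeat([0.0, 1.0], 100))
        fit = cox_fit(x, times, events)
        assert abs(fit.beta) < 3 * fit.standard_error

    def test_binary_covariate_recovers_hazard_ratio_four(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 2, 500).astype(float)
        times = rng.exponential(1.0 / (0.02 * 4.0**x))
        fit = cox_fit(x, times, np.ones(500, int))
        assert 3.2 <= fit.hazard_ratio <= 5.0
        assert fit.ci_lower < fit.hazard_ratio < fit.ci_upper

    def test_agrees_with_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        times = rng.exponential(10, 80)
        events = rng.integers(0, 2, 80)
        events[0] = 1
        x = rng.normal(size=80)
        fit = cox_fit(x, times, events)
        frame = pd.DataFrame({"t": times, "e": events, "x": x})
        reference = CoxPHFitter().fit(frame, "t", "e")
        assert fit.beta == pytest.approx(reference.params_["x"], abs=1e-6)
        assert fit.standard_error == pytest.approx(reference.standard_errors_["x"], abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(DataError):
            cox_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 0])

    def test_perfect_separation_flagged_not_raised(self):
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit(x, times, events)
        assert fit.separated
        assert np.isfinite(fit.beta)


class TestReverseAnalysis:
    def scored_cohort(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        high = rng.random(n // 2) * 0.4 + 0.6
        low = rng.random(n - n // 2) * 0.4
        times = np.concatenate([rng.exponential(4, n // 2), rng.exponential(60, n - n // 2)]) + 0.2
        events = np.concatenate([np.ones(n // 2, int), rng.integers(0, 2, n - n // 2)])
        cohort = survival_frame(times, events)
        scores = pd.Series(np.concatenate([high, low]), index=cohort["patient_id"])
        return scores, cohort

    def test_ordered_scores_pick_top_scoring_high_group_at_oracle_maximum(self):
        from irsurv.stratify import logrank

        scores, cohort = self.scored_cohort(seed=5)
        result = reverse_analysis(scores, cohort, min_group_size=3)
        # the high group is always a contiguous top-score set …
        ordered = scores.sort_values(ascending=False)
        k = (result.groups == "high").sum()
        assert set(result.groups[result.groups == "high"].index) == set(ordered.index[:k])
        # … and the chosen threshold attains the exhaustive-enumeration maximum,
        # which is at least as large as the class-boundary split
        best = -np.inf
        s = scores.to_numpy()
        for threshold in (np.unique(s)[:-1] + np.unique(s)[1:]) / 2:
            high = s >= threshold
            if min(high.sum(), (~high).sum()) < 3:
                continue
            stat = logrank(
                cohort["time_months"], cohort["event"], np.where(high, "h", "l")
            ).statistic
            best = max(best, stat)
        assert result.logrank.statistic == pytest.approx(best, abs=1e-9)
        boundary = logrank(
            cohort["time_months"], cohort["event"], np.array(["h"] * 6 + ["l"] * 6)
        )
        assert result.logrank.statistic >= boundary.statistic - 1e-9

    def test_statistic_maximal_over_all_candidates(self):
        scores, cohort = self.scored_cohort(seed=6)
        scores = pd.Series(
            np.random.default_rng(7).permutation(scores.to_numpy()), index=scores.index
        )
        result = reverse_analysis(scores, cohort, min_group_size=3)
        admissible = result.candidate_profile.query("admissible")
        assert result.logrank.statistic == pytest.approx(admissible["statistic"].max())

    def test_km_curves_attached_with_bands(self):
        scores, cohort = self.scored_cohort(seed=8)
        result = reverse_analysis(scores, cohort, min_group_size=3)
        assert result.km_high.ci_lower is not None
        assert result.km_low.ci_lower is not None

    def test_identical_scores_degenerate(self):
        _, cohort = self.scored_cohort()
        scores = pd.Series(0.5, index=cohort["patient_id"])
        with pytest.raises(DegenerateInputError):
            reverse_analysis(scores, cohort, min_group_size=3)

    def test_unsatisfiable_group_size_degenerate(self):
        scores, cohort = self.scored_cohort(n=6)
        with pytest.raises(DegenerateInputError):
            reverse_analysis(scores, cohort, min_group_size=4)
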