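"""Growth-kinetics estimator: windows, candidates, medians, phase detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecophys.errors import (
    DuplicateTimesError,
    EmptyInputError,
    NonPositiveDensityError,
    TooFewPointsError,
)
from ecophys.growth import (
    CandidateRate,
    GrowthCurve,
    InstantRateSeries,
    SigmoidFit,
    WindowEstimate,
    compute_window_estimates,
    estimate_rate_series,
    exponential_phase_rates,
    fit_sigmoid_decay,
    generate_candidates,
    growth_envelope,
    median_rate_series,
    summarize_condition,
)


def ols_slope_se_oracle(t, y):
    """Closed-form least squares on 3 points, independent of scipy."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    tbar, ybar = t.mean(), y.mean()
    sxx = ((t - tbar) ** 2).sum()
    slope = ((t - tbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * tbar
    sse = ((y - (intercept + slope * t)) ** 2).sum()
    se = np.sqrt(sse / (len(t) - 2) / sxx)
    return slope, se, intercept


def make_curve(times, densities, **kw):
    kw.setdefault("strain_id", "s")
    kw.setdefault("replicate_id", "r")
    kw.setdefault("condition", {})
    return GrowthCurve(times=np.asarray(times, float), densities=np.asarray(densities, float), **kw)


class TestGrowthCurveValidation:
    def test_rejects_nonpositive_density(self):
        with pytest.raises(NonPositiveDensityError):
            make_curve([0, 1, 2], [100, 0, 400])

    def test_rejects_nonincreasing_times(self):
        with pytest.raises(DuplicateTimesError):
            make_curve([0, 1, 1], [100, 200, 400])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            make_curve([0, 1], [100, 200, 400])


class TestWindowEstimates:
    def test_exact_doubling_gives_unit_slope_zero_se(self):
        w = compute_window_estimates(make_curve([0, 1, 2], [1000, 2000, 4000]))[0]
        assert w.slope == pytest.approx(1.0, abs=1e-12)
        assert w.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_noisy_window_matches_frozen_ols_values(self):
        # log2 densities 10.0, 11.1, 11.9 at days 0, 1, 2
        curve = make_curve([0, 1, 2], 2.0 ** np.array([10.0, 11.1, 11.9]))
        w = compute_window_estimates(curve)[0]
        assert w.slope == pytest.approx(0.95, abs=1e-12)
        assert w.slope_se == pytest.approx(0.0866025403784, abs=1e-10)

    def test_five_point_curve_yields_three_windows(self):
        curve = make_curve(np.arange(5.0), 1000 * 2.0 ** np.arange(5.0))
        ws = compute_window_estimates(curve)
        assert [w.window_index for w in ws] == [0, 1, 2]

    def test_too_few_points_rejected(self):
        with pytest.raises(TooFewPointsError):
            compute_window_estimates(make_curve([0, 1], [100, 200]))

    def test_other_window_sizes_rejected(self):
        curve = make_curve(np.arange(5.0), 1000 * 2.0 ** np.arange(5.0))
        with pytest.raises(ValueError):
            compute_window_estimates(curve, window_size=4)

    @given(
        y=st.lists(st.floats(5.0, 25.0), min_size=3, max_size=3),
        t=st.lists(
            st.floats(0.0, 10.0).filter(lambda x: x == x), min_size=3, max_size=3, unique=True
        ),
    )
    @settings(max_examples=200)
    def test_ols_agrees_with_closed_form_oracle(self, y, t):
        t = sorted(t)
        curve = make_curve(t, 2.0 ** np.asarray(y))
        w = compute_window_estimates(curve)[0]
        slope, se, intercept = ols_slope_se_oracle(t, y)
        assert w.slope == pytest.approx(slope, abs=1e-9, rel=1e-9)
        assert w.slope_se == pytest.approx(se, abs=1e-9, rel=1e-9)

    def test_time_rescaling_rescales_rates(self):
        curve = make_curve([0, 1, 2, 3], [1000, 2100, 3900, 8200])
        scaled = make_curve([0, 2, 4, 6], [1000, 2100, 3900, 8200])
        for w, ws in zip(compute_window_estimates(curve), compute_window_estimates(scaled)):
            assert ws.slope == pytest.approx(w.slope / 2)
            assert ws.slope_se == pytest.approx(w.slope_se / 2)


class TestCandidates:
    def test_nine_candidates_three_rates_three_times(self):
        w = WindowEstimate(0, (0.0, 1.0, 2.0), slope=0.95, slope_se=0.0866025403784, intercept=10.05)
        cands = generate_candidates(w)
        assert len(cands) == 9
        assert sorted({round(c.rate, 5) for c in cands}) == [0.8634, 0.95, 1.0366]
        assert sorted({c.time for c in cands}) == [0.0, 1.0, 2.0]

    def test_zero_se_degenerates_to_single_rate(self):
        w = WindowEstimate(0, (0.0, 1.0, 2.0), slope=1.0, slope_se=0.0, intercept=10.0)
        cands = generate_candidates(w)
        assert len(cands) == 9
        assert {c.rate for c in cands} == {1.0}

    def test_candidate_count_scales_with_windows(self):
        curve = make_curve(np.arange(6.0), 1000 * 2.0 ** np.arange(6.0))
        series = estimate_rate_series(curve)
        assert len(series.candidates) == 9 * 4  # n - 2 windows
        assert series.times.size == 6  # every unique input time covered


class TestMedianSeries:
    def test_single_window_uniform_rate(self):
        w = WindowEstimate(0, (0.0, 1.0, 2.0), slope=1.0, slope_se=0.0, intercept=10.0)
        series = median_rate_series(generate_candidates(w))
        assert np.allclose(series.median_rates, 1.0)
        assert np.allclose(series.times, [0, 1, 2])

    def test_two_overlapping_windows_pool_candidates(self):
        w0 = WindowEstimate(0, (0.0, 1.0, 2.0), slope=1.0, slope_se=0.0, intercept=0.0)
        w1 = WindowEstimate(1, (1.0, 2.0, 3.0), slope=0.5, slope_se=0.0, intercept=0.0)
        series = median_rate_series(generate_candidates(w0) + generate_candidates(w1))
        expected = {0.0: 1.0, 1.0: 0.75, 2.0: 0.75, 3.0: 0.5}
        for t, r in zip(series.times, series.median_rates):
            assert r == pytest.approx(expected[t])

    def test_order_and_batching_invariance(self, rng):
        curve = make_curve(np.arange(7.0), 1000 * 2.0 ** (np.arange(7.0) + rng.normal(0, 0.1, 7)))
        cands = list(estimate_rate_series(curve).candidates)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        a = median_rate_series(cands)
        b = median_rate_series(shuffled)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.median_rates, b.median_rates)

    def test_empty_candidates_rejected(self):
        with pytest.raises(EmptyInputError):
            median_rate_series([])


class TestSigmoidDecay:
    @staticmethod
    def series(times, rates):
        return InstantRateSeries(np.asarray(times, float), np.asarray(rates, float), ())

    def test_recovers_generating_parameters(self):
        t = np.linspace(0, 6, 13)
        r_low, r_high, t_inflect, tau = 0.0, 2.0, 3.0, 0.5
        rates = r_low + (r_high - r_low) / (1 + np.exp((t - t_inflect) / tau))
        fit = fit_sigmoid_decay(self.series(t, rates))
        assert fit.converged
        assert fit.r_high == pytest.approx(r_high, rel=1e-6)
        assert fit.r_low == pytest.approx(r_low, abs=1e-6)
        assert fit.t_inflect == pytest.approx(t_inflect, rel=1e-6)
        assert fit.tau == pytest.approx(tau, rel=1e-6)

    def test_constant_series_does_not_converge(self):
        fit = fit_sigmoid_decay(self.series([0, 1, 2, 3, 4], [1.0] * 5))
        assert not fit.converged

    def test_increasing_series_does_not_converge(self):
        fit = fit_sigmoid_decay(self.series([0, 1, 2, 3, 4], [0.1, 0.5, 1.0, 1.5, 2.0]))
        assert not fit.converged

    def test_short_series_does_not_converge(self):
        fit = fit_sigmoid_decay(self.series([0, 1, 2], [2.0, 1.0, 0.1]))
        assert not fit.converged


class TestExponentialPhaseSelection:
    @staticmethod
    def series(times, rates):
        return InstantRateSeries(np.asarray(times, float), np.asarray(rates, float), ())

    @staticmethod
    def fit(t_inflect, converged=True):
        return SigmoidFit(2.0, 0.0, t_inflect, 0.5, converged, 0.0)

    def test_converged_fit_keeps_strictly_pre_inflection(self):
        s = self.series([0, 1, 2, 3, 4, 5], [2, 2, 2, 1, 0.2, 0.1])
        chosen = exponential_phase_rates(s, self.fit(3.0))
        assert [t for t, _ in chosen] == [0, 1, 2]

    def test_failed_fit_takes_top_three_absolute(self):
        s = self.series([0, 1, 2, 3, 4], [0.2, 1.5, 1.4, 0.1, -0.3])
        chosen = exponential_phase_rates(s, self.fit(np.nan, converged=False))
        assert sorted(r for _, r in chosen) == pytest.approx([-0.3, 1.4, 1.5])

    def test_equal_magnitudes_break_ties_by_earlier_time(self):
        s = self.series([0, 1, 2, 3], [1.0, -1.0, 1.0, -1.0])
        chosen = exponential_phase_rates(s, self.fit(np.nan, converged=False))
        assert [t for t, _ in chosen] == [0, 1, 2]

    def test_inflection_before_first_time_falls_back(self):
        s = self.series([0, 1, 2, 3, 4], [0.2, 1.5, 1.4, 0.1, -0.3])
        chosen = exponential_phase_rates(s, self.fit(-1.0))
        assert sorted(r for _, r in chosen) == pytest.approx([-0.3, 1.4, 1.5])

    def test_short_series_returns_everything(self):
        s = self.series([0, 1], [0.5, 0.4])
        chosen = exponential_phase_rates(s, self.fit(np.nan, converged=False))
        assert len(chosen) == 2


class TestConditionSummary:
    def test_noise_free_exponential_recovers_rate_exactly(self, exact_doubling_curve):
        summ = summarize_condition([exact_doubling_curve])
        assert summ.representative_rate == pytest.approx(1.0, abs=1e-9)
        assert summ.rate_dispersion == pytest.approx(0.0, abs=1e-9)
        assert summ.growth_call
        assert summ.fold_increase == pytest.approx(64.0)

    def test_flat_curves_are_called_no_growth(self):
        flat = make_curve(np.arange(6.0), np.full(6, 5e4))
        summ = summarize_condition([flat])
        assert summ.representative_rate == pytest.approx(0.0, abs=1e-12)
        assert not summ.growth_call

    def test_pooled_median_across_replicates(self, monkeypatch):
        # median of pooled exponential-phase rates {1.0, 1.2, 1.1, 0.9} = 1.05
        import ecophys.growth as gk

        pools = iter([((0.0, 1.0), (1.0, 1.2)), ((0.0, 1.1), (1.0, 0.9))])
        monkeypatch.setattr(gk, "exponential_phase_rates", lambda s, f: next(pools))
        c1 = make_curve([0, 1, 2, 3], [1e3, 2e3, 4e3, 8e3])
        c2 = make_curve([0, 1, 2, 3], [1e3, 2.1e3, 4.2e3, 8.1e3])
        summ = gk.summarize_condition([c1, c2])
        assert summ.representative_rate == pytest.approx(1.05)

    def test_empty_replicates_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_condition([])


class TestGrowthEnvelope:
    @staticmethod
    def summary(value, rate, call, variable="temperature_C"):
        from ecophys.growth import ConditionSummary

        return ConditionSummary(
            condition={variable: value},
            exp_phase_rates=((0.0, rate),),
            representative_rate=rate,
            mean_rate=rate,
            rate_dispersion=0.0,
            rate_range=(rate, rate),
            max_density=1e6,
            fold_increase=16.0 if call else 1.0,
            growth_call=call,
        )

    def test_permissive_range_spans_growth_positive_values(self):
        summaries = [
            self.summary(12, 0.0, False),
            self.summary(16, 0.8, True),
            self.summary(20, 1.5, True),
            self.summary(25, 1.0, True),
            self.summary(28.5, 0.0, False),
        ]
        env = growth_envelope(summaries, "temperature_C")
        assert env.permissive_range == (16, 25)
        assert env.max_rate == pytest.approx(1.5)
        assert env.max_rate_condition["temperature_C"] == 20
        assert env.non_permissive_values == (12, 28.5)

    def test_single_positive_condition(self):
        env = growth_envelope([self.summary(20, 1.0, True)], "temperature_C")
        assert env.permissive_range == (20, 20)

    def test_all_negative_is_flagged_not_raised(self):
        env = growth_envelope([self.summary(4, 0.0, False)], "temperature_C")
        assert not env.has_growth
        assert env.permissive_range is None
        assert np.isnan(env.max_rate)
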