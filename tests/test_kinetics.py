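import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from particokin.kinetics import (LN2, FitConfig, IdentifiabilityError,
                                 OnePhaseClearance, RetentionSeries,
                                 TwoPhaseClearance, exact_constrained_solve,
                                 fit_one_phase, fit_two_phase,
                                 fraction_cleared_by, half_time,
                                 predict_retention, select_model)


class TestHalfTime:
    def test_ln2_rate_gives_one_day(self):
        assert half_time(LN2) == pytest.approx(1.0)

    def test_inverse_of_published_gold_half_time(self):
        assert half_time(0.008504) == pytest.approx(81.5, rel=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(lam=st.floats(1e-4, 10.0))
    def test_scaling_and_identity(self, lam):
        assert half_time(2 * lam) == pytest.approx(half_time(lam) / 2)
        assert half_time(lam) * lam == pytest.approx(LN2)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_time(0.0)


class TestPredictRetention:
    def test_unit_at_baseline(self):
        fit = TwoPhaseClearance.from_parameters(0.3, 0.5, 0.01)
        assert predict_retention(fit, 0.0) == pytest.approx(1.0)

    def test_published_silver_parameters_reproduce_measured_points(self):
        # single-Ag fit: 1/3 fast (T1/2 3.1 d), 2/3 slow (T1/2 48.5 d)
        fit = TwoPhaseClearance.from_parameters(1 / 3, LN2 / 3.1, LN2 / 48.5)
        assert predict_retention(fit, 6.0) == pytest.approx(0.699, abs=5e-4)
        assert predict_retention(fit, 27.0) == pytest.approx(0.454, abs=5e-4)

    def test_negative_time_rejected(self):
        fit = OnePhaseClearance.from_parameters(0.1)
        with pytest.raises(ValueError):
            predict_retention(fit, -1.0)

    def test_strictly_decreasing_and_bounded(self):
        fit = TwoPhaseClearance.from_parameters(0.4, 0.3, 0.01)
        t = np.linspace(0, 100, 200)
        y = predict_retention(fit, t)
        assert np.all(np.diff(y) < 0)
        assert np.all((y > 0) & (y <= 1))


class TestOnePhase:
    def test_exact_on_noiseless_model(self):
        t = np.array([0.0, 6.0, 27.0])
        fit = OnePhaseClearance().fit(t, np.exp(-0.1 * t))
        assert fit.lambda1_ == pytest.approx(0.1, rel=1e-12)
        assert fit.p1_ == pytest.approx(1.0, rel=1e-12)

    def test_gold_single_exposure_half_time(self, au_single_retention):
        t, y = au_single_retention
        fit = OnePhaseClearance(amplitude="free", objective_scale="log")
        fit.fit(t, y)
        # closed-form log-linear slope; published value 81.5 d
        assert fit.half_time_ == pytest.approx(83.1, abs=0.1)
        assert fit.half_time_ == pytest.approx(81.5, rel=0.10)

    def test_gold_co_exposure_half_time(self, au_co_retention):
        t, y = au_co_retention
        fit = OnePhaseClearance().fit(t, y)
        assert fit.half_time_ == pytest.approx(51.3, abs=0.1)
        assert fit.half_time_ == pytest.approx(54.2, rel=0.10)

    def test_log_fit_matches_independent_polyfit(self, au_co_retention):
        t, y = au_co_retention
        slope = np.polyfit(t, np.log(y), 1)[0]
        fit = OnePhaseClearance().fit(t, y)
        assert fit.lambda1_ == pytest.approx(-slope, rel=1e-12)

    def test_linear_scale_objective(self):
        t = np.array([0.0, 3.0, 9.0, 20.0])
        y = 0.95 * np.exp(-0.05 * t)
        fit = OnePhaseClearance(objective_scale="linear").fit(t, y)
        assert fit.lambda1_ == pytest.approx(0.05, rel=1e-6)
        assert fit.p1_ == pytest.approx(0.95, rel=1e-6)

    def test_increasing_series_fails_with_diagnosis(self):
        from particokin.kinetics import FitFailureError
        with pytest.raises(FitFailureError):
            OnePhaseClearance().fit([0.0, 5.0, 10.0], [1.0, 1.2, 1.5])


class TestTwoPhase:
    def test_recovers_noiseless_parameters_free_fraction(self):
        t = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 40.0])
        y = 0.4 * np.exp(-0.3 * t) + 0.6 * np.exp(-0.01 * t)
        fit = TwoPhaseClearance().fit(t, y)
        assert fit.p1_ == pytest.approx(0.4, rel=1e-6)
        assert fit.lambda_fast_ == pytest.approx(0.3, rel=1e-6)
        assert fit.lambda_slow_ == pytest.approx(0.01, rel=1e-6)

    def test_silver_single_constrained(self, ag_single_retention):
        t, y = ag_single_retention
        fit = TwoPhaseClearance(fast_fraction=1 / 3).fit(t, y)
        # published: fast 3.1 d, slow 48.5 d
        assert fit.half_time_fast_ == pytest.approx(3.1, rel=0.10)
        assert fit.half_time_slow_ == pytest.approx(48.5, rel=0.10)

    def test_silver_co_constrained(self, ag_co_retention):
        t, y = ag_co_retention
        fit = TwoPhaseClearance(fast_fraction=0.5).fit(t, y)
        assert fit.half_time_fast_ == pytest.approx(2.2, rel=0.15)
        assert fit.half_time_slow_ == pytest.approx(28.4, rel=0.15)

    def test_three_points_free_fraction_unidentifiable(self,
                                                       ag_single_retention):
        t, y = ag_single_retention
        with pytest.raises(IdentifiabilityError, match="fraction"):
            TwoPhaseClearance().fit(t, y)

    def test_fast_slow_ordering_enforced(self):
        t = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 40.0])
        y = 0.6 * np.exp(-0.01 * t) + 0.4 * np.exp(-0.3 * t)
        fit = TwoPhaseClearance(seed=3).fit(t, y)
        assert fit.lambda_fast_ >= fit.lambda_slow_
        assert fit.p1_ + fit.p2_ == pytest.approx(1.0)

    def test_deterministic_given_seed(self, ag_single_retention):
        t, y = ag_single_retention
        a = TwoPhaseClearance(fast_fraction=1 / 3, seed=5).fit(t, y)
        b = TwoPhaseClearance(fast_fraction=1 / 3, seed=5).fit(t, y)
        assert a.lambda_fast_ == b.lambda_fast_
        assert a.lambda_slow_ == b.lambda_slow_

    def test_sklearn_get_set_params_roundtrip(self):
        est = TwoPhaseClearance(fast_fraction=0.25, seed=9)
        params = est.get_params()
        clone = TwoPhaseClearance().set_params(**params)
        assert clone.get_params() == params


class TestExactConstrainedSolve:
    def test_round_trip_from_known_parameters(self):
        p, l1, l2 = 0.35, 0.4, 0.02
        t = np.array([0.0, 6.0, 27.0])
        y = p * np.exp(-l1 * t) + (1 - p) * np.exp(-l2 * t)
        fit = exact_constrained_solve(t, y, p)
        assert fit.lambda_fast_ == pytest.approx(l1, abs=1e-10)
        assert fit.lambda_slow_ == pytest.approx(l2, abs=1e-10)

    def test_matches_least_squares_on_silver_case(self, ag_single_retention):
        t, y = ag_single_retention
        exact = exact_constrained_solve(t, y, 1 / 3)
        ls = TwoPhaseClearance(fast_fraction=1 / 3).fit(t, y)
        assert ls.lambda_fast_ == pytest.approx(exact.lambda_fast_, rel=1e-6)
        assert ls.lambda_slow_ == pytest.approx(exact.lambda_slow_, rel=1e-6)

    def test_degenerate_equal_rates(self):
        lam = 0.05
        t = np.array([0.0, 6.0, 27.0])
        y = np.exp(-lam * t)
        # generating model has lambda1 == lambda2: solution collapses to the
        # boundary of the bracket
        fit = exact_constrained_solve(t, y, 0.5)
        assert fit.lambda_fast_ == pytest.approx(lam, rel=1e-4)
        assert fit.lambda_slow_ == pytest.approx(lam, rel=1e-4)

    def test_non_declining_values_rejected(self):
        with pytest.raises(ValueError):
            exact_constrained_solve([0, 6, 27], [1.0, 1.1, 0.9], 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.1, 0.9),
           l2=st.floats(5e-3, 0.05),
           ratio=st.floats(3.0, 50.0))
    def test_oracle_equivalence_random_problems(self, p, l2, ratio):
        # least-squares path and bracketing solver must agree on any valid
        # 3-point constrained problem
        l1 = l2 * ratio
        t = np.array([0.0, 6.0, 27.0])
        y = p * np.exp(-l1 * t) + (1 - p) * np.exp(-l2 * t)
        exact = exact_constrained_solve(t, y, p)
        ls = TwoPhaseClearance(fast_fraction=p).fit(t, y)
        assert ls.lambda_fast_ == pytest.approx(exact.lambda_fast_, rel=1e-6)
        assert ls.lambda_slow_ == pytest.approx(exact.lambda_slow_, rel=1e-6)


class TestFractionCleared:
    def test_zero_at_time_zero(self):
        fit = OnePhaseClearance.from_parameters(0.1)
        assert fraction_cleared_by(fit, 0.0) == pytest.approx(0.0)

    def test_published_co_silver_parameters_within_reported_interval(self):
        fit = TwoPhaseClearance.from_parameters(0.5, LN2 / 2.2, LN2 / 28.4)
        cleared = fraction_cleared_by(fit, 5.0)
        assert 34.0 <= cleared <= 49.0
        assert cleared == pytest.approx(45.4, abs=0.1)

    def test_slow_gold_clearance_small_at_five_days(self):
        fit = OnePhaseClearance.from_parameters(LN2 / 81.5)
        assert fraction_cleared_by(fit, 5.0) == pytest.approx(4.2, abs=0.1)


class TestModelSelection:
    def _fits(self, t, y, fraction=None):
        one = OnePhaseClearance().fit(t, y)
        two = TwoPhaseClearance(fast_fraction=fraction).fit(t, y)
        return one, two

    def test_one_phase_preferred_on_monoexponential_data(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 40, 9)
        y = np.exp(-0.05 * t) * np.exp(rng.normal(0, 0.01, t.size))
        y[0] = 1.0
        one, two = self._fits(t, y)
        sel = select_model(one, two)
        assert sel.aicc_choice == "one-phase"

    def test_two_phase_preferred_on_well_separated_biexponential(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 40, 9)
        y = 0.4 * np.exp(-0.5 * t) + 0.6 * np.exp(-0.01 * t)
        y *= np.exp(rng.normal(0, 0.01, t.size))
        y[0] = 1.0
        one, two = self._fits(t, y)
        sel = select_model(one, two)
        assert sel.aicc_choice == "two-phase"

    def test_three_point_series_requires_a_priori(self, ag_single_retention):
        t, y = ag_single_retention
        one, two = self._fits(t, y, fraction=1 / 3)
        with pytest.raises(IdentifiabilityError):
            select_model(one, two)
        sel = select_model(one, two, a_priori="two-phase")
        assert sel.chosen == "two-phase"
        assert not sel.aicc_reliable


class TestSeriesAndConfig:
    def test_series_validation(self):
        with pytest.raises(ValueError):
            RetentionSeries(times=(0.0, 6.0), values=(0.9, 0.5))  # y0 != 1
        with pytest.raises(ValueError):
            RetentionSeries(times=(1.0, 6.0), values=(1.0, 0.5))  # t0 != 0
        s = RetentionSeries(times=(0.0, 6.0, 27.0),
                            values=(1.0, 0.7, 0.4), analyte="Ag")
        assert s.t[0] == 0.0

    def test_mass_scale_rescaling_invariance_free_amplitude(self):
        t = np.array([0.0, 6.0, 27.0])
        m = 8930 * np.exp(-0.012 * t) * np.array([1.0, 1.03, 0.96])
        cfg = FitConfig(amplitude="free")
        f1 = fit_one_phase(RetentionSeries(times=tuple(t), values=tuple(m),
                                           scale="mass"), cfg)
        f2 = fit_one_phase(RetentionSeries(times=tuple(t),
                                           values=tuple(7.7 * m),
                                           scale="mass"), cfg)
        assert f1.lambda1_ == pytest.approx(f2.lambda1_, rel=1e-12)

    def test_wrapper_uses_config(self, ag_co_retention):
        t, y = ag_co_retention
        series = RetentionSeries(times=tuple(t), values=tuple(y))
        fit = fit_two_phase(series, FitConfig(fraction_constraint=0.5))
        assert fit.p1_ == pytest.approx(0.5)
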