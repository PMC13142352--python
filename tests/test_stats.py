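"""Window summaries, Cohen's d, Hill / dwell-time / NPo / conductance fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poreblock import (
    FrameSeries,
    WindowSummary,
    classify_effect,
    cohens_d,
    compute_npo,
    fit_dwell_exponential,
    fit_hill,
    fit_iv_conductance,
    hill_curve,
    last_fraction,
    window_summary,
)
from poreblock.stats import DegenerateStatisticError


def series(values):
    values = np.asarray(values, dtype=float)
    return FrameSeries("m", values, np.arange(len(values), dtype=float))


class TestWindowSummary:
    def test_constant_series_has_zero_sd(self):
        s = window_summary(series(np.full(40, 7.0)), last_fraction(0.25))
        assert s.mean == 7.0
        assert s.sd == 0.0
        assert s.n_frames_used == 10

    def test_final_quarter_of_2000_frames_uses_500(self):
        s = window_summary(series(np.arange(2000.0)), last_fraction(0.25))
        assert s.n_frames_used == 500
        assert s.mean == pytest.approx(np.arange(1500, 2000).mean())

    def test_full_window_moments(self):
        s = window_summary(series([1, 2, 3, 4] * 2), (0.0, 1.0))
        assert s.mean == 2.5
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4] * 2, ddof=1))

    def test_sample_sd_uses_n_minus_one(self):
        s = window_summary(series([1.0, 2.0, 3.0, 4.0, 1, 2, 3, 4]), (0.5, 1.0))
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_window_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            window_summary(series(np.arange(20.0)), (0.5, 1.5))

    def test_nan_frames_excluded_from_moments(self):
        v = np.full(20, 3.0)
        v[18] = np.nan
        s = window_summary(series(v), last_fraction(0.25))
        assert s.mean == 3.0 and s.sd == 0.0


class TestCohensD:
    def test_identical_summaries_give_zero_negligible(self):
        a = WindowSummary((0.75, 1.0), 10, 5.0, 2.0)
        es = cohens_d(a, a)
        assert es.d == 0.0 and es.label == "negligible"

    def test_equal_sd_example(self):
        a = WindowSummary((0.75, 1.0), 10, 10.0, 2.0)
        b = WindowSummary((0.75, 1.0), 10, 7.0, 2.0)
        es = cohens_d(a, b)
        assert es.d == pytest.approx(1.5)
        assert es.sd_pooled == pytest.approx(2.0)
        assert es.label == "large"

    def test_mixed_sd_example(self):
        a = WindowSummary((0.75, 1.0), 10, 5.0, 3.0)
        b = WindowSummary((0.75, 1.0), 10, 0.0, 4.0)
        es = cohens_d(a, b)
        assert es.d == pytest.approx(5.0 / np.sqrt(12.5))

    def test_quadrature_convention_flag(self):
        a = WindowSummary((0.75, 1.0), 10, 5.0, 3.0)
        b = WindowSummary((0.75, 1.0), 10, 0.0, 4.0)
        es = cohens_d(a, b, pooled="quadrature")
        assert es.sd_pooled == pytest.approx(5.0)
        assert es.d == pytest.approx(1.0)

    def test_both_zero_sd_is_undefined(self):
        a = WindowSummary((0.75, 1.0), 10, 5.0, 0.0)
        with pytest.raises(DegenerateStatisticError):
            cohens_d(a, a)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(0.1, 20), s2=st.floats(0.1, 20),
        k=st.floats(0.1, 10),
    )
    def test_antisymmetry_and_scale_equivariance(self, m1, m2, s1, s2, k):
        a = WindowSummary((0.75, 1.0), 10, m1, s1)
        b = WindowSummary((0.75, 1.0), 10, m2, s2)
        ka = WindowSummary((0.75, 1.0), 10, k * m1, k * s1)
        kb = WindowSummary((0.75, 1.0), 10, k * m2, k * s2)
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)
        assert cohens_d(ka, kb).d == pytest.approx(cohens_d(a, b).d, rel=1e-9)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0.0, "negligible"), (0.19, "negligible"),
            (0.2, "small"), (0.49, "small"),
            (0.5, "medium"), (0.79, "medium"),
            (0.8, "large"), (-0.9, "large"), (-0.3, "small"),
        ],
    )
    def test_threshold_boundaries(self, d, label):
        assert classify_effect(d) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(float("nan"))


class TestHillFit:
    def test_noise_free_recovery_of_generating_parameters(self):
        c = np.array([2.0, 5.0, 10.0, 13.6, 30.0, 100.0])
        y = hill_curve(c, 1.0, 13.6, 3.6)
        fit = fit_hill(c, y)
        assert fit.converged
        assert fit.imax == pytest.approx(1.0, rel=1e-3)
        assert fit.ic50 == pytest.approx(13.6, rel=1e-3)
        assert fit.n_h == pytest.approx(3.6, rel=1e-3)

    def test_midpoint_identity(self):
        fit_params = (0.9, 20.0, 2.5)
        assert hill_curve(np.array([20.0]), *fit_params)[0] == pytest.approx(0.45)

    def test_flat_response_flags_non_convergence(self):
        c = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        y = np.full(5, 0.01)
        fit = fit_hill(c, y)
        assert not fit.converged

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, 1.0, 10.0, 10.0], [0.1, 0.1, 0.9, 0.9])

    def test_noisy_recovery_within_stochastic_tolerance(self):
        """Gaussian noise sigma=0.03 on an 8x5 design generated from
        (Imax=0.9, IC50=20 uM, nH=2.5): IC50 back within 15%, nH within 25%."""
        rng = np.random.default_rng(2024)
        c = np.repeat(np.geomspace(2.0, 200.0, 8), 5)
        y = np.clip(hill_curve(c, 0.9, 20.0, 2.5) + rng.normal(0, 0.03, c.size), 0, 1)
        fit = fit_hill(c, y)
        assert abs(fit.ic50 - 20.0) / 20.0 < 0.15
        assert abs(fit.n_h - 2.5) / 2.5 < 0.25


class TestDwellFit:
    def test_mle_is_the_sample_mean(self):
        fit = fit_dwell_exponential([1.0, 2.0, 3.0] * 4)
        assert fit.tau == 2.0
        assert fit.n_events == 12

    def test_stochastic_recovery_of_open_time_constant(self):
        rng = np.random.default_rng(17)
        draws = rng.exponential(17.22, 5000)
        fit = fit_dwell_exponential(draws)
        assert abs(fit.tau - 17.22) / 17.22 < 0.05

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_exponential([1.0] * 11 + [0.0])

    def test_insufficient_events_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_exponential([1.0] * 5)

    def test_estimator_unbiased_in_mean(self):
        """Over 200 seeded replicates of n=100, mean(tau_hat)/tau in [0.97, 1.03]."""
        rng = np.random.default_rng(99)
        tau = 5.0
        taus = [fit_dwell_exponential(rng.exponential(tau, 100)).tau for _ in range(200)]
        assert 0.97 < np.mean(taus) / tau < 1.03


class TestNPo:
    def test_half_open_record(self):
        res = compute_npo([("open", 50.0), ("closed", 50.0)], 100.0)
        assert res.npo == 0.5

    def test_no_open_events_is_zero(self):
        assert compute_npo([("closed", 100.0)], 100.0).npo == 0.0

    def test_stacked_levels_sum(self):
        assert compute_npo([(2, 100.0)], 100.0).npo == 2.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            compute_npo([("open", -1.0)], 100.0)

    def test_events_exceeding_record_rejected(self):
        with pytest.raises(ValueError):
            compute_npo([("open", 80.0), ("closed", 30.0)], 100.0)


class TestConductance:
    def test_exact_line_returns_slope_in_ps(self):
        v = np.array([-60.0, -40.0, -20.0, 20.0, 40.0, 60.0])
        fit = fit_iv_conductance(v, 0.293 * v)
        assert fit.conductance == pytest.approx(293.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_symmetric_points_plus_origin(self):
        fit = fit_iv_conductance([-60.0, 0.0, 60.0], [-17.58, 0.0, 17.58])
        assert fit.conductance == pytest.approx(293.0)

    def test_zero_currents_give_zero_conductance(self):
        fit = fit_iv_conductance([-60.0, 0.0, 60.0], [0.0, 0.0, 0.0])
        assert fit.conductance == 0.0

    def test_degenerate_voltages_rejected(self):
        with pytest.raises(ValueError):
            fit_iv_conductance([10.0, 10.0, 10.0], [1.0, 2.0, 3.0])
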