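"""Thermal performance curve fitting: oracles, properties, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermolife import (
    RatePoint,
    briere1_rate,
    briere1_topt_closed_form,
    compare_models,
    fit_linear,
    fit_nonlinear,
    lactin2_rate,
    make_rate_points,
    predict_duration,
)
from thermolife.datasets import reference_rate_points
from thermolife.thermal import ThermalFitError


class TestRatePoints:
    def test_rate_is_reciprocal_duration(self):
        pts = make_rate_points({15.0: 40.0, 25.0: 1.0})
        assert pts[0].rate_per_day == pytest.approx(0.025)
        assert pts[1].rate_per_day == pytest.approx(1.0)

    def test_reference_nymph_rates(self):
        rates = [p.rate_per_day for p in reference_rate_points("nymph")]
        assert rates == pytest.approx([0.02500, 0.03984, 0.05000, 0.06211, 0.06098], abs=5e-6)

    def test_ordering_by_temperature(self):
        pts = make_rate_points({30.0: 10.0, 15.0: 40.0, 25.0: 20.0})
        assert [p.temperature_c for p in pts] == [15.0, 25.0, 30.0]

    def test_zero_rate_point(self):
        p = RatePoint.zero_rate(32.5)
        assert p.rate_per_day == 0.0


class TestLinearFit:
    def test_noiseless_line_recovered_exactly(self):
        # rate = 0.01·(T − 10): slope 0.01, K = 100 DD, t_min = 10 °C
        pts = make_rate_points({t: 1.0 / (0.01 * (t - 10)) for t in (15.0, 20.0, 25.0)})
        fit = fit_linear(pts)
        assert fit.slope_b == pytest.approx(0.01, abs=1e-12)
        assert fit.K_degree_days == pytest.approx(100.0, abs=1e-8)
        assert fit.t_min_c == pytest.approx(10.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        T = np.array([12.0, 17.0, 21.0, 24.0, 28.0, 31.0])
        r = 0.004 * (T - 8.0) + rng.normal(0, 5e-4, T.size)
        fit = fit_linear(make_rate_points({t: 1 / ri for t, ri in zip(T, r)}))
        # independent closed-form least squares from raw sums
        n = T.size
        sx, sy, sxx, sxy = T.sum(), r.sum(), (T * T).sum(), (T * r).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert fit.slope_b == pytest.approx(slope, abs=1e-10)
        assert fit.intercept_a == pytest.approx(intercept, abs=1e-10)

    def test_predicted_rate_zero_at_threshold(self):
        fit = fit_linear(reference_rate_points("nymph"))
        assert fit.rate(fit.t_min_c) == pytest.approx(0.0, abs=1e-10)
        assert fit.K_degree_days * fit.slope_b == pytest.approx(1.0)

    def test_reference_nymph_rates_strongly_linear(self):
        assert fit_linear(reference_rate_points("nymph")).diagnostics.r_squared >= 0.95

    @given(shift=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_temperature_shift_equivariance(self, shift):
        base = {15.0: 40.0, 20.0: 25.1, 25.0: 20.0, 27.5: 16.1, 30.0: 16.4}
        fit0 = fit_linear(make_rate_points(base))
        fit1 = fit_linear(make_rate_points({t + shift: d for t, d in base.items()}))
        assert fit1.t_min_c == pytest.approx(fit0.t_min_c + shift, abs=1e-6)
        assert fit1.K_degree_days == pytest.approx(fit0.K_degree_days, rel=1e-9)

    def test_singular_design_raises(self):
        pts = [RatePoint(25.0, 10.0), RatePoint(25.0, 11.0), RatePoint(25.0, 12.0)]
        with pytest.raises(ThermalFitError, match="singular"):
            fit_linear(pts)


class TestModelCurves:
    def test_briere_zero_at_both_thresholds(self):
        assert briere1_rate(7.0, 2e-5, 7.0, 34.0) == 0.0
        assert briere1_rate(34.0, 2e-5, 7.0, 34.0) == 0.0
        assert briere1_rate(40.0, 2e-5, 7.0, 34.0) == 0.0

    def test_briere_matches_direct_formula(self):
        a, tmin, tmax, T = 2e-5, 7.0, 34.0, 25.0
        expected = a * T * (T - tmin) * math.sqrt(tmax - T)
        assert briere1_rate(T, a, tmin, tmax) == pytest.approx(expected, rel=1e-14)

    def test_lactin_at_tmax_param_equals_lambda(self):
        # exp(ρT) − exp(ρ·t_max − 0) + λ = λ at T = t_max_param
        assert lactin2_rate(35.0, 0.1, 35.0, 4.0, -0.8) == pytest.approx(-0.8, abs=1e-10)
        assert lactin2_rate(35.0, 0.1, 35.0, 4.0, 0.0) == pytest.approx(0.0, abs=1e-10)

    @given(
        rho=st.floats(0.01, 0.3),
        tmaxp=st.floats(30, 45),
        delta=st.floats(0.5, 10),
        lam=st.floats(-2, 1),
        T=st.floats(-5, 40),
    )
    @settings(max_examples=50, deadline=None)
    def test_lactin_matches_direct_formula(self, rho, tmaxp, delta, lam, T):
        expected = math.exp(rho * T) - math.exp(rho * tmaxp - (tmaxp - T) / delta) + lam
        assert lactin2_rate(T, rho, tmaxp, delta, lam) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(tmin=st.floats(0, 12), width=st.floats(10, 30))
    @settings(max_examples=30, deadline=None)
    def test_briere_topt_closed_form_matches_numeric(self, tmin, width):
        tmax = tmin + width
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: -briere1_rate(t, 1e-4, tmin, tmax), bounds=(tmin, tmax), method="bounded"
        )
        assert briere1_topt_closed_form(tmin, tmax) == pytest.approx(res.x, abs=1e-3)


class TestNonlinearFit:
    def test_briere_recovers_noiseless_parameters(self):
        a, tmin, tmax = 1.5e-5, 7.0, 34.0
        T = [10.0, 15.0, 20.0, 25.0, 30.0, 33.0]
        pts = [RatePoint(t, 1.0 / briere1_rate(t, a, tmin, tmax)) for t in T]
        fit = fit_nonlinear(pts, "briere1")
        assert fit.a_coeff == pytest.approx(a, rel=1e-4)
        assert fit.t_min_c == pytest.approx(tmin, rel=1e-4)
        assert fit.t_max_c == pytest.approx(tmax, rel=1e-4)
        assert fit.t_opt_c == pytest.approx(briere1_topt_closed_form(tmin, tmax), abs=1e-3)

    def test_lactin_recovers_noiseless_parameters(self):
        rho, tmaxp, delta, lam = 0.12, 36.0, 5.0, -0.9
        T = [12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 35.0]
        pts = [RatePoint(t, 1.0 / lactin2_rate(t, rho, tmaxp, delta, lam)) for t in T]
        fit = fit_nonlinear(pts, "lactin2")
        assert fit.rho == pytest.approx(rho, rel=1e-4)
        assert fit.t_max_param_c == pytest.approx(tmaxp, rel=1e-4)
        assert fit.delta_width == pytest.approx(delta, rel=1e-4)
        assert fit.lambda_shift == pytest.approx(lam, rel=1e-4)

    def test_lactin_thresholds_are_zero_crossings(self):
        fit = fit_nonlinear(
            reference_rate_points("total"), "lactin2", zero_rate_temps=(32.5,)
        )
        assert fit.t_min_c < fit.t_opt_c < fit.t_max_c
        assert fit.rate(fit.t_min_c) == pytest.approx(0.0, abs=1e-6)
        assert fit.rate(fit.t_max_c) == pytest.approx(0.0, abs=1e-6)

    def test_multistart_is_deterministic(self):
        pts = reference_rate_points("total")
        f1 = fit_nonlinear(pts, "lactin2", zero_rate_temps=(32.5,))
        f2 = fit_nonlinear(pts, "lactin2", zero_rate_temps=(32.5,))
        assert f1 == f2

    def test_too_few_points_raises(self):
        pts = [RatePoint(15.0, 40.0), RatePoint(20.0, 25.0), RatePoint(25.0, 20.0)]
        with pytest.raises(ThermalFitError, match="at least"):
            fit_nonlinear(pts, "lactin2")


class TestModelComparison:
    def test_aic_matches_brute_force(self):
        pts = reference_rate_points("nymph")
        fits = {
            "linear": fit_linear(pts),
            "briere1": fit_nonlinear(pts, "briere1"),
            "lactin2": fit_nonlinear(pts, "lactin2", zero_rate_temps=(32.5,)),
        }
        table = compare_models(fits)
        for name, fit in fits.items():
            d = fit.diagnostics
            expected = d.n_points * math.log(d.rss / d.n_points) + 2 * d.n_params
            assert table.loc[name, "aic"] == pytest.approx(expected, rel=1e-12)

    def test_lower_rss_wins_at_equal_k(self):
        # AIC is monotone in RSS for fixed n and k
        n, k = 6, 3
        aic = lambda rss: n * math.log(rss / n) + 2 * k  # noqa: E731
        assert aic(1.0) < aic(2.0)

    def test_ranks_follow_criteria(self):
        pts = reference_rate_points("nymph")
        table = compare_models({"linear": fit_linear(pts)})
        assert table.loc["linear", ["rank_r_squared", "rank_rss", "rank_aic"]].tolist() == [1, 1, 1]


class TestPredictDuration:
    def test_stated_formula(self):
        assert predict_duration(393.98, 4.74, 20.0) == pytest.approx(25.82, abs=0.005)
        assert predict_duration(100.0, 10.0, 20.0) == pytest.approx(10.0)

    def test_diverges_at_threshold(self):
        with pytest.raises(ValueError, match="diverges"):
            predict_duration(100.0, 10.0, 10.0)
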