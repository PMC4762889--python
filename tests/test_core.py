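"""Core decomposition model: modifiers, rate matrix, annual step, steady state."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from socagg.core import (ClimateRecord, SingularMatrixError, SoilState,
                         build_rate_matrix, climate_modifier,
                         climate_modifier_vec, size_modifier, steady_state,
                         step_annual, step_annual_with_flux)
from socagg.params import ParameterSet, default_parameters


def make_record(mat, precip, amp=8.0):
    return ClimateRecord(2000, mat, mat - amp, mat + amp, precip)


# ---------------------------------------------------------------------------
# climate modifier

class TestClimateModifier:
    def test_zero_temperature_leaves_precipitation_term(self, params):
        """At T = 0 the temperature response is exp(0) = 1."""
        for precip in (200.0, 800.0, 1500.0):
            got = climate_modifier(make_record(0.0, precip), params)
            expected = 1.0 - np.exp(params.gamma * precip / 1000.0)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_large_precipitation_asymptote_is_temperature_term(self, params):
        """The precipitation term saturates at 1 for very wet climates."""
        t = 4.0
        got = climate_modifier(make_record(t, 1e6), params)
        expected = np.exp(params.beta1 * t + params.beta2 * t**2)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_negative_precipitation_rejected(self, params):
        with pytest.raises(ValueError):
            ClimateRecord(2000, 3.0, -5.0, 12.0, -10.0)

    def test_inconsistent_monthly_extremes_rejected(self):
        with pytest.raises(ValueError):
            ClimateRecord(2000, 3.0, 5.0, 12.0, 800.0)

    def test_sinusoid_mode_matches_explicit_monthly_average(self, params):
        """Sinusoid mode = mean of the response over 12 reconstructed months."""
        rec = make_record(3.5, 1150.0, amp=9.0)
        months = np.arange(1, 13)
        t_m = rec.mat + 9.0 * np.sin(2 * np.pi * months / 12)
        expected = np.mean(np.exp(params.beta1 * t_m + params.beta2 * t_m**2)) \
            * (1 - np.exp(params.gamma * 1.15))
        got = climate_modifier(rec, params, use_sinusoid=True)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got != pytest.approx(climate_modifier(rec, params), rel=1e-4)

    def test_vectorized_matches_scalar(self, params, rng):
        mats = rng.uniform(-5, 10, 40)
        precs = rng.uniform(100, 3000, 40)
        amps = rng.uniform(3, 12, 40)
        for sinusoid in (False, True):
            vec = climate_modifier_vec(mats, mats - amps, mats + amps, precs,
                                       params, sinusoid)
            scal = [climate_modifier(
                ClimateRecord(0, m, m - a, m + a, p), params, sinusoid)
                for m, a, p in zip(mats, amps, precs)]
            np.testing.assert_allclose(vec, scal, rtol=1e-12)

    def test_strictly_increasing_in_precipitation(self, params):
        precs = np.linspace(50, 4000, 200)
        vals = climate_modifier_vec(np.full_like(precs, 3.0), None, None,
                                    precs, params)
        assert np.all(np.diff(vals) > 0)


# ---------------------------------------------------------------------------
# size modifier

class TestSizeModifier:
    def test_nonwoody_unmodified(self, params):
        assert size_modifier(0.0, params) == 1.0

    def test_strictly_decreasing_over_size_classes(self, params):
        h0, h2, h10 = (size_modifier(d, params) for d in (0.0, 2.0, 10.0))
        assert h0 > h2 > h10 > 0

    def test_matches_packaged_functional_form(self, params):
        """Direct evaluation of min(1, (1 + phi1 d + phi2 d^2)^r)."""
        for d in (2.0, 10.0):
            base = 1 + params.size_phi1 * d + params.size_phi2 * d**2
            assert size_modifier(d, params) == pytest.approx(
                min(1.0, base ** params.size_r), rel=1e-12)

    def test_slower_mass_loss_for_larger_wood(self, params):
        """One year of pure decay loses less mass at 10 cm than at 2 cm."""
        m = build_rate_matrix(params, 1.0, size_modifier(2.0, params))
        m10 = build_rate_matrix(params, 1.0, size_modifier(10.0, params))
        x0 = SoilState(np.array([1.0, 1.0, 1.0, 1.0, 0.0]))
        zero = np.zeros(5)
        left2 = step_annual(x0, zero, m).total
        left10 = step_annual(x0, zero, m10).total
        assert left10 > left2

    def test_negative_diameter_rejected(self, params):
        with pytest.raises(ValueError):
            size_modifier(-1.0, params)


# ---------------------------------------------------------------------------
# rate matrix

class TestRateMatrix:
    def test_zero_climate_factor_gives_zero_matrix(self, params):
        assert np.all(build_rate_matrix(params, 0.0, 1.0) == 0)

    def test_unit_modifiers_reproduce_reference_rates(self, params):
        m = build_rate_matrix(params, 1.0, 1.0)
        np.testing.assert_allclose(np.diag(m), -params.alphas)

    def test_column_outflow_bookkeeping(self, params, rng):
        """Transfers + humus flow + mass loss of each labile column = k_i."""
        c, s = rng.uniform(0.2, 1.9), rng.uniform(0.3, 1.0)
        m = build_rate_matrix(params, c, s)
        k = params.alphas[:4] * c * s
        for i in range(4):
            transfers = m[:, i].sum() - m[i, i]  # includes humus row
            loss = -m[:, i].sum()
            assert transfers + loss == pytest.approx(k[i], rel=1e-12)
            expected_loss = k[i] * (1 - params.flow_fractions[i].sum()
                                    - params.humus_fraction)
            assert loss == pytest.approx(expected_loss, rel=1e-9, abs=1e-15)

    def test_humus_receives_configured_fraction(self, params):
        m = build_rate_matrix(params, 1.3, 0.7)
        k = params.alphas[:4] * 1.3 * 0.7
        np.testing.assert_allclose(m[4, :4], params.humus_fraction * k)

    def test_non_finite_modifier_rejected(self, params):
        with pytest.raises(ValueError):
            build_rate_matrix(params, np.nan, 1.0)


# ---------------------------------------------------------------------------
# annual step

class TestStepAnnual:
    def test_zero_matrix_accumulates_input(self, params):
        x0 = SoilState(np.array([0.1, 0.2, 0.0, 0.3, 1.0]))
        b = np.array([0.05, 0.01, 0.0, 0.02, 0.0])
        out = step_annual(x0, b, np.zeros((5, 5)))
        np.testing.assert_allclose(out.pools, x0.pools + b, rtol=1e-12)

    def test_single_pool_closed_form_decay(self):
        k = 0.37
        m = np.diag([-k, 0, 0, 0, 0]).astype(float)
        x0 = SoilState(np.array([2.0, 0, 0, 0, 0]))
        out = step_annual(x0, np.zeros(5), m)
        assert out.pools[0] == pytest.approx(2.0 * np.exp(-k), rel=1e-12)

    def test_agrees_with_independent_ode_integration(self, params, rng):
        """Generic forced 5-pool step vs an adaptive ODE solver."""
        m = build_rate_matrix(params, 1.2, 0.8)
        x0 = rng.uniform(0, 2, 5)
        b = rng.uniform(0, 0.3, 5)
        sol = solve_ivp(lambda t, x: m @ x + b, (0, 1), x0,
                        rtol=1e-11, atol=1e-13, method="DOP853")
        out = step_annual(SoilState(x0), b, m)
        np.testing.assert_allclose(out.pools, sol.y[:, -1], rtol=1e-6)

    def test_mass_balance_closes(self, params, rng):
        x0 = SoilState(rng.uniform(0, 3, 5))
        b = rng.uniform(0, 0.4, 5)
        m = build_rate_matrix(params, 0.9, 1.0)
        out, export = step_annual_with_flux(x0, b, m)
        lhs = out.total - x0.total
        rhs = b.sum() - export
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_rejects_non_finite_matrix(self, params):
        m = build_rate_matrix(params, 1.0, 1.0).copy()
        m[0, 0] = np.inf
        with pytest.raises(ValueError):
            step_annual(SoilState(np.zeros(5)), np.zeros(5), m)

    @given(c=st.floats(0.05, 1.9), seed=st.integers(0, 10_000))
    def test_non_negativity_preserved(self, c, seed):
        """Non-negative states and inputs stay non-negative."""
        params = default_parameters()
        local = np.random.default_rng(seed)
        m = build_rate_matrix(params, c, local.uniform(0.2, 1.0))
        x = SoilState(local.uniform(0, 5, 5))
        b = local.uniform(0, 0.5, 5)
        out = step_annual(x, b, m)
        assert np.all(out.pools >= -1e-12)


# ---------------------------------------------------------------------------
# steady state

class TestSteadyState:
    def test_scalar_balance_single_pool(self, params):
        """With no internal flows, each pool settles at input/rate."""
        lonely = params.with_(flow_fractions=np.zeros((4, 4)),
                              humus_fraction=0.0)
        b = np.array([0.2, 0.0, 0.0, 0.0, 0.0])
        out = steady_state(lonely, 1.0, 1.0, b)
        assert out.pools[0] == pytest.approx(0.2 / lonely.alpha_a, rel=1e-12)

    def test_linear_in_input(self, params, rng):
        b = rng.uniform(0, 0.3, 5)
        one = steady_state(params, 0.9, 1.0, b).pools
        two = steady_state(params, 0.9, 1.0, 2 * b).pools
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_is_fixed_point_of_annual_step(self, params, rng):
        b = rng.uniform(0, 0.3, 5)
        ss = steady_state(params, 1.1, 0.8, b)
        m = build_rate_matrix(params, 1.1, 0.8)
        after = step_annual(ss, b, m)
        np.testing.assert_allclose(after.pools, ss.pools, rtol=1e-9)

    def test_zero_climate_factor_fails_loudly(self, params):
        with pytest.raises(SingularMatrixError):
            steady_state(params, 0.0, 1.0, np.full(5, 0.1))

    def test_total_stock_decreasing_in_climate_factor(self, params):
        """Faster decomposition -> smaller steady-state stock, fixed input."""
        b = np.array([0.1, 0.05, 0.02, 0.08, 0.0])
        totals = [steady_state(params, c, 1.0, b).total
                  for c in np.linspace(0.2, 1.9, 12)]
        assert np.all(np.diff(totals) < 0)
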