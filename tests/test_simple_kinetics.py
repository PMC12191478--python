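"""Simple-order fits, model selection, and Arrhenius analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrkinet import (ValidationError, arrhenius_fit, fit_all_orders,
                     fit_order, rate_ratio, select_model)
from mrkinet.published import (COLOR_ACTIVATION_ENERGIES,
                               COLOR_RATE_CONSTANTS,
                               PRODUCT_ACTIVATION_ENERGIES,
                               PRODUCT_RATE_CONSTANTS, TEMPERATURES_C)
from mrkinet.simple_kinetics import GAS_CONSTANT, KELVIN_OFFSET
from mrkinet.synthetic import simple_series_closed_form

HOURS = 60.0  # minutes per hour


class TestFitOrder:
    def test_exact_zero_order_line(self):
        # C = 10 + 2*t_h sampled at t = 0..3 h
        times = np.array([0, 1, 2, 3]) * HOURS
        fit = fit_order(times, [10, 12, 14, 16], order=0)
        assert fit.k == pytest.approx(2.0, abs=1e-12)
        assert fit.C0_hat == pytest.approx(10.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_first_order_exponential(self):
        t_h = np.arange(6.0)
        values = 5.0 * np.exp(0.3 * t_h)
        fit = fit_order(t_h * HOURS, values, order=1)
        assert fit.k == pytest.approx(0.3, abs=1e-12)
        assert fit.C0_hat == pytest.approx(5.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_second_order(self):
        times = np.array([0, 5, 10, 20, 30.0])
        values = simple_series_closed_form(2, k=0.8, C0=4.0, times_min=times)
        fit = fit_order(times, values, order=2)
        assert fit.k == pytest.approx(0.8, rel=1e-10)
        assert fit.C0_hat == 4.0
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_protein_slope_matches_normal_equations(self, protein_series):
        times, values = protein_series
        fit = fit_order(times, values, order=0, response="protein")
        # independent OLS oracle via the normal equations
        X = np.column_stack([np.ones_like(times), times / HOURS])
        beta = np.linalg.solve(X.T @ X, X.T @ values)
        assert fit.C0_hat == pytest.approx(beta[0], rel=1e-12)
        assert fit.k == pytest.approx(beta[1], rel=1e-12)
        assert fit.k < 0  # protein is consumed

    def test_first_order_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            fit_order([0, 10, 20], [1.0, 0.0, 2.0], order=1)

    def test_second_order_rejects_zero(self):
        with pytest.raises(ValidationError):
            fit_order([0, 10, 20], [1.0, 0.0, 2.0], order=2)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_order([0, 10], [1.0, 2.0], order=0)


class TestSelectModel:
    def test_exact_line_selects_zero_order(self):
        times = np.array([0, 1, 2, 3, 4]) * HOURS
        fits = fit_all_orders(times, 10 + 2 * np.arange(5.0))
        assert select_model(fits).order == 0

    def test_tie_broken_toward_lowest_order(self):
        f0 = fit_order([0, 60, 120], [1.0, 2.0, 3.0], 0)
        f1 = fit_order([0, 60, 120],
                       [1.0, math.e, math.e**2], 1)
        assert f0.r_squared == f1.r_squared == pytest.approx(1.0)
        assert select_model([f1, f0]).order == 0

    def test_first_order_decay_selected(self):
        times = np.array([0, 5, 10, 15, 20, 25, 30.0])
        values = simple_series_closed_form(1, k=-0.05, C0=2.0,
                                           times_min=times)
        fits = fit_all_orders(times, values)
        assert select_model(fits).order == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            select_model([])


class TestArrhenius:
    @pytest.mark.parametrize("name,table,expected", [
        *[(n, PRODUCT_RATE_CONSTANTS, PRODUCT_ACTIVATION_ENERGIES[n])
          for n in ("GO", "MGO", "3-DG", "5-HMF", "CML")],
        ("L*", COLOR_RATE_CONSTANTS, COLOR_ACTIVATION_ENERGIES["L*"]),
        ("a*", COLOR_RATE_CONSTANTS, COLOR_ACTIVATION_ENERGIES["a*"]),
    ])
    def test_reported_activation_energies(self, name, table, expected):
        """Zero-order rate constants at 60-90 C reproduce the reported Ea
        within the rounding of the 4-significant-figure k values."""
        ks = table[name][0]
        res = arrhenius_fit(list(zip(ks, TEMPERATURES_C)))
        assert res.Ea == pytest.approx(expected, rel=0.02)
        assert res.Ea_stderr >= 0

    def test_flat_line_zero_ea(self):
        res = arrhenius_fit([(0.5, 60), (0.5, 70), (0.5, 80)])
        assert res.Ea == pytest.approx(0.0, abs=1e-12)

    def test_forward_generated_ea_recovered(self):
        Ea, A = 50e3, 1e6  # J/mol
        pairs = [(A * math.exp(-Ea / (GAS_CONSTANT * (T + KELVIN_OFFSET))), T)
                 for T in TEMPERATURES_C]
        res = arrhenius_fit(pairs)
        assert res.Ea == pytest.approx(50.0, rel=1e-12)
        assert res.lnA == pytest.approx(math.log(A), rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_negative_constants_admissible(self):
        ks = COLOR_RATE_CONSTANTS["L*"][0]  # all negative (L* decreases)
        res = arrhenius_fit(list(zip(ks, TEMPERATURES_C)))
        assert res.Ea > 0

    @given(st.floats(1e-3, 1e3))
    def test_ea_invariant_under_uniform_rescale(self, scale):
        base = [(0.1476, 60.0), (0.1644, 70.0), (0.1770, 80.0),
                (0.2106, 90.0)]
        r1 = arrhenius_fit(base)
        r2 = arrhenius_fit([(k * scale, T) for k, T in base])
        assert r2.Ea == pytest.approx(r1.Ea, rel=1e-9)

    def test_sign_mixed_rejected(self):
        with pytest.raises(ValidationError):
            arrhenius_fit([(0.5, 60), (-0.6, 70), (0.7, 80)])

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            arrhenius_fit([(0.5, 60), (0.6, 60)])

    def test_two_points_stderr_undefined(self):
        res = arrhenius_fit([(0.5, 60), (0.7, 90)])
        assert math.isnan(res.Ea_stderr)


class TestRateRatio:
    def test_reported_ratios(self):
        assert rate_ratio(24.4548, 11.5734) == pytest.approx(2.11, abs=5e-3)
        assert rate_ratio(141.6066, 69.5022) == pytest.approx(2.04, abs=5e-3)

    def test_identity(self):
        assert rate_ratio(0.3, 0.3) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            rate_ratio(1.0, 0.0)

    def test_sign_mixed_rejected(self):
        with pytest.raises(ValidationError):
            rate_ratio(1.0, -1.0)
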