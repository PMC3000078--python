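"""Denaturation kinetics: Arrhenius rates, scan and isothermal solutions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from calorikin import (
    GAS_CONSTANT,
    DomainModel,
    KineticParameters,
    OneStageDomain,
    TwoStageDomain,
    arrhenius_rate,
    half_life,
    isothermal_fractions,
    native_fraction_scan,
    simulate_one_stage,
    simulate_two_stage,
)
from calorikin.kinetics import anneal_model, default_grid, two_stage_state_fractions

NU = 1.0


class TestArrhenius:
    def test_rate_is_one_at_T_star(self):
        assert arrhenius_rate(KineticParameters(400, 321.2), 321.2) == pytest.approx(1.0)

    def test_scalar_value(self):
        # direct evaluation: exp[(400/R)(1/321.2 - 1/317.15)]
        expected = math.exp((400 / GAS_CONSTANT) * (1 / 321.2 - 1 / 317.15))
        assert arrhenius_rate(KineticParameters(400, 321.2), 317.15) == pytest.approx(expected)
        assert expected == pytest.approx(0.148, abs=5e-4)

    @given(E_a=st.floats(50, 800), T_star=st.floats(290, 350),
           dT=st.floats(0.5, 20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_around_T_star(self, E_a, T_star, dT):
        p = KineticParameters(E_a, T_star)
        assert arrhenius_rate(p, T_star - dT) < 1.0 < arrhenius_rate(p, T_star + dT)

    def test_half_life_at_T_star(self):
        assert half_life(KineticParameters(300, 320), 320.0) == pytest.approx(math.log(2))

    def test_half_life_strictly_decreasing(self):
        p = KineticParameters(400, 321.2)
        ts = [half_life(p, T) for T in np.linspace(300, 340, 30)]
        assert np.all(np.diff(ts) < 0)


class TestNativeFractionScan:
    def test_frozen_limit_far_below_T_star(self):
        p = KineticParameters(300, 320)
        x = native_fraction_scan(p, np.linspace(280, 295, 200), NU)
        assert x[-1] > 0.999

    def test_starts_at_one_and_non_increasing(self):
        p = KineticParameters(300, 320)
        x = native_fraction_scan(p, default_grid(), NU)
        assert x[0] == pytest.approx(1.0)
        assert np.all(np.diff(x) <= 0)

    def test_grid_refinement_of_half_crossing(self):
        p = KineticParameters(300, 320)

        def crossing(step):
            g = default_grid(288.15, 70, step)
            x = native_fraction_scan(p, g, NU)
            return float(np.interp(0.5, x[::-1], g[::-1]))

        assert abs(crossing(0.05) - crossing(0.025)) < 0.01

    def test_faster_scan_shifts_crossing_up(self):
        p = KineticParameters(300, 320)
        g = default_grid()
        x1 = native_fraction_scan(p, g, 1.0)
        x2 = native_fraction_scan(p, g, 2.0)
        c1 = np.interp(0.5, x1[::-1], g[::-1])
        c2 = np.interp(0.5, x2[::-1], g[::-1])
        assert c2 > c1

    def test_grid_below_T0_rejected(self):
        with pytest.raises(ValueError):
            native_fraction_scan(KineticParameters(300, 320), default_grid(), NU, T0=300.0)


class TestOneStage:
    def test_area_conservation(self):
        d = OneStageDomain(KineticParameters(290, 317.5), 200.0)
        ex = simulate_one_stage(d, default_grid(), NU)
        assert ex.total_enthalpy == pytest.approx(200.0, rel=5e-3)

    def test_peak_condition(self):
        # at the maximum of Eq. C_p^ex: k(T_max) = nu E_a / (R T_max^2)
        d = OneStageDomain(KineticParameters(300, 320), 150.0)
        ex = simulate_one_stage(d, default_grid(), NU)
        T_max_sim = ex.temperature[int(np.argmax(ex.excess_heat_capacity))]

        def f(T):
            return arrhenius_rate(d.kinetics, T) - NU * d.kinetics.E_a / (GAS_CONSTANT * T**2)

        T_max_oracle = brentq(f, 300.0, 340.0)
        assert abs(T_max_sim - T_max_oracle) < 0.05

    def test_linearity_in_initial_fraction(self):
        d = OneStageDomain(KineticParameters(300, 320), 150.0)
        g = default_grid()
        full = simulate_one_stage(d, g, NU, initial_fraction=1.0)
        half = simulate_one_stage(d, g, NU, initial_fraction=0.5)
        np.testing.assert_allclose(half.excess_heat_capacity,
                                   0.5 * full.excess_heat_capacity, rtol=1e-12)


class TestTwoStage:
    def test_area_both_stages(self):
        d = TwoStageDomain(KineticParameters(400, 321.2), KineticParameters(340, 324.5),
                           1030.0, 500.0)
        ex = simulate_two_stage(d, default_grid(), NU)
        assert ex.total_enthalpy == pytest.approx(1530.0, rel=5e-3)

    def test_area_with_initial_intermediate(self):
        d = TwoStageDomain(KineticParameters(400, 321.2), KineticParameters(340, 324.5),
                           1030.0, 500.0, x_N0=0.3, x_I0=0.5)
        ex = simulate_two_stage(d, default_grid(), NU)
        expected = 0.3 * 1530.0 + 0.5 * 500.0
        assert ex.total_enthalpy == pytest.approx(expected, rel=5e-3)

    def test_pure_intermediate_matches_one_stage(self):
        st2 = KineticParameters(340, 324.5)
        d = TwoStageDomain(KineticParameters(400, 321.2), st2, 1030.0, 500.0,
                           x_N0=0.0, x_I0=1.0)
        g = default_grid()
        two = simulate_two_stage(d, g, NU)
        one = simulate_one_stage(OneStageDomain(st2, 500.0), g, NU)
        scale = float(np.max(one.excess_heat_capacity))
        np.testing.assert_allclose(two.excess_heat_capacity, one.excess_heat_capacity,
                                   rtol=1e-6, atol=1e-6 * scale)

    def test_against_stiff_ode_oracle(self, s1_model):
        # independent integration of dx_N/dT, dx_I/dT with an implicit solver
        d = s1_model.domains[1]
        g = default_grid()

        def rhs(T, y):
            k1 = arrhenius_rate(d.stage1, T)
            k2 = arrhenius_rate(d.stage2, T)
            return [-k1 * y[0] / NU, (k1 * y[0] - k2 * y[1]) / NU]

        sol = solve_ivp(rhs, (g[0], g[-1]), [1.0, 0.0], t_eval=g,
                        method="Radau", rtol=1e-10, atol=1e-13)
        oracle = (d.dH1 * arrhenius_rate(d.stage1, g) * sol.y[0]
                  + d.dH2 * arrhenius_rate(d.stage2, g) * sol.y[1]) / NU
        ours = simulate_two_stage(d, g, NU).excess_heat_capacity
        assert np.max(np.abs(ours - oracle)) / np.max(oracle) < 1e-4


class TestIsothermal:
    def test_zero_time_returns_initial_values(self, s1_model):
        fr = isothermal_fractions(s1_model, 319.15, 0.0)
        assert fr[0] == (1.0,)
        assert fr[1] == (1.0, 0.0)

    def test_domain_I_eliminated_by_15min_at_46C(self, s1_model):
        # the hold used to erase the less stable domain
        fr = isothermal_fractions(s1_model, 319.15, 15.0)
        assert fr[0][0] < 0.01

    def test_two_stage_k2_zero_limit(self):
        # with k2 = 0 every converted molecule piles up in I
        d = TwoStageDomain(KineticParameters(300, 320), KineticParameters(300, 1e6),
                           100.0, 100.0, x_N0=0.8, x_I0=0.1)
        model = DomainModel((d,))
        t, T = 7.0, 318.0
        k1 = arrhenius_rate(d.stage1, T)
        (xN, xI), = isothermal_fractions(model, T, t)
        assert xN == pytest.approx(0.8 * math.exp(-k1 * t), rel=1e-9)
        assert xI == pytest.approx(0.8 * (1 - math.exp(-k1 * t)) + 0.1, rel=1e-6)

    def test_degenerate_equal_rates(self):
        p = KineticParameters(300, 320)
        d = TwoStageDomain(p, p, 100.0, 100.0)
        model = DomainModel((d,))
        t, T = 5.0, 319.0
        k = arrhenius_rate(p, T)
        (xN, xI), = isothermal_fractions(model, T, t)
        # limit formula: x_I = k t e^{-k t}
        assert xI == pytest.approx(k * t * math.exp(-k * t), rel=1e-6)

    def test_annealing_linearity_one_stage(self):
        # scanning an annealed one-stage domain = scaled native scan
        d = OneStageDomain(KineticParameters(290, 317.5), 200.0)
        model = DomainModel((d,))
        g = default_grid()
        annealed = anneal_model(model, 315.15, 20.0)
        x = annealed.initial_fractions[0]
        native = simulate_one_stage(d, g, NU)
        after = simulate_one_stage(d, g, NU, initial_fraction=x)
        scale = float(np.max(native.excess_heat_capacity))
        np.testing.assert_allclose(after.excess_heat_capacity,
                                   x * native.excess_heat_capacity,
                                   rtol=1e-12, atol=1e-15 * scale)

    def test_scan_fractions_sum_conserved(self, s1_model):
        d = s1_model.domains[1]
        xN, xI, xD = two_stage_state_fractions(d, default_grid(), NU)
        np.testing.assert_allclose(xN + xI + xD, 1.0, atol=1e-12)
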