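"""Channel-level checks of the I_Kur formulation and its mutant variants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kcna5.ikur import (
    IDENTITY_DELTA,
    KQ10,
    TABLE1_DELTAS,
    BoltzmannParams,
    MutantDelta,
    activation_steady_state,
    apply_mutant,
    canonical_mutant_label,
    conductance_scale,
    ikur_current,
    inactivation_steady_state,
    mutant_model,
    step_gates,
    tau_activation,
    tau_inactivation,
    wt_equivalent_activation,
    wt_model,
)


class TestSteadyStates:
    def test_activation_midpoint_of_first_factor(self, wt):
        # product of 0.5 and the second Boltzmann factor at its own argument
        expected = 0.5 / (1.0 + math.exp((17.67 - 8.45) / 11.51))
        assert activation_steady_state(-17.67, wt) == pytest.approx(expected, abs=1e-10)
        assert activation_steady_state(-17.67, wt) == pytest.approx(0.1549, abs=2e-4)

    def test_activation_limits(self, wt):
        assert activation_steady_state(-100.0, wt) < 1e-6
        assert activation_steady_state(80.0, wt) == pytest.approx(0.9995, abs=1e-4)

    @pytest.mark.parametrize("v, expected", [
        (1e4, 0.46),                 # depolarised limit: the availability floor
        (15.11, 0.52 / 2 + 0.46),    # Boltzmann midpoint
        (-1e4, 0.98),                # hyperpolarised limit: amplitude + floor
    ])
    def test_inactivation_anchor_points(self, wt, v, expected):
        assert inactivation_steady_state(v, wt) == pytest.approx(expected, abs=1e-9)

    def test_bounded_on_grid(self, wt, voltage_grid):
        a = activation_steady_state(voltage_grid, wt)
        i = inactivation_steady_state(voltage_grid, wt)
        assert np.all((a >= 0) & (a <= 1))
        assert np.all((i >= wt.inact_ss.floor_ma - 1e-12)
                      & (i <= wt.inact_ss.floor_ma + wt.inact_ss.amplitude + 1e-12))


class TestTimeConstants:
    def test_activation_limits(self, wt):
        assert tau_activation(1e4, wt) == pytest.approx(4.27 * 0.55 / KQ10, rel=1e-9)
        assert tau_activation(-1e4, wt) == pytest.approx(49.94 * 0.29 / KQ10, rel=1e-9)
        assert tau_activation(1e4, wt) == pytest.approx(0.667, abs=5e-4)
        assert tau_activation(-1e4, wt) == pytest.approx(4.114, abs=5e-4)

    def test_inactivation_limits_and_monotonicity(self, wt, voltage_grid):
        assert tau_inactivation(1e4, wt) == pytest.approx(1739.14 / KQ10, rel=1e-9)
        assert tau_inactivation(-1e4, wt) == pytest.approx((2328 + 1739.14) / KQ10,
                                                           rel=1e-9)
        taus = tau_inactivation(voltage_grid, wt)
        assert np.all(np.diff(taus) < 0)

    def test_positive_on_grid(self, wt, voltage_grid):
        assert np.all(tau_activation(voltage_grid, wt) > 0)
        assert np.all(tau_inactivation(voltage_grid, wt) > 0)

    def test_q10_is_exact_scalar_division(self, wt, voltage_grid):
        from dataclasses import replace

        uncorrected = replace(wt, kq10=1.0)
        assert np.allclose(tau_activation(voltage_grid, uncorrected),
                           KQ10 * tau_activation(voltage_grid, wt),
                           rtol=1e-14, atol=0)
        assert np.allclose(tau_inactivation(voltage_grid, uncorrected),
                           KQ10 * tau_inactivation(voltage_grid, wt),
                           rtol=1e-14, atol=0)


class TestConductanceAndCurrent:
    def test_conductance_limits(self, wt):
        assert conductance_scale(-1e4, wt) == pytest.approx(0.64 * 4.51, rel=1e-12)
        assert conductance_scale(1e4, wt) == pytest.approx(0.64 * 6.41, rel=1e-12)

    def test_conductance_bounds_exclusive(self, wt, voltage_grid):
        g = conductance_scale(voltage_grid, wt)
        assert np.all(g > 0.64 * 4.51)
        assert np.all(g < 0.64 * 6.41)

    def test_p488s_conductance_ratio(self, wt):
        p488s = mutant_model("P488S")
        for v in (-60.0, 0.0, 40.0):
            assert conductance_scale(v, p488s) == pytest.approx(
                0.038 * conductance_scale(v, wt), rel=1e-12)

    def test_current_zero_cases(self, wt):
        assert ikur_current(30.0, 0.0, 0.7, -85.0, wt) == 0.0
        assert ikur_current(-85.0, 0.5, 0.7, -85.0, wt) == 0.0

    def test_current_composition(self, wt):
        v, e_k = 30.0, -85.0
        a = activation_steady_state(v, wt)
        i = inactivation_steady_state(v, wt)
        expected = conductance_scale(v, wt) * a * i * (v - e_k)
        assert ikur_current(v, a, i, e_k, wt) == pytest.approx(expected, rel=1e-12)


class TestGateIntegration:
    def test_infinite_dt_reaches_steady_state(self, wt):
        a, i = step_gates((0.2, 0.9), 10.0, 1e9, wt)
        assert a == pytest.approx(activation_steady_state(10.0, wt), abs=1e-12)
        assert i == pytest.approx(inactivation_steady_state(10.0, wt), abs=1e-12)

    def test_zero_dt_is_identity(self, wt):
        a, i = step_gates((0.2, 0.9), 10.0, 0.0, wt)
        assert a == pytest.approx(0.2, abs=1e-15)
        assert i == pytest.approx(0.9, abs=1e-15)

    @pytest.mark.parametrize("v, dt", [(-30.0, 0.5), (0.0, 0.2), (40.0, 0.5)])
    def test_matches_fine_euler_oracle(self, wt, v, dt):
        # forward-Euler as the independent integrator; the sub-step is chosen
        # so the oracle's own O(h) error sits far below the 1e-6 tolerance
        # (the activation time constant drops below 1 ms at positive voltages)
        a, i = 0.1, 0.95
        a_inf = activation_steady_state(v, wt)
        i_inf = inactivation_steady_state(v, wt)
        ta, ti = tau_activation(v, wt), tau_inactivation(v, wt)
        n_sub = 200_000
        h = dt / n_sub
        fa = 1.0 - h / ta
        fi = 1.0 - h / ti
        # closed-form Euler recursion: x_n = inf + (x0 - inf) * (1 - h/tau)^n
        ae = a_inf + (a - a_inf) * fa ** n_sub
        ie = i_inf + (i - i_inf) * fi ** n_sub
        ar, ir = step_gates((a, i), v, dt, wt)
        assert ar == pytest.approx(ae, abs=1e-6)
        assert ir == pytest.approx(ie, abs=1e-6)


class TestMutants:
    def test_identity_delta_matches_wt_equivalent(self):
        m = apply_mutant(IDENTITY_DELTA, label="identity")
        eq = wt_equivalent_activation()
        assert m.act_ss[0] == eq
        assert m.inact_ss == wt_model().inact_ss
        assert m.g_factor == 1.0
        assert m.tau_act_params == wt_model().tau_act_params

    def test_d469e_parameter_changes(self):
        eq = wt_equivalent_activation()
        m = mutant_model("D469E")
        assert m.act_ss[0].v_half == pytest.approx(eq.v_half)
        assert m.act_ss[0].slope_k == pytest.approx(eq.slope_k)
        assert m.inact_ss.v_half == pytest.approx(15.11 + 4.545)
        assert m.inact_ss.slope_k == pytest.approx(7.57 * 0.842)
        assert m.inact_ss.floor_ma == pytest.approx(0.46 - 0.093)
        assert m.g_factor == pytest.approx(0.546)

    def test_y155c_scales_conductance(self, wt):
        m = mutant_model("Y155C")
        assert conductance_scale(0.0, m) == pytest.approx(
            0.475 * conductance_scale(0.0, wt), rel=1e-12)

    def test_rejects_non_positive_slope_factor(self):
        with pytest.raises(ValueError):
            MutantDelta(0.0, -1.0, 0.0, 1.0, 0.0, 1.0)

    def test_ma_clipping_keeps_floor_in_range(self):
        extreme = MutantDelta(0.0, 1.0, 0.0, 1.0, -0.99, 1.0)
        m = apply_mutant(extreme)
        assert 0.0 <= m.inact_ss.floor_ma < 1.0

    def test_alias_resolves_to_canonical_label(self):
        assert canonical_mutant_label("D322H") == "D332H"
        assert mutant_model("D322H").g_factor == TABLE1_DELTAS["D332H"].g_factor
        with pytest.raises(KeyError):
            canonical_mutant_label("Q999X")

    def test_all_mutant_steady_states_bounded(self, mutants, voltage_grid):
        for m in mutants.values():
            a = activation_steady_state(voltage_grid, m)
            i = inactivation_steady_state(voltage_grid, m)
            assert np.all((a >= 0) & (a <= 1))
            assert np.all((i >= 0) & (i <= 1))
            assert np.all(tau_activation(voltage_grid, m) > 0)
            assert np.all(tau_inactivation(voltage_grid, m) > 0)


class TestBoltzmannParams:
    @given(v_half=st.floats(-80, 40), slope_k=st.floats(-30, 30).filter(
        lambda k: abs(k) > 0.5))
    @settings(max_examples=50, deadline=None)
    def test_values_between_floor_and_amplitude_plus_floor(self, v_half, slope_k):
        b = BoltzmannParams(v_half=v_half, slope_k=slope_k, amplitude=0.8,
                            floor_ma=0.1)
        v = np.linspace(-120, 80, 41)
        y = b(v)
        assert np.all(y >= 0.1 - 1e-12)
        assert np.all(y <= 0.9 + 1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BoltzmannParams(v_half=0.0, slope_k=0.0)
        with pytest.raises(ValueError):
            BoltzmannParams(v_half=0.0, slope_k=-5.0, amplitude=0.9, floor_ma=0.2)
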