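"""Boltzmann/mono-exponential fitting and relative-change recovery."""

import numpy as np
import pytest

from kcna5.clamp import ClampProtocol, CurrentTrace, simulate_voltage_clamp
from kcna5.fitting import (
    FitError,
    apply_q10,
    default_activation_window,
    derive_relative_changes,
    fit_boltzmann_activation,
    fit_boltzmann_inactivation,
    fit_monoexp_tau,
)
from kcna5.ikur import (
    KQ10,
    TABLE1_DELTAS,
    activation_steady_state,
    tau_activation,
    wt_equivalent_activation,
    wt_model,
)
from kcna5.roundtrip import recover_delta, fit_variant


class TestBoltzmannActivation:
    def test_exact_recovery_from_noiseless_points(self):
        v = np.arange(-60.0, 41.0, 5.0)
        y = 1.0 / (1.0 + np.exp((v + 10.0) / -6.0))
        fit = fit_boltzmann_activation(np.column_stack([v, y]))
        assert fit.v_half == pytest.approx(-10.0, abs=1e-6)
        assert fit.slope_k == pytest.approx(-6.0, abs=1e-6)

    def test_wt_product_fit_defines_the_reference(self, wt):
        v = np.arange(-60.0, 60.5, 1.0)
        y = activation_steady_state(v, wt)
        fit = fit_boltzmann_activation(np.column_stack([v, y]))
        eq = wt_equivalent_activation()
        assert fit.v_half == pytest.approx(eq.v_half, abs=1e-9)
        assert fit.slope_k == pytest.approx(eq.slope_k, abs=1e-9)

    def test_grid_search_oracle_agrees_with_reference_fit(self, wt):
        # independent coarse grid search over (v_half, k) followed by local
        # refinement cross-checks the least-squares reference
        v = np.arange(-60.0, 60.5, 1.0)
        y = activation_steady_state(v, wt)
        vh_grid = np.arange(-20.0, 0.01, 0.05)
        k_grid = np.arange(-12.0, -5.99, 0.05)
        best, best_cost = None, np.inf
        for vh in vh_grid:
            curves = 1.0 / (1.0 + np.exp((v[None, :] - vh) / k_grid[:, None]))
            costs = np.sum((curves - y) ** 2, axis=1)
            i = int(np.argmin(costs))
            if costs[i] < best_cost:
                best_cost, best = costs[i], (vh, k_grid[i])
        eq = wt_equivalent_activation()
        assert best[0] == pytest.approx(eq.v_half, abs=0.05)
        assert best[1] == pytest.approx(eq.slope_k, abs=0.05)

    def test_noisy_recovery_within_one_millivolt(self):
        # 12 voltages, 5% of plateau noise, mean absolute error over 50 seeds
        v = np.linspace(-50, 60, 12)
        truth = 1.0 / (1.0 + np.exp((v + 8.0) / -7.0))
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = truth + rng.normal(0, 0.05, v.size)
            fit = fit_boltzmann_activation(np.column_stack([v, y]))
            errors.append(abs(fit.v_half + 8.0))
        assert np.mean(errors) < 1.0

    def test_degenerate_input_raises(self):
        v = np.arange(-40.0, 0.0, 5.0)
        with pytest.raises(FitError):
            fit_boltzmann_activation(np.column_stack([v, np.full(v.size, 0.5)]))
        with pytest.raises(FitError):
            fit_boltzmann_activation(np.array([[0.0, 0.5], [1.0, 0.6]]))

    def test_invariant_to_grid_permutation(self):
        v = np.arange(-60.0, 41.0, 5.0)
        y = 1.0 / (1.0 + np.exp((v + 10.0) / -6.0))
        fit1 = fit_boltzmann_activation(np.column_stack([v, y]))
        perm = np.random.default_rng(0).permutation(v.size)
        fit2 = fit_boltzmann_activation(np.column_stack([v[perm], y[perm]]))
        assert fit1.v_half == pytest.approx(fit2.v_half, abs=1e-10)
        assert fit1.slope_k == pytest.approx(fit2.slope_k, abs=1e-10)


class TestBoltzmannInactivation:
    def test_recovers_printed_availability_parameters(self, wt):
        v = np.arange(-60.0, 60.5, 2.0)
        y = wt.inact_ss(v)
        fit = fit_boltzmann_inactivation(np.column_stack([v, y]))
        assert fit.v_half == pytest.approx(15.11, abs=1e-6)
        assert fit.slope_k == pytest.approx(7.57, abs=1e-6)
        assert fit.floor_ma == pytest.approx(0.46, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.52, abs=1e-6)

    def test_flat_data_degenerates_to_floor_with_flag(self):
        v = np.arange(-40.0, 20.0, 5.0)
        fit = fit_boltzmann_inactivation(np.column_stack([v, np.full(v.size, 0.37)]))
        assert fit.floor_ma == pytest.approx(0.37)
        assert fit.amplitude == 0.0
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_p488s_floor_shift_recovered_via_synthesis(self, wt):
        # generate synthetic clamp data with P488S truth, fit, compare floors
        from kcna5.ikur import mutant_model

        _, wt_fit, _ = fit_variant(wt_model(), is_wt=True)
        _, mut_fit, _ = fit_variant(mutant_model("P488S"))
        assert mut_fit.floor_ma - wt_fit.floor_ma == pytest.approx(-0.110,
                                                                   abs=1e-6)


class TestMonoExp:
    def test_exact_exponential(self):
        t = np.arange(0.0, 80.0, 0.1)
        tr = CurrentTrace(time=t, current=5.0 * (1 - np.exp(-t / 12.0)) + 0.3,
                          step_v=40.0)
        assert fit_monoexp_tau(tr, (0.0, float(t[-1]))) == pytest.approx(12.0, abs=1e-6)

    def test_decay_form(self):
        t = np.arange(0.0, 200.0, 0.5)
        tr = CurrentTrace(time=t, current=4.0 * np.exp(-t / 35.0) + 1.0,
                          step_v=40.0)
        assert fit_monoexp_tau(tr, (0.0, float(t[-1]))) == pytest.approx(35.0, abs=1e-6)

    def test_recovers_activation_time_constant_from_clamp_trace(self, wt):
        # at fixed voltage the activation phase is exactly exponential in the
        # a gate; with slow inactivation nearly frozen the fitted tau matches
        proto = ClampProtocol(step_voltages=(40.0,), step_duration=30.0,
                              sample_dt=0.02)
        (tr,) = simulate_voltage_clamp(wt, proto)
        window = default_activation_window(tr)
        tau = fit_monoexp_tau(tr, window)
        assert tau == pytest.approx(tau_activation(40.0, wt), rel=0.02)

    def test_non_monotone_window_raises(self):
        t = np.arange(0.0, 100.0, 0.5)
        tr = CurrentTrace(time=t, current=np.sin(t / 8.0), step_v=0.0)
        with pytest.raises(FitError):
            fit_monoexp_tau(tr, (0.0, float(t[-1])))

    def test_window_outside_trace_raises(self, wt):
        (tr,) = simulate_voltage_clamp(
            wt, ClampProtocol(step_voltages=(40.0,), step_duration=30.0))
        with pytest.raises(ValueError):
            fit_monoexp_tau(tr, (0.0, 500.0))


class TestQ10:
    def test_division_identities(self):
        assert apply_q10(3.52, 3.52) == 1.0
        assert apply_q10(49.94 * 0.29, KQ10) == pytest.approx(4.114, abs=5e-4)
        assert apply_q10(7.7, 1.0) == 7.7

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            apply_q10(-1.0, 3.52)
        with pytest.raises(ValueError):
            apply_q10(1.0, 0.0)


class TestRelativeChanges:
    def test_identical_fits_give_identity_delta(self, wt):
        act, inact, g = fit_variant(wt_model(), is_wt=True)
        d = derive_relative_changes(act, inact, g, act, inact, g)
        assert d.d_vhalf_act == 0.0
        assert d.k_act_factor == 1.0
        assert d.d_ma == 0.0
        assert d.g_factor == 1.0

    def test_d469e_roundtrip_inverse_composition(self):
        d = recover_delta("D469E")
        truth = TABLE1_DELTAS["D469E"]
        assert d.d_vhalf_act == pytest.approx(truth.d_vhalf_act, abs=1e-9)
        assert d.k_act_factor == pytest.approx(truth.k_act_factor, abs=1e-9)
        assert d.d_vhalf_inact == pytest.approx(truth.d_vhalf_inact, abs=1e-9)
        assert d.k_inact_factor == pytest.approx(truth.k_inact_factor, abs=1e-9)
        assert d.d_ma == pytest.approx(truth.d_ma, abs=1e-9)
        assert d.g_factor == pytest.approx(truth.g_factor, abs=1e-9)

    def test_e48g_generate_then_recover(self):
        d = recover_delta("E48G")
        assert d.d_vhalf_act == pytest.approx(-3.024, abs=1e-6)
        assert d.k_act_factor == pytest.approx(0.956, abs=1e-6)
        assert d.d_vhalf_inact == pytest.approx(+4.028, abs=1e-6)
        assert d.k_inact_factor == pytest.approx(0.940, abs=1e-6)
        assert d.d_ma == pytest.approx(+0.039, abs=1e-6)
        assert d.g_factor == pytest.approx(1.323, abs=1e-6)

    def test_zero_wt_conductance_guard(self, wt):
        act, inact, _ = fit_variant(wt_model(), is_wt=True)
        with pytest.raises(ZeroDivisionError):
            derive_relative_changes(act, inact, 0.0, act, inact, 1.0)


def test_recovery_error_degrades_monotonically_with_noise():
    """Mean absolute v_half recovery error grows with the noise level."""
    from kcna5.roundtrip import fit_variant as fv

    wt_ref = wt_equivalent_activation()
    maes = []
    for noise in (0.0, 0.01, 0.05, 0.10):
        errs = []
        for seed in range(8):
            act, _, _ = fv(wt_model(), noise_frac=noise, seed=seed * 13 + 1,
                           is_wt=True)
            errs.append(abs(act.v_half - wt_ref.v_half))
        maes.append(np.mean(errs))
    assert maes[0] < 1e-6
    assert maes[0] <= maes[1] <= maes[2] <= maes[3]
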