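"""Synthetic clamp-data generator: determinism, mixtures, point extraction."""

import numpy as np
import pytest

from kcna5.clamp import ClampProtocol, simulate_voltage_clamp
from kcna5.fitting import default_activation_window, fit_monoexp_tau
from kcna5.ikur import activation_steady_state, inactivation_steady_state
from kcna5.synthetic import ClampDataSpec, generate_traces, steady_state_points


@pytest.fixture(scope="module")
def proto():
    return ClampProtocol(step_voltages=tuple(range(-40, 61, 20)),
                         step_duration=300.0, sample_dt=0.5)


def test_noiseless_reproduces_deterministic_simulation(wt, proto):
    traces, truth = generate_traces(ClampDataSpec(truth=wt), proto)
    ref = simulate_voltage_clamp(wt, proto)
    for a, b in zip(traces, ref):
        assert np.array_equal(a.current, b.current)
    assert truth["label"] == "WT"


def test_same_seed_is_bit_identical(wt, proto):
    spec = ClampDataSpec(truth=wt, noise_sd=2.0, seed=42)
    t1, _ = generate_traces(spec, proto)
    t2, _ = generate_traces(spec, proto)
    for a, b in zip(t1, t2):
        assert np.array_equal(a.current, b.current)


def test_different_seed_differs(wt, proto):
    t1, _ = generate_traces(ClampDataSpec(truth=wt, noise_sd=2.0, seed=1), proto)
    t2, _ = generate_traces(ClampDataSpec(truth=wt, noise_sd=2.0, seed=2), proto)
    assert not np.array_equal(t1[0].current, t2[0].current)


def test_pure_fast_mixture_equals_fast_trace(wt, proto):
    mix, _ = generate_traces(
        ClampDataSpec(truth=wt, fast_slow=(0.5, 2.0, 1.0)), proto)
    fast = simulate_voltage_clamp(wt, proto, tau_act_scale=0.5)
    for a, b in zip(mix, fast):
        assert np.allclose(a.current, b.current, atol=1e-12)


def test_mixture_tau_lies_between_components(wt):
    # mono-exponential tau fitted to a w-mixture sits between the pure taus
    proto = ClampProtocol(step_voltages=(40.0,), step_duration=60.0,
                          sample_dt=0.05)
    taus = {}
    for w in (1.0, 0.5, 0.0):
        (tr,), _ = generate_traces(
            ClampDataSpec(truth=wt, fast_slow=(0.5, 2.0, w)), proto)
        taus[w] = fit_monoexp_tau(tr, (0.2, 20.0))
    assert taus[1.0] < taus[0.5] < taus[0.0]


def test_mixture_tau_monotone_on_w_grid(wt):
    proto = ClampProtocol(step_voltages=(40.0,), step_duration=60.0,
                          sample_dt=0.05)
    fitted = []
    for w in np.arange(0.0, 1.01, 0.1):
        (tr,), _ = generate_traces(
            ClampDataSpec(truth=wt, fast_slow=(0.5, 2.0, float(w))), proto)
        fitted.append(fit_monoexp_tau(tr, (0.2, 20.0)))
    lo = min(fitted[0], fitted[-1])
    hi = max(fitted[0], fitted[-1])
    assert all(lo - 1e-9 <= tau <= hi + 1e-9 for tau in fitted)


def test_leak_adds_linear_offset(wt, proto):
    clean, _ = generate_traces(ClampDataSpec(truth=wt), proto)
    leaky, _ = generate_traces(ClampDataSpec(truth=wt, leak_conductance=0.1),
                               proto)
    for a, b in zip(clean, leaky):
        assert np.allclose(b.current - a.current, 0.1 * a.step_v, atol=1e-12)


class TestSteadyStatePoints:
    @pytest.fixture(scope="class")
    def extracted(self, wt):
        act_proto = ClampProtocol(
            step_voltages=tuple(range(-60, 61, 10)), step_duration=200.0,
            sample_dt=0.5)
        avail_proto = ClampProtocol(
            step_voltages=tuple(range(-60, 61, 10)), step_duration=30000.0,
            tail_v=60.0, tail_duration=200.0, sample_dt=0.5)
        act, _ = generate_traces(ClampDataSpec(truth=wt), act_proto)
        avail, _ = generate_traces(ClampDataSpec(truth=wt), avail_proto,
                                   arm="availability")
        return steady_state_points(act, avail, avail_proto, shape_model=wt,
                                   t_measure=150.0)

    def test_noiseless_points_lie_on_steady_state_curves(self, wt, extracted):
        act_pts, avail_pts = extracted
        a_true = activation_steady_state(act_pts["v_mV"].to_numpy(), wt)
        i_true = inactivation_steady_state(avail_pts["v_mV"].to_numpy(), wt)
        assert np.max(np.abs(act_pts["value"].to_numpy() - a_true)) < 1e-6
        assert np.max(np.abs(avail_pts["value"].to_numpy() - i_true)) < 1e-6

    def test_noisy_point_means_converge_to_curve(self, wt):
        proto = ClampProtocol(step_voltages=(-20.0, 0.0, 20.0),
                              step_duration=200.0, sample_dt=0.5)
        avail_proto = ClampProtocol(step_voltages=(-20.0, 0.0, 20.0),
                                    step_duration=30000.0, tail_v=60.0,
                                    tail_duration=200.0, sample_dt=0.5)
        acc = []
        for seed in range(50):
            act, _ = generate_traces(
                ClampDataSpec(truth=wt, noise_sd=20.0, seed=seed), proto)
            avail, _ = generate_traces(
                ClampDataSpec(truth=wt, noise_sd=20.0, seed=seed + 500),
                avail_proto, arm="availability")
            pts, _ = steady_state_points(act, avail, avail_proto,
                                         shape_model=wt, t_measure=150.0)
            acc.append(pts["value"].to_numpy())
        mean_pts = np.mean(acc, axis=0)
        truth = activation_steady_state(np.array([-20.0, 0.0, 20.0]), wt)
        # Monte-Carlo error of the mean ~ sd/sqrt(50 x 41 samples)
        assert np.max(np.abs(mean_pts - truth)) < 0.02

    def test_zero_current_guard(self, wt):
        proto = ClampProtocol(step_voltages=(-87.0,), step_duration=200.0)
        act, _ = generate_traces(ClampDataSpec(truth=wt), proto, e_k=-87.0)
        with pytest.raises(ZeroDivisionError):
            steady_state_points(act, act, proto, e_k=-87.0, shape_model=wt)


def test_spec_validation():
    with pytest.raises(ValueError):
        ClampDataSpec(noise_sd=-1.0)
    with pytest.raises(ValueError):
        ClampDataSpec(fast_slow=(0.5, 2.0, 1.5))
    with pytest.raises(ValueError):
        ClampDataSpec(fast_slow=(-0.5, 2.0, 0.5))
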