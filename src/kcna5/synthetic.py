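"""Synthetic whole-cell voltage-clamp recordings with known ground truth.

Emulates the experimental Kv1.5 recordings the channel formulation was fitted
to, so the fitting stage can be validated by parameter recovery without any
external data:

* deterministic clamp traces from a ground-truth channel model,
* an optional mixture of fast and slow activation kinetics (experimental
  traces show two activation phenotypes across cells; the channel model uses
  their weighted mean), realised as two activation-time-constant scalings
  mixed with weight ``w``,
* optional linear seal leak,
* additive i.i.d. Gaussian recording noise, reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from kcna5.clamp import (
    DEFAULT_EK,
    ClampProtocol,
    CurrentTrace,
    simulate_voltage_clamp,
    simulate_availability,
)
from kcna5.ikur import (
    IKurModel,
    activation_steady_state,
    inactivation_steady_state,
    tau_activation,
    tau_inactivation,
    conductance_scale,
    wt_model,
)

__all__ = ["ClampDataSpec", "generate_traces", "steady_state_points", "write_dataset"]

#: Default fast/slow activation tau scalings and mixing weight.  The
#: underlying per-cell kinetic values were never published; these spreads are
#: an explicitly arbitrary but realistic two-population stand-in.
DEFAULT_FAST_SLOW = (0.5, 2.0, 0.5)


@dataclass(frozen=True)
class ClampDataSpec:
    """Specification of one synthetic clamp dataset.

    ``fast_slow`` is ``(fast_scale, slow_scale, w)``; the generated current is
    ``w * I_fast + (1 - w) * I_slow``.  ``None`` disables the mixture.
    """

    truth: IKurModel = field(default_factory=wt_model)
    noise_sd: float = 0.0
    fast_slow: tuple[float, float, float] | None = None
    leak_conductance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fast_slow is not None:
            fast, slow, w = self.fast_slow
            if fast <= 0 or slow <= 0:
                raise ValueError("tau scalings must be positive")
            if not (0.0 <= w <= 1.0):
                raise ValueError("mixing weight w must be in [0, 1]")


def _mix(traces_fast, traces_slow, w):
    mixed = []
    for tf, ts in zip(traces_fast, traces_slow):
        mixed.append(CurrentTrace(
            time=tf.time, current=w * tf.current + (1.0 - w) * ts.current,
            step_v=tf.step_v, label=tf.label))
    return mixed


def _simulate(spec, protocol, e_k, arm):
    sim = simulate_voltage_clamp if arm == "activation" else simulate_availability
    if spec.fast_slow is None:
        return sim(spec.truth, protocol, e_k)
    fast, slow, w = spec.fast_slow
    return _mix(sim(spec.truth, protocol, e_k, tau_act_scale=fast),
                sim(spec.truth, protocol, e_k, tau_act_scale=slow), w)


def generate_traces(
    spec: ClampDataSpec,
    protocol: ClampProtocol | None = None,
    e_k: float = DEFAULT_EK,
    arm: str = "activation",
) -> tuple[list[CurrentTrace], dict]:
    """Generate noisy clamp traces plus a ground-truth record.

    With ``noise_sd = 0``, no leak and no mixture the traces reproduce the
    deterministic clamp simulation exactly.  Identical seeds give bit-identical
    samples.  ``arm`` selects the activation step family or the two-pulse
    availability family.
    """
    if arm not in ("activation", "availability"):
        raise ValueError("arm must be 'activation' or 'availability'")
    protocol = protocol or ClampProtocol()
    traces = _simulate(spec, protocol, e_k, arm)
    rng = np.random.default_rng(spec.seed)
    for tr in traces:
        v_seg = tr.step_v if arm == "activation" else protocol.tail_v
        if spec.leak_conductance:
            tr.current = tr.current + spec.leak_conductance * v_seg
        if spec.noise_sd:
            tr.current = tr.current + rng.normal(0.0, spec.noise_sd, tr.current.shape)
    truth = {
        "label": spec.truth.label,
        "act_ss": [asdict(b) for b in spec.truth.act_ss],
        "inact_ss": asdict(spec.truth.inact_ss),
        "g_factor": spec.truth.g_factor,
        "kq10": spec.truth.kq10,
        "noise_sd": spec.noise_sd,
        "fast_slow": spec.fast_slow,
        "leak_conductance": spec.leak_conductance,
        "seed": spec.seed,
        "arm": arm,
        "e_k": e_k,
    }
    return traces, truth


def steady_state_points(
    act_traces: list[CurrentTrace],
    avail_traces: list[CurrentTrace],
    protocol: ClampProtocol,
    e_k: float = DEFAULT_EK,
    shape_model: IKurModel | None = None,
    t_measure: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract normalised activation / availability sample tables.

    Activation points: current at ``t_measure`` into each step (activation is
    complete, inactivation barely progressed), converted to conductance with
    the driving force and divided by the known voltage-dependence *shape* of
    the maximal conductance (``shape_model``; the shape is part of the channel
    formulation, while its magnitude stays free).  The slow inactivation
    reached by ``t_measure`` and the availability occupied at the holding
    potential are divided out using the shape model's inactivation kinetics.
    The resulting points equal a_inf times a free scale (the relative maximal
    conductance), which the activation fit recovers as its amplitude.

    Availability points: early test-pulse current per conditioning voltage,
    corrected by driving force, the shape model's *absolute* conductance
    (including its g_factor) and the activation reached during the test-pulse
    measurement window, then inverted for the inactivation decay between
    prepulse end and measurement.  When ``shape_model`` is the generator's
    truth record the points equal the availability at the prepulse end
    exactly; with the default WT shape they are the usual experimental
    approximation.

    Raises ZeroDivisionError when the maximal measured current is zero.
    """
    shape = shape_model or wt_model()

    rows = []
    for tr in act_traces:
        v = tr.step_v
        sel = np.abs(tr.time - t_measure) <= 10.0  # 20 ms averaging window
        if not np.any(sel):
            sel = np.array([np.argmin(np.abs(tr.time - t_measure))])
        cur = tr.current[sel]
        drive = v - e_k
        if drive == 0.0:
            continue
        g_shape = conductance_scale(v, shape) / shape.g_factor
        # inactivation progress from holding, per sample in the window
        i0 = float(inactivation_steady_state(protocol.holding_v, shape))
        i_inf = float(inactivation_steady_state(v, shape))
        ti = float(tau_inactivation(v, shape))
        i_t = i_inf + (i0 - i_inf) * np.exp(-tr.time[sel] / ti)
        rows.append({"v_mV": v, "value": float(np.mean(cur / (drive * g_shape * i_t)))})
    act_points = pd.DataFrame(rows)
    if act_points.empty or np.max(np.abs(act_points["value"])) == 0.0:
        raise ZeroDivisionError("zero maximal activation current")

    rows = []
    v_test = protocol.tail_v
    drive = v_test - e_k
    g_abs_t = conductance_scale(v_test, shape)
    for tr in avail_traces:
        t_meas = min(30.0, float(tr.time[-1]))
        sel = np.abs(tr.time - t_meas) <= 10.0
        if not np.any(sel):
            sel = np.array([np.argmin(np.abs(tr.time - t_meas))])
        cur = tr.current[sel]
        # activation reached during the test pulse (from the prepulse level)
        a0 = float(activation_steady_state(tr.step_v, shape))
        a_inf = float(activation_steady_state(v_test, shape))
        ta = float(tau_activation(v_test, shape))
        a_t = a_inf + (a0 - a_inf) * np.exp(-tr.time[sel] / ta)
        # inactivation decay between prepulse end and each sample time
        i_pre_inf = float(inactivation_steady_state(v_test, shape))
        ti = float(tau_inactivation(v_test, shape))
        decay = np.exp(-tr.time[sel] / ti)
        raw = cur / (drive * g_abs_t * a_t)
        # raw = i_inf_test + (i_pre - i_inf_test) * decay  ->  solve for i_pre
        rows.append({"v_mV": tr.step_v,
                     "value": float(np.mean((raw - i_pre_inf * (1.0 - decay)) / decay))})
    avail_points = pd.DataFrame(rows)
    if avail_points.empty or np.max(np.abs(avail_points["value"])) == 0.0:
        raise ZeroDivisionError("zero maximal availability current")
    return act_points, avail_points


def write_dataset(path, traces: list[CurrentTrace], truth: dict) -> None:
    """Write traces as CSV with the ground-truth record as a JSON sidecar."""
    from kcna5.clamp import traces_to_frame

    path = Path(path)
    traces_to_frame(traces).to_csv(path, index=False)
    path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))
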