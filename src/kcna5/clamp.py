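"""Simulated whole-cell voltage-clamp of I_Kur variants.

At a fixed command voltage the two Hodgkin-Huxley gates relax exponentially
toward their steady states with the model time constants, so each protocol
segment is integrated in closed form (Rush-Larsen stepping at the sampling
interval, which is exact for piecewise-constant voltage).

Two protocol arms are provided:

* activation arm: hold, then a family of depolarising steps; the I-V table
  records the end-of-step (default, I_Kur inactivates slowly) or peak current
  per step voltage;
* availability (two-pulse) arm: a long conditioning prepulse to each step
  voltage followed by a fixed test pulse, whose early current reports the
  channel availability reached during the prepulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kcna5.ikur import (
    IKurModel,
    activation_steady_state,
    inactivation_steady_state,
    tau_activation,
    tau_inactivation,
    ikur_current,
)

__all__ = [
    "DEFAULT_EK",
    "ClampProtocol",
    "CurrentTrace",
    "simulate_voltage_clamp",
    "simulate_availability",
    "iv_table",
    "traces_to_frame",
]

#: Default K+ reversal potential (mV) for standalone clamp simulations.
DEFAULT_EK = -87.0


@dataclass(frozen=True)
class ClampProtocol:
    """Step voltage-clamp protocol.

    ``step_voltages`` are the command potentials of the step family;
    ``tail_v`` is the test-pulse potential of the availability arm.
    """

    holding_v: float = -80.0
    step_voltages: tuple[float, ...] = tuple(float(v) for v in range(-40, 61, 10))
    step_duration: float = 1500.0
    interpulse_duration: float = 5000.0
    tail_v: float = 60.0
    tail_duration: float = 500.0
    sample_dt: float = 0.5

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if not self.step_voltages:
            raise ValueError("step_voltages must be non-empty")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")


@dataclass
class CurrentTrace:
    """A sampled current trace for one voltage step."""

    time: np.ndarray
    current: np.ndarray
    step_v: float
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


def _gate_course(t, g0, g_inf, tau):
    return g_inf + (g0 - g_inf) * np.exp(-t / tau)


def _segment_current(model, v, a0, i0, t, e_k, tau_act_scale=1.0):
    """Closed-form gate time courses and current over one fixed-V segment."""
    a_inf = activation_steady_state(v, model)
    i_inf = inactivation_steady_state(v, model)
    ta = tau_activation(v, model) * tau_act_scale
    ti = tau_inactivation(v, model)
    a = _gate_course(t, a0, a_inf, ta)
    i = _gate_course(t, i0, i_inf, ti)
    cur = ikur_current(v, a, i, e_k, model)
    if not np.all(np.isfinite(cur)):
        raise FloatingPointError(f"non-finite clamp current at step {v} mV")
    return a, i, cur


def simulate_voltage_clamp(
    model: IKurModel,
    protocol: ClampProtocol | None = None,
    e_k: float = DEFAULT_EK,
    tau_act_scale: float = 1.0,
) -> list[CurrentTrace]:
    """Activation-arm clamp: one trace per step voltage.

    Gates start from their steady state at the holding potential.
    ``tau_act_scale`` rescales the activation time constant (used by the
    synthetic-data generator to emulate fast/slow kinetic populations).
    """
    protocol = protocol or ClampProtocol()
    a0 = float(activation_steady_state(protocol.holding_v, model))
    i0 = float(inactivation_steady_state(protocol.holding_v, model))
    n = int(round(protocol.step_duration / protocol.sample_dt)) + 1
    t = np.arange(n) * protocol.sample_dt
    traces = []
    for v in protocol.step_voltages:
        _, _, cur = _segment_current(model, v, a0, i0, t, e_k, tau_act_scale)
        traces.append(CurrentTrace(time=t.copy(), current=cur, step_v=float(v),
                                   label=model.label))
    return traces


def simulate_availability(
    model: IKurModel,
    protocol: ClampProtocol | None = None,
    e_k: float = DEFAULT_EK,
    tau_act_scale: float = 1.0,
) -> list[CurrentTrace]:
    """Availability (two-pulse) arm: test-pulse traces after conditioning.

    Each conditioning prepulse lasts ``step_duration`` at the step voltage;
    the returned traces cover the test pulse at ``tail_v`` only, with the
    prepulse voltage recorded in ``step_v``.
    """
    protocol = protocol or ClampProtocol()
    a_hold = float(activation_steady_state(protocol.holding_v, model))
    i_hold = float(inactivation_steady_state(protocol.holding_v, model))
    n = int(round(protocol.tail_duration / protocol.sample_dt)) + 1
    t = np.arange(n) * protocol.sample_dt
    t_end = np.array([protocol.step_duration])
    traces = []
    for v in protocol.step_voltages:
        a_pre, i_pre, _ = _segment_current(
            model, v, a_hold, i_hold, t_end, e_k, tau_act_scale)
        _, _, cur = _segment_current(
            model, protocol.tail_v, float(a_pre[0]), float(i_pre[0]), t, e_k,
            tau_act_scale)
        traces.append(CurrentTrace(time=t.copy(), current=cur, step_v=float(v),
                                   label=model.label))
    return traces


def iv_table(traces: list[CurrentTrace], measure: str = "end") -> pd.DataFrame:
    """I-V relation: per-step current measured at end of step or at the peak."""
    if measure not in ("end", "peak"):
        raise ValueError("measure must be 'end' or 'peak'")
    rows = []
    for tr in traces:
        if measure == "end":
            cur = float(tr.current[-1])
        else:
            cur = float(tr.current[np.argmax(np.abs(tr.current))])
        rows.append({"step_v_mV": tr.step_v, "current_pA_per_pF": cur})
    return pd.DataFrame(rows).sort_values("step_v_mV", ignore_index=True)


def traces_to_frame(traces: list[CurrentTrace]) -> pd.DataFrame:
    """Long-format table (step_v_mV, time_ms, current_pA_per_pF) for CSV export."""
    frames = [
        pd.DataFrame({
            "step_v_mV": tr.step_v,
            "time_ms": tr.time,
            "current_pA_per_pF": tr.current,
        })
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)
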