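"""Hodgkin-Huxley formulation of the atrial ultra-rapid delayed rectifier I_Kur.

The wild-type (WT) channel is described by

* a steady-state activation that is the product of two Boltzmann factors,
* a single-Boltzmann steady-state inactivation with a non-zero floor
  ("minimum availability", the fraction of channels that never inactivate),
* bi-sigmoidal activation and mono-sigmoidal inactivation time constants,
  divided by a Q10 temperature-correction factor KQ10 = 3.52 (recordings at
  room temperature, simulations at 37 C),
* a maximal conductance with an explicit sigmoidal voltage dependence.

Six KCNA5 mutations are represented as relative changes to the WT Boltzmann
parameters and conductance (additive half-activation voltage shifts,
multiplicative slope and conductance factors, additive minimum-availability
change); the time constants are kept identical to WT.

Voltage is in mV, time in ms throughout.  The printed conductance expression
is interpreted as a whole-cell conductance in nS; when the current is embedded
in a cell model it is normalised by the membrane capacitance (CM_NORM_PF) to
yield pA/pF.  Standalone operations return the direct product of conductance,
gates and driving force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KQ10",
    "CM_NORM_PF",
    "BoltzmannParams",
    "IKurModel",
    "MutantDelta",
    "TABLE1_DELTAS",
    "MUTANT_ALIASES",
    "GAIN_OF_FUNCTION",
    "LOSS_OF_FUNCTION",
    "canonical_mutant_label",
    "boltzmann",
    "wt_model",
    "wt_equivalent_activation",
    "apply_mutant",
    "activation_steady_state",
    "inactivation_steady_state",
    "tau_activation",
    "tau_inactivation",
    "conductance_scale",
    "ikur_current",
    "step_gates",
]

#: Q10 temperature correction factor applied to both gate time constants.
KQ10 = 3.52

#: Membrane capacitance (pF) used to convert the whole-cell nS conductance
#: expression into a pA/pF current density inside a host cell model.
CM_NORM_PF = 100.0

# Activation time constant (ms, before Q10 division):
#   tau_a = (A1/(1+exp((V+Vt1)/k1)) + C1) * (A2/(1+exp((V+Vt2)/k2)) + C2)
TAU_ACT_PARAMS = (45.67, 11.23, 11.53, 4.27, 0.26, 35.87, -3.88, 0.29)

# Inactivation time constant (ms, before Q10 division):
#   tau_i = A/(1+exp((V-Vt)/k)) + C
TAU_INACT_PARAMS = (2328.0, 9.44, 3.58, 1739.14)

# Voltage-dependent maximal conductance (whole-cell nS):
#   g(V) = c0 * (c1 + c2/(1+exp((V - vh)/k)))
G_PARAMS = (0.64, 4.51, 1.90, 20.52, -8.27)


@dataclass(frozen=True)
class BoltzmannParams:
    """One Boltzmann factor: amplitude/(1+exp((V-v_half)/slope_k)) + floor_ma.

    ``slope_k`` is signed: negative for rising (activation-type) sigmoids,
    positive for falling (inactivation-type) ones.  ``floor_ma`` is the
    minimum availability (0 for activation).
    """

    v_half: float
    slope_k: float
    amplitude: float = 1.0
    floor_ma: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_k == 0:
            raise ValueError("slope_k must be non-zero")
        if not (0.0 <= self.floor_ma < 1.0):
            raise ValueError(f"floor_ma must be in [0, 1): {self.floor_ma}")
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError(f"amplitude must be in (0, 1]: {self.amplitude}")
        if self.amplitude + self.floor_ma > 1.0 + 1e-9:
            raise ValueError("amplitude + floor_ma must not exceed 1")

    def __call__(self, v):
        return boltzmann(v, self.v_half, self.slope_k, self.amplitude, self.floor_ma)


def boltzmann(v, v_half, slope_k, amplitude=1.0, floor=0.0):
    """Evaluate amplitude/(1+exp((v-v_half)/slope_k)) + floor (vectorised)."""
    return amplitude / (1.0 + np.exp((np.asarray(v, dtype=float) - v_half) / slope_k)) + floor


@dataclass(frozen=True)
class MutantDelta:
    """Relative changes of a mutant channel with respect to WT.

    Half-(in)activation voltages shift additively (mV), slope factors and
    maximal conductance multiply, minimum availability shifts additively.
    """

    d_vhalf_act: float
    k_act_factor: float
    d_vhalf_inact: float
    k_inact_factor: float
    d_ma: float
    g_factor: float

    def __post_init__(self) -> None:
        if self.k_act_factor <= 0 or self.k_inact_factor <= 0:
            raise ValueError("slope factors must be positive")
        if self.g_factor < 0:
            raise ValueError("g_factor must be non-negative")


#: Identity record (a "mutant" indistinguishable from WT).
IDENTITY_DELTA = MutantDelta(0.0, 1.0, 0.0, 1.0, 0.0, 1.0)

#: The six published KCNA5 mutant parameter-change records.
TABLE1_DELTAS: dict[str, MutantDelta] = {
    "D332H": MutantDelta(-3.264, 0.809, +9.615, 0.801, +0.074, 1.799),
    "E48G": MutantDelta(-3.024, 0.956, +4.028, 0.940, +0.039, 1.323),
    "A305T": MutantDelta(-4.068, 1.101, +6.032, 0.748, +0.071, 1.445),
    "Y155C": MutantDelta(-0.893, 0.757, +5.013, 0.782, +0.035, 0.475),
    "D469E": MutantDelta(0.0, 1.0, +4.545, 0.842, -0.093, 0.546),
    "P488S": MutantDelta(0.0, 0.834, -1.415, 0.688, -0.110, 0.038),
}

#: The same variant appears in the literature under two residue numberings.
MUTANT_ALIASES: dict[str, str] = {"D322H": "D332H"}

GAIN_OF_FUNCTION = ("D332H", "E48G", "A305T")
LOSS_OF_FUNCTION = ("Y155C", "D469E", "P488S")


def canonical_mutant_label(label: str) -> str:
    """Resolve aliases to the canonical mutant label; raise on unknown names."""
    label = MUTANT_ALIASES.get(label, label)
    if label not in TABLE1_DELTAS and label != "WT":
        raise KeyError(
            f"unknown mutant label {label!r}; known: "
            f"{sorted(TABLE1_DELTAS)} (+ aliases {sorted(MUTANT_ALIASES)})"
        )
    return label


@dataclass(frozen=True)
class IKurModel:
    """Full parameterisation of one I_Kur variant.

    ``act_ss`` is a tuple of Boltzmann factors whose product is the
    steady-state activation: two factors for the WT formulation, one for
    mutant variants (built on the WT-equivalent single-Boltzmann fit).
    """

    label: str
    act_ss: tuple[BoltzmannParams, ...]
    inact_ss: BoltzmannParams
    tau_act_params: tuple[float, ...] = TAU_ACT_PARAMS
    tau_inact_params: tuple[float, ...] = TAU_INACT_PARAMS
    kq10: float = KQ10
    g_params: tuple[float, ...] = G_PARAMS
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kq10 <= 0:
            raise ValueError("kq10 must be positive")
        if self.g_factor < 0:
            raise ValueError("g_factor must be non-negative")
        if not self.act_ss:
            raise ValueError("act_ss needs at least one Boltzmann factor")


def wt_model() -> IKurModel:
    """The wild-type I_Kur parameterisation."""
    return IKurModel(
        label="WT",
        act_ss=(
            BoltzmannParams(v_half=-17.67, slope_k=-5.75),
            BoltzmannParams(v_half=-8.45, slope_k=-11.51),
        ),
        inact_ss=BoltzmannParams(v_half=15.11, slope_k=7.57, amplitude=0.52, floor_ma=0.46),
    )


@lru_cache(maxsize=1)
def wt_equivalent_activation() -> BoltzmannParams:
    """Single-Boltzmann least-squares equivalent of the WT activation product.

    Fitted on a 1 mV grid over [-60, +60] mV (the voltage-clamp range used
    for the steady-state curves).  Mutant parameter changes are applied to
    this fit, matching the single-Boltzmann form in which the mutant data
    were reported; the WT model itself keeps the exact two-factor product.
    """
    from kcna5.fitting import fit_boltzmann_activation  # deferred: avoids cycle

    wt = wt_model()
    v = np.arange(-60.0, 60.0 + 0.5, 1.0)
    target = activation_steady_state(v, wt)
    fit = fit_boltzmann_activation(np.column_stack([v, target]))
    return BoltzmannParams(v_half=fit.v_half, slope_k=fit.slope_k)


def apply_mutant(delta: MutantDelta, label: str = "mutant") -> IKurModel:
    """Build a mutant I_Kur model by applying a relative-change record to WT.

    Activation: the WT-equivalent single Boltzmann with v_half shifted and
    slope multiplied.  Inactivation: WT parameters with v_half shifted, slope
    multiplied and the minimum-availability floor shifted additively (clipped
    to [0, 1)); the amplitude is adjusted so amplitude + floor is preserved
    (the mutant data were reported in the normalised (1-MA)/... + MA form, so
    a raised floor reduces the inactivating span).  Time constants and the
    voltage dependence of the conductance are copied from WT unchanged; the
    conductance is scaled multiplicatively.
    """
    if delta.k_act_factor <= 0 or delta.k_inact_factor <= 0:
        raise ValueError("slope factors must be positive")
    wt = wt_model()
    act_eq = wt_equivalent_activation()
    act = BoltzmannParams(
        v_half=act_eq.v_half + delta.d_vhalf_act,
        slope_k=act_eq.slope_k * delta.k_act_factor,
    )
    span = wt.inact_ss.amplitude + wt.inact_ss.floor_ma
    floor = float(np.clip(wt.inact_ss.floor_ma + delta.d_ma, 0.0, 1.0 - 1e-12))
    amplitude = min(span - floor, 1.0 - floor)
    inact = BoltzmannParams(
        v_half=wt.inact_ss.v_half + delta.d_vhalf_inact,
        slope_k=wt.inact_ss.slope_k * delta.k_inact_factor,
        amplitude=amplitude,
        floor_ma=floor,
    )
    return replace(wt, label=label, act_ss=(act,), inact_ss=inact,
                   g_factor=wt.g_factor * delta.g_factor)


def mutant_model(label: str) -> IKurModel:
    """Convenience constructor from a published mutant label (aliases ok)."""
    label = canonical_mutant_label(label)
    if label == "WT":
        return wt_model()
    return apply_mutant(TABLE1_DELTAS[label], label=label)


# ---------------------------------------------------------------------------
# Channel operations (total functions of voltage; vectorised over v)
# ---------------------------------------------------------------------------

def activation_steady_state(v, model: IKurModel):
    """Steady-state activation a_inf(v) in [0, 1]."""
    out = np.ones_like(np.asarray(v, dtype=float))
    for b in model.act_ss:
        out = out * b(v)
    return out if out.ndim else float(out)


def inactivation_steady_state(v, model: IKurModel):
    """Steady-state inactivation (availability) i_inf(v) in [floor, floor+amp]."""
    out = model.inact_ss(v)
    return out if np.ndim(out) else float(out)


def tau_activation(v, model: IKurModel):
    """Activation time constant (ms), Q10-corrected."""
    a1, vt1, k1, c1, a2, vt2, k2, c2 = model.tau_act_params
    v = np.asarray(v, dtype=float)
    tau = (a1 / (1.0 + np.exp((v + vt1) / k1)) + c1) * (
        a2 / (1.0 + np.exp((v + vt2) / k2)) + c2
    )
    tau = tau / model.kq10
    return tau if tau.ndim else float(tau)


def tau_inactivation(v, model: IKurModel):
    """Inactivation time constant (ms), Q10-corrected."""
    a, vt, k, c = model.tau_inact_params
    v = np.asarray(v, dtype=float)
    tau = (a / (1.0 + np.exp((v - vt) / k)) + c) / model.kq10
    return tau if tau.ndim else float(tau)


def conductance_scale(v, model: IKurModel):
    """Voltage-dependent maximal conductance (whole-cell nS), times g_factor."""
    c0, c1, c2, vh, k = model.g_params
    v = np.asarray(v, dtype=float)
    g = c0 * (c1 + c2 / (1.0 + np.exp((v - vh) / k))) * model.g_factor
    return g if g.ndim else float(g)


def ikur_current(v, a, i, e_k, model: IKurModel):
    """I_Kur = g(V) * a * i * (V - E_K) (whole-cell nS times mV -> pA)."""
    out = conductance_scale(v, model) * np.asarray(a) * np.asarray(i) * (
        np.asarray(v, dtype=float) - e_k
    )
    return out if np.ndim(out) else float(out)


def step_gates(state, v, dt, model: IKurModel):
    """Advance the (a, i) gate pair by dt at fixed voltage (Rush-Larsen).

    The update is the exact exponential relaxation toward the steady state,
    hence unconditionally stable for any dt >= 0.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    a, i = state
    a_inf = activation_steady_state(v, model)
    i_inf = inactivation_steady_state(v, model)
    ea = math.exp(-dt / tau_activation(v, model))
    ei = math.exp(-dt / tau_inactivation(v, model))
    return (a_inf + (a - a_inf) * ea, i_inf + (i - i_inf) * ei)
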