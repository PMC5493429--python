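"""Shared numba-side I_Kur parameter block and gate kinetics.

Both atrial cell models carry a small block of I_Kur parameters inside their
parameter vectors so that tissue kernels can hold heterogeneous channel
variants per node:

====  ==========================================================
slot  meaning
====  ==========================================================
0     mode: 0 = the model's native I_Kur, 1 = the new formulation
1-4   activation Boltzmann(s): vh1, k1, vh2, k2 (k2 = 0 -> single)
5-8   inactivation Boltzmann: vh, k, amplitude, floor (minimum availability)
9     conductance factor (mutant g_factor x variant scalings)
====  ==========================================================

In mode 1 the two I_Kur gate state slots relax with the new formulation's
Q10-corrected time constants and the current uses its voltage-dependent
maximal conductance (whole-cell nS, normalised by the 100 pF reference
capacitance).  In mode 0 the host model's native kinetics are used and the
Boltzmann block redefines the native steady-state curves (how mutant
relative changes enter the unmodified lineage models).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from kcna5.ikur import (
    CM_NORM_PF,
    KQ10,
    IKurModel,
)

__all__ = ["N_IKUR_PAR", "ikur_param_block", "new_ikur_rates", "new_ikur_g"]

N_IKUR_PAR = 10


def ikur_param_block(model: IKurModel | None, native_inact_amp: float = 1.0,
                     native_act=(0.0, -1.0), native_inact=(0.0, 1.0),
                     g_factor: float = 1.0) -> np.ndarray:
    """Build the 10-slot I_Kur block.

    ``model=None`` selects the native current (mode 0) with the supplied
    native Boltzmann parameters (already delta-adjusted by the caller);
    otherwise mode 1 with the new formulation's parameters.
    """
    blk = np.zeros(N_IKUR_PAR)
    if model is None:
        blk[0] = 0.0
        blk[1], blk[2] = native_act
        blk[3], blk[4] = 0.0, 0.0
        blk[5], blk[6] = native_inact
        blk[7] = native_inact_amp
        blk[8] = max(0.0, 1.0 - native_inact_amp)
        blk[9] = g_factor
        return blk
    blk[0] = 1.0
    acts = model.act_ss
    blk[1], blk[2] = acts[0].v_half, acts[0].slope_k
    if len(acts) > 1:
        blk[3], blk[4] = acts[1].v_half, acts[1].slope_k
    blk[5] = model.inact_ss.v_half
    blk[6] = model.inact_ss.slope_k
    blk[7] = model.inact_ss.amplitude
    blk[8] = model.inact_ss.floor_ma
    blk[9] = model.g_factor * g_factor
    return blk


@njit(cache=True)
def _sig(x):
    # overflow-safe logistic 1/(1+exp(x))
    if x > 0.0:
        e = math.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=True)
def new_ikur_rates(v, blk):
    """(a_inf, tau_a, i_inf, tau_i) of the block's steady states with the
    new formulation's Q10-corrected time constants."""
    a_inf = _sig((v - blk[1]) / blk[2])
    if blk[4] != 0.0:
        a_inf *= _sig((v - blk[3]) / blk[4])
    i_inf = blk[7] * _sig((v - blk[5]) / blk[6]) + blk[8]
    tau_a = (45.67 * _sig((v + 11.23) / 11.53) + 4.27) * (
        0.26 * _sig((v + 35.87) / -3.88) + 0.29) / KQ10
    tau_i = (2328.0 * _sig((v - 9.44) / 3.58) + 1739.14) / KQ10
    return a_inf, tau_a, i_inf, tau_i


@njit(cache=True)
def new_ikur_g(v, blk):
    """Voltage-dependent maximal conductance (pA/pF per mV) incl. g factor."""
    return 0.64 * (4.51 + 1.90 * _sig((v - 20.52) / -8.27)) * blk[9] / CM_NORM_PF
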