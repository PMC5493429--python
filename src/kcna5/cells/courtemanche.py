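"""Courtemanche-lineage human atrial myocyte model (21 state variables).

Reimplementation of the classic human atrial action-potential model
(fast Na+, transient outward, ultra-rapid/rapid/slow delayed rectifier and
inward rectifier K+ currents, L-type Ca2+ current, Na+/K+ pump, Na+/Ca2+
exchanger, sarcolemmal Ca2+ pump, background currents, and a two-compartment
sarcoplasmic reticulum with Ca2+-induced Ca2+ release), in per-capacitance
units (pA/pF), voltages in mV, time in ms, concentrations in mM.

The ultra-rapid delayed rectifier slot is switchable (see
:mod:`kcna5.cells.ikurshared`): mode 0 keeps the model's native I_Kur
(cubed activation gate) with its steady-state Boltzmann curves optionally
redefined by mutant relative changes; mode 1 swaps in the new I_Kur
formulation (the updated-lineage variant of this model).

Gates advance by Rush-Larsen exponential updates; voltage and concentrations
by forward Euler.  dt up to 0.02 ms is stable; 0.005 ms is the single-cell
default.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from kcna5.cells.ikurshared import N_IKUR_PAR, _sig, new_ikur_g, new_ikur_rates

__all__ = ["N_STATE", "N_PAR", "default_params", "initial_state", "step",
           "step_fast", "make_tables", "PAR_INDEX", "STATE_INDEX"]

# --- physical constants -------------------------------------------------
R = 8.3143
T = 310.0
F = 96.4867
RTF = R * T / F
CM = 100.0          # pF
V_I = 13668.0       # myoplasm volume, um^3
V_UP = 1109.52      # network SR
V_REL = 96.48       # junctional SR
KO = 5.4
NAO = 140.0
CAO = 1.8
SIGMA = (math.exp(NAO / 67.3) - 1.0) / 7.0

# --- state layout -------------------------------------------------------
STATE_INDEX = {
    "v": 0, "m": 1, "h": 2, "j": 3, "oa": 4, "oi": 5, "ua": 6, "ui": 7,
    "xr": 8, "xs": 9, "d": 10, "f": 11, "fca": 12, "u": 13, "vrel": 14,
    "w": 15, "nai": 16, "ki": 17, "cai": 18, "caup": 19, "carel": 20,
    # aliases for the switchable I_Kur gate pair
    "a_kur": 6, "i_kur": 7,
}
N_STATE = 21

# --- parameter layout ---------------------------------------------------
PAR_INDEX = {
    "g_na": 0, "g_k1": 1, "g_to": 2, "g_kr": 3, "g_ks": 4, "g_cal": 5,
    "g_bca": 6, "g_bna": 7, "i_nak_max": 8, "k_naca": 9, "i_pca_max": 10,
    "k_rel": 11, "i_up_max": 12, "k_up": 13,
    "ikur": 14,  # start of the shared 10-slot I_Kur block
}
N_PAR = 14 + N_IKUR_PAR


def default_params() -> np.ndarray:
    """Published baseline parameter vector with the native I_Kur block."""
    p = np.zeros(N_PAR)
    p[0] = 7.8
    p[1] = 0.09
    p[2] = 0.1652
    p[3] = 0.029411765
    p[4] = 0.12941176
    p[5] = 0.12375
    p[6] = 0.001131
    p[7] = 0.0006744375
    p[8] = 0.59933874
    p[9] = 1600.0
    p[10] = 0.275
    p[11] = 30.0
    p[12] = 0.005
    p[13] = 0.00092
    blk = p[14:]
    blk[0] = 0.0                   # native I_Kur
    blk[1], blk[2] = -30.3, -9.6   # ua_inf Boltzmann
    blk[5], blk[6] = 99.45, 27.48  # ui_inf Boltzmann
    blk[7], blk[8] = 1.0, 0.0
    blk[9] = 1.0
    return p


def initial_state() -> np.ndarray:
    """Published resting conditions."""
    u = np.zeros(N_STATE)
    u[0] = -81.18
    u[1] = 2.908e-3
    u[2] = 9.649e-1
    u[3] = 9.775e-1
    u[4] = 3.043e-2
    u[5] = 9.992e-1
    u[6] = 4.966e-3
    u[7] = 9.986e-1
    u[8] = 3.296e-5
    u[9] = 1.869e-2
    u[10] = 1.367e-4
    u[11] = 9.996e-1
    u[12] = 7.755e-1
    u[13] = 2.35e-112
    u[14] = 1.0
    u[15] = 9.992e-1
    u[16] = 1.117e1
    u[17] = 1.39e2
    u[18] = 1.013e-4
    u[19] = 1.488
    u[20] = 1.488
    return u


@njit(cache=True)
def step(u, p, dt, istim):  # noqa: C901 - one flat kernel by design
    """Advance the full state in place by dt (ms); istim in pA/pF."""
    v = u[0]
    nai = u[16]
    ki = u[17]
    cai = u[18]

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(KO / ki)
    e_ca = 0.5 * RTF * math.log(CAO / cai)

    # --- fast Na+ current gates
    if abs(v + 47.13) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * math.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp(-(v + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23)))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    i_na = p[0] * u[1] ** 3 * u[2] * u[3] * (v - e_na)

    # --- transient outward
    a_oa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    tau_oa = 1.0 / ((a_oa + b_oa) * 3.0)
    oa_inf = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    tau_oi = 1.0 / ((a_oi + b_oi) * 3.0)
    oi_inf = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))
    i_to = p[2] * u[4] ** 3 * u[5] * (v - e_k)

    # --- ultra-rapid delayed rectifier (switchable block)
    blk = p[14:14 + N_IKUR_PAR]
    if blk[0] < 0.5:
        # native kinetics; Boltzmann curves from the block
        a_ua = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
        b_ua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
        tau_a = 1.0 / ((a_ua + b_ua) * 3.0)
        a_inf = _sig((v - blk[1]) / blk[2])
        a_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
        b_ui = math.exp((v - 158.0) / 16.0)
        tau_i = 1.0 / ((a_ui + b_ui) * 3.0)
        i_inf = blk[7] * _sig((v - blk[5]) / blk[6]) + blk[8]
        g_kur = (0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))) * blk[9]
        i_kur = g_kur * u[6] ** 3 * u[7] * (v - e_k)
    else:
        a_inf, tau_a, i_inf, tau_i = new_ikur_rates(v, blk)
        i_kur = new_ikur_g(v, blk) * u[6] * u[7] * (v - e_k)

    # --- rapid delayed rectifier
    if abs(v + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (v + 14.1) / (1.0 - math.exp(-(v + 14.1) / 5.0))
    if abs(v - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * (v - 3.3328) / (math.exp((v - 3.3328) / 5.1237) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    xr_inf = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5))
    i_kr = p[3] * u[8] * (v - e_k) / (1.0 + math.exp((v + 15.0) / 22.4))

    # --- slow delayed rectifier
    if abs(v - 19.9) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * (v - 19.9) / (1.0 - math.exp(-(v - 19.9) / 17.0))
        b_xs = 3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1.0)
    tau_xs = 0.5 / (a_xs + b_xs)
    xs_inf = 1.0 / math.sqrt(1.0 + math.exp(-(v - 19.9) / 12.7))
    i_ks = p[4] * u[9] ** 2 * (v - e_k)

    # --- L-type Ca2+ current
    if abs(v + 10.0) < 1e-10:
        tau_d = 2.2894737
    else:
        ed = math.exp(-(v + 10.0) / 6.24)
        tau_d = (1.0 - ed) / (0.035 * (v + 10.0) * (1.0 + ed))
    d_inf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 8.0))
    tau_f = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    f_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    i_cal = p[5] * u[10] * u[11] * u[12] * (v - 65.0)

    # --- pumps, exchangers, background
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                   + 0.0365 * SIGMA * math.exp(-v / RTF))
    i_nak = p[8] * f_nak / (1.0 + (10.0 / nai) ** 1.5) * KO / (KO + 1.5)
    evg = math.exp(0.35 * v / RTF)
    evg1 = math.exp((0.35 - 1.0) * v / RTF)
    i_naca = p[9] * (evg * nai ** 3 * CAO - evg1 * NAO ** 3 * cai) / (
        (87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1.0 + 0.1 * evg1))
    i_pca = p[10] * cai / (0.0005 + cai)
    i_bna = p[7] * (v - e_na)
    i_bca = p[6] * (v - e_ca)
    i_k1 = p[1] * (v - e_k) / (1.0 + math.exp(0.07 * (v + 80.0)))

    # --- SR Ca2+ handling
    i_rel = p[11] * u[13] ** 2 * u[14] * u[15] * (u[20] - cai)
    fn = 1000.0 * (1e-15 * V_REL * i_rel
                   - 1e-15 / (2.0 * F) * (0.5 * i_cal * CM - 0.2 * i_naca * CM))
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau_v_g = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    if abs(v - 7.9) < 1e-10:
        tau_w = 0.9231
    else:
        ew = math.exp(-(v - 7.9) / 5.0)
        tau_w = 6.0 * (1.0 - ew) / ((1.0 + 0.3 * ew) * (v - 7.9))
    w_inf = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))
    i_up = p[12] / (1.0 + p[13] / cai)
    i_up_leak = p[12] * u[19] / 15.0
    i_tr = (u[19] - u[20]) / 180.0

    # --- membrane potential
    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca)
    u[0] = v + dt * (-(i_ion + istim))

    # --- Rush-Larsen gate updates
    m_inf = am / (am + bm)
    tau_m = 1.0 / (am + bm)
    h_inf = ah / (ah + bh)
    tau_h = 1.0 / (ah + bh)
    j_inf = aj / (aj + bj)
    tau_j = 1.0 / (aj + bj)
    u[1] = m_inf + (u[1] - m_inf) * math.exp(-dt / tau_m)
    u[2] = h_inf + (u[2] - h_inf) * math.exp(-dt / tau_h)
    u[3] = j_inf + (u[3] - j_inf) * math.exp(-dt / tau_j)
    u[4] = oa_inf + (u[4] - oa_inf) * math.exp(-dt / tau_oa)
    u[5] = oi_inf + (u[5] - oi_inf) * math.exp(-dt / tau_oi)
    u[6] = a_inf + (u[6] - a_inf) * math.exp(-dt / tau_a)
    u[7] = i_inf + (u[7] - i_inf) * math.exp(-dt / tau_i)
    u[8] = xr_inf + (u[8] - xr_inf) * math.exp(-dt / tau_xr)
    u[9] = xs_inf + (u[9] - xs_inf) * math.exp(-dt / tau_xs)
    u[10] = d_inf + (u[10] - d_inf) * math.exp(-dt / tau_d)
    u[11] = f_inf + (u[11] - f_inf) * math.exp(-dt / tau_f)
    u[12] = fca_inf + (u[12] - fca_inf) * math.exp(-dt / 2.0)
    u[13] = u_inf + (u[13] - u_inf) * math.exp(-dt / 8.0)
    u[14] = v_inf + (u[14] - v_inf) * math.exp(-dt / tau_v_g)
    u[15] = w_inf + (u[15] - w_inf) * math.exp(-dt / tau_w)

    # --- ionic concentrations (forward Euler)
    u[16] = nai + dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    u[17] = ki + dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * CM / (F * V_I)
    b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I) \
        + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I
    b2 = 1.0 + 0.07 * 0.0005 / (cai + 0.0005) ** 2 + 0.05 * 0.00238 / (cai + 0.00238) ** 2
    u[18] = cai + dt * b1 / b2
    u[19] = u[19] + dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    u[20] = u[20] + dt * (i_tr - i_rel) / (1.0 + 10.0 * 0.8 / (u[20] + 0.8) ** 2)


# ---------------------------------------------------------------------------
# Table-driven fast kernel
# ---------------------------------------------------------------------------
# All parameter-independent voltage functions (gate steady states, Rush-Larsen
# decay factors for a fixed dt, current shape factors) are pre-sampled on a
# fine voltage grid and linearly interpolated inside the hot loop.  The
# I_Kur block's steady-state curves stay analytic because mutant variants
# redefine them per parameter vector.  ``step_fast(u, p, tab, dt, istim)``
# reproduces ``step`` to interpolation accuracy (<1e-6 on gate curves).

V_MIN = -150.0
V_STEP = 0.05
N_V = int(round((100.0 - V_MIN) / V_STEP)) + 1
N_TAB = 33


def make_tables(dt: float) -> np.ndarray:
    """Voltage tables for ``step_fast`` at a fixed time step."""
    v = V_MIN + V_STEP * np.arange(N_V)
    tab = np.empty((N_V, N_TAB))

    def dec(tau):
        return np.exp(-dt / tau)

    with np.errstate(divide="ignore", invalid="ignore"):
        am = np.where(np.abs(v + 47.13) < 1e-10, 3.2,
                      0.32 * (v + 47.13) / (1.0 - np.exp(-0.1 * (v + 47.13))))
    bm = 0.08 * np.exp(-v / 11.0)
    hi = v >= -40.0
    ah = np.where(hi, 0.0, 0.135 * np.exp(-(v + 80.0) / 6.8))
    bh = np.where(hi, 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
                  3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v))
    aj = np.where(hi, 0.0,
                  (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
                  * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
    bj = np.where(hi, 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
                  0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))))
    tab[:, 0] = am / (am + bm)
    tab[:, 1] = dec(1.0 / (am + bm))
    tab[:, 2] = ah / (ah + bh)
    tab[:, 3] = dec(1.0 / (ah + bh))
    tab[:, 4] = aj / (aj + bj)
    tab[:, 5] = dec(1.0 / (aj + bj))

    a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tab[:, 6] = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
    tab[:, 7] = dec(1.0 / ((a_oa + b_oa) * 3.0))
    a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    tab[:, 8] = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))
    tab[:, 9] = dec(1.0 / ((a_oi + b_oi) * 3.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        a_xr = np.where(np.abs(v + 14.1) < 1e-10, 0.0015,
                        0.0003 * (v + 14.1) / (1.0 - np.exp(-(v + 14.1) / 5.0)))
        b_xr = np.where(np.abs(v - 3.3328) < 1e-10, 3.7836118e-4,
                        7.3898e-5 * (v - 3.3328) / (np.exp((v - 3.3328) / 5.1237) - 1.0))
    tab[:, 10] = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))
    tab[:, 11] = dec(1.0 / (a_xr + b_xr))
    sing = np.abs(v - 19.9) < 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        a_xs = np.where(sing, 0.00068,
                        4e-5 * (v - 19.9) / (1.0 - np.exp(-(v - 19.9) / 17.0)))
        b_xs = np.where(sing, 0.000315,
                        3.5e-5 * (v - 19.9) / (np.exp((v - 19.9) / 9.0) - 1.0))
    tab[:, 12] = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))
    tab[:, 13] = dec(0.5 / (a_xs + b_xs))

    ed = np.exp(-(v + 10.0) / 6.24)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_d = np.where(np.abs(v + 10.0) < 1e-10, 2.2894737,
                         (1.0 - ed) / (0.035 * (v + 10.0) * (1.0 + ed)))
    tab[:, 14] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0))
    tab[:, 15] = dec(tau_d)
    tab[:, 16] = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))
    tab[:, 17] = dec(9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02))

    ew = np.exp(-(v - 7.9) / 5.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_w = np.where(np.abs(v - 7.9) < 1e-10, 0.9231,
                         6.0 * (1.0 - ew) / ((1.0 + 0.3 * ew) * (v - 7.9)))
    tab[:, 18] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))
    tab[:, 19] = dec(tau_w)

    tab[:, 20] = dec(1.0 / ((a_oa + b_oa) * 3.0))  # native ua shares oa rates
    a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b_ui = np.exp((v - 158.0) / 16.0)
    tab[:, 21] = dec(1.0 / ((a_ui + b_ui) * 3.0))
    tab[:, 22] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))

    from kcna5.ikur import KQ10 as _KQ10
    tau_a_new = (45.67 / (1.0 + np.exp((v + 11.23) / 11.53)) + 4.27) * (
        0.26 / (1.0 + np.exp((v + 35.87) / -3.88)) + 0.29) / _KQ10
    tau_i_new = (2328.0 / (1.0 + np.exp((v - 9.44) / 3.58)) + 1739.14) / _KQ10
    tab[:, 23] = dec(tau_a_new)
    tab[:, 24] = dec(tau_i_new)
    tab[:, 25] = 0.64 * (4.51 + 1.90 / (1.0 + np.exp((v - 20.52) / -8.27))) / 100.0

    tab[:, 26] = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
    tab[:, 27] = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
    tab[:, 28] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                        + 0.0365 * SIGMA * np.exp(-v / RTF))
    tab[:, 29] = np.exp(0.35 * v / RTF)
    tab[:, 30] = np.exp((0.35 - 1.0) * v / RTF)
    tab[:, 31] = math.exp(-dt / 2.0)   # fca gate
    tab[:, 32] = math.exp(-dt / 8.0)   # u release gate
    return tab


@njit(cache=True)
def step_fast(u, p, tab, dt, istim):  # noqa: C901
    """Table-driven variant of :func:`step` (same state/parameter layout)."""
    v = u[0]
    nai = u[16]
    ki = u[17]
    cai = u[18]

    pos = (v - V_MIN) / V_STEP
    if pos < 0.0:
        pos = 0.0
    elif pos > N_V - 2:
        pos = N_V - 2.0
    ii = int(pos)
    w = pos - ii
    r0 = tab[ii]
    r1 = tab[ii + 1]

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(KO / ki)
    e_ca = 0.5 * RTF * math.log(CAO / cai)

    i_na = p[0] * u[1] ** 3 * u[2] * u[3] * (v - e_na)
    i_to = p[2] * u[4] ** 3 * u[5] * (v - e_k)

    blk = p[14:14 + N_IKUR_PAR]
    if blk[0] < 0.5:
        a_inf = _sig((v - blk[1]) / blk[2])
        i_inf = blk[7] * _sig((v - blk[5]) / blk[6]) + blk[8]
        dec_a = r0[20] + w * (r1[20] - r0[20])
        dec_i = r0[21] + w * (r1[21] - r0[21])
        g_kur = (r0[22] + w * (r1[22] - r0[22])) * blk[9]
        i_kur = g_kur * u[6] ** 3 * u[7] * (v - e_k)
    else:
        a_inf = _sig((v - blk[1]) / blk[2])
        if blk[4] != 0.0:
            a_inf *= _sig((v - blk[3]) / blk[4])
        i_inf = blk[7] * _sig((v - blk[5]) / blk[6]) + blk[8]
        dec_a = r0[23] + w * (r1[23] - r0[23])
        dec_i = r0[24] + w * (r1[24] - r0[24])
        g_new = (r0[25] + w * (r1[25] - r0[25])) * blk[9]
        i_kur = g_new * u[6] * u[7] * (v - e_k)

    i_kr = p[3] * u[8] * (v - e_k) * (r0[27] + w * (r1[27] - r0[27]))
    i_ks = p[4] * u[9] ** 2 * (v - e_k)
    i_cal = p[5] * u[10] * u[11] * u[12] * (v - 65.0)
    f_nak = r0[28] + w * (r1[28] - r0[28])
    i_nak = p[8] * f_nak / (1.0 + (10.0 / nai) ** 1.5) * KO / (KO + 1.5)
    evg = r0[29] + w * (r1[29] - r0[29])
    evg1 = r0[30] + w * (r1[30] - r0[30])
    i_naca = p[9] * (evg * nai ** 3 * CAO - evg1 * NAO ** 3 * cai) / (
        (87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1.0 + 0.1 * evg1))
    i_pca = p[10] * cai / (0.0005 + cai)
    i_bna = p[7] * (v - e_na)
    i_bca = p[6] * (v - e_ca)
    i_k1 = p[1] * (v - e_k) * (r0[26] + w * (r1[26] - r0[26]))

    i_rel = p[11] * u[13] ** 2 * u[14] * u[15] * (u[20] - cai)
    fn = 1000.0 * (1e-15 * V_REL * i_rel
                   - 1e-15 / (2.0 * F) * (0.5 * i_cal * CM - 0.2 * i_naca * CM))
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau_v_g = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    i_up = p[12] / (1.0 + p[13] / cai)
    i_up_leak = p[12] * u[19] / 15.0
    i_tr = (u[19] - u[20]) / 180.0

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca)
    u[0] = v + dt * (-(i_ion + istim))

    # table gate order: m h j oa oi xr xs d f -> state slots 1-5, 8-11
    for g in range(9):
        c_inf = 2 * g
        gi = g + 1 if g < 5 else g + 3
        inf = r0[c_inf] + w * (r1[c_inf] - r0[c_inf])
        de = r0[c_inf + 1] + w * (r1[c_inf + 1] - r0[c_inf + 1])
        u[gi] = inf + (u[gi] - inf) * de
    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    u[12] = fca_inf + (u[12] - fca_inf) * r0[31]
    u[13] = u_inf + (u[13] - u_inf) * r0[32]
    u[14] = v_inf + (u[14] - v_inf) * math.exp(-dt / tau_v_g)
    w_inf = r0[18] + w * (r1[18] - r0[18])
    u[15] = w_inf + (u[15] - w_inf) * (r0[19] + w * (r1[19] - r0[19]))
    u[6] = a_inf + (u[6] - a_inf) * dec_a
    u[7] = i_inf + (u[7] - i_inf) * dec_i

    u[16] = nai + dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    u[17] = ki + dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * CM / (F * V_I)
    b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I) \
        + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I
    b2 = 1.0 + 0.07 * 0.0005 / (cai + 0.0005) ** 2 + 0.05 * 0.00238 / (cai + 0.00238) ** 2
    u[18] = cai + dt * b1 / b2
    u[19] = u[19] + dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    u[20] = u[20] + dt * (i_tr - i_rel) / (1.0 + 10.0 * 0.8 / (u[20] + 0.8) ** 2)
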