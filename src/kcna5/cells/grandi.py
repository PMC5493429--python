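"""Grandi-lineage human atrial myocyte model (20 state variables).

A reimplementation of the Grandi-style human atrial electrophysiology:
ten Tusscher-type fast Na+ current, Maleckar-style I_Kur, fast transient
outward current, rapid/slow delayed rectifiers, inward rectifier, plateau K+
and Ca2+-activated/background Cl- currents, GHK-type L-type Ca2+ current
with voltage- and Ca2+-dependent inactivation, Na+/Ca2+ exchange with
allosteric Ca2+ activation, Na+/K+ pump, sarcolemmal Ca2+ pump and
background currents.  The intracellular Ca2+ system is consolidated to
three pools -- junctional cleft (receiving I_CaL and ryanodine-receptor
release), bulk cytosol and sarcoplasmic reticulum (SERCA with forward/
reverse Michaelis terms, passive leak, Shannon-type four-state ryanodine
receptor with luminal Ca2+ regulation) -- rather than the published model's
junctional/subsarcolemmal split.  Parameters of the consolidated Ca2+
subsystem were calibrated during model construction to the published
lineage's headline behaviours: resting potential near -74 mV, APD90 near
300 ms at 1 Hz with a dome-less, triangular action potential, a small
(~0.2 uM) Ca2+ transient, and the native susceptibility to phase-2
early-after-depolarisations under beta-adrenergic stimulation combined
with loss of I_Kur.

Intracellular K+ is held constant (as in the published lineage).  Units:
mV, ms, mM, currents in A/F (pA/pF).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from kcna5.cells.ikurshared import N_IKUR_PAR, _sig, new_ikur_g, new_ikur_rates

__all__ = ["N_STATE", "N_PAR", "default_params", "initial_state", "step",
           "PAR_INDEX", "STATE_INDEX", "KI_FIXED", "KO"]

# --- physical constants / geometry --------------------------------------
RTF = 26.712832          # mV at 310 K
KO = 5.4
NAO = 140.0
CAO = 1.8
KI_FIXED = 120.0
E_CL = -61.47            # Cl- reversal (15 mM in / 150 mM out)

CM = 1.1e-10             # F
FARADAY = 96485.0
V_CELL = 3.30e-11        # L
V_MYO = 0.65 * V_CELL
V_SR = 0.035 * V_CELL
V_JUNC = 5.39e-4 * V_CELL

CONV_MYO = CM / (2.0 * FARADAY * V_MYO)    # A/F -> mM/ms (divalent, cytosol)
CONV_MYO_NA = CM / (FARADAY * V_MYO)       # A/F -> mM/ms (monovalent)
CONV_JUNC = CM / (2.0 * FARADAY * V_JUNC)  # A/F -> mM/ms (divalent, cleft)
VJ_VM = V_JUNC / V_MYO
VSR_VJ = V_SR / V_JUNC
VM_VSR = V_MYO / V_SR

STATE_INDEX = {
    "v": 0, "m": 1, "h": 2, "j": 3, "d": 4, "f": 5, "fcb": 6,
    "xto": 7, "yto": 8, "xkr": 9, "xks": 10, "a_kur": 11, "i_kur": 12,
    "u_rel": 13, "v_rel": 14, "w_rel": 15,
    "caj": 16, "cai": 17, "casr": 18, "nai": 19, "f2": 20,
}
N_STATE = 21

PAR_INDEX = {
    "g_na": 0, "g_nab": 1, "i_nak_max": 2, "g_kr": 3, "g_ks": 4, "g_to": 5,
    "g_k1": 6, "g_kp": 7, "g_clca": 8, "g_clb": 9, "g_cal": 10, "ncx_max": 11,
    "pmca_max": 12, "g_cab": 13, "serca_vmax": 14, "serca_km": 15,
    "serca_kmr": 16, "rel_krel": 17,
    "ikur": 18,
}
N_PAR = 18 + N_IKUR_PAR

#: plateau timescale (ms) of the slow L-type inactivation gate
F2_TAU_PLATEAU = 500.0

# consolidated Ca2+ subsystem constants (calibrated; see module docstring)
TAU_JDIFF = 0.1          # junctional-to-cytosol Ca2+ equilibration, ms
BMAX_J, KM_J = 0.25, 0.013          # junctional membrane buffer
BMAX_CSQN, KM_CSQN = 2.6, 0.65      # SR calsequestrin (SR-referenced)
SR_LEAK = 1.0e-4         # passive SR leak rate, /ms (cytosol-referenced)


def default_params() -> np.ndarray:
    p = np.zeros(N_PAR)
    p[0] = 23.0
    p[1] = 0.597e-3
    p[2] = 1.8
    p[3] = 0.035
    p[4] = 0.0035
    p[5] = 0.10
    p[6] = 0.0525
    p[7] = 0.002
    p[8] = 0.0548
    p[9] = 9.0e-3
    p[10] = 2.25
    p[11] = 3.15
    p[12] = 0.0471
    p[13] = 6.0643e-4
    p[14] = 5.3114e-3
    p[15] = 3.5e-4
    p[16] = 1.7
    p[17] = 4.0
    blk = p[18:]
    blk[0] = 0.0                  # native Maleckar-style I_Kur
    blk[1], blk[2] = -6.0, -8.6   # activation Boltzmann
    blk[5], blk[6] = 7.5, 10.0    # inactivation Boltzmann
    blk[7], blk[8] = 1.0, 0.0
    blk[9] = 0.045                # conductance (mS/uF) x variant factors
    return p


def initial_state() -> np.ndarray:
    """Approximate resting conditions (quiescent-equilibrated)."""
    u = np.zeros(N_STATE)
    u[0] = -74.0
    u[1] = 1.4e-3
    u[2] = 0.95
    u[3] = 0.96
    u[4] = 1.0e-5
    u[5] = 1.0
    u[6] = 0.02
    u[7] = 4.0e-3
    u[8] = 0.94
    u[9] = 8.0e-3
    u[10] = 6.0e-3
    u[11] = 3.0e-4
    u[12] = 0.95
    u[13] = 0.0
    u[14] = 1.0
    u[15] = 0.99
    u[16] = 2.0e-4
    u[17] = 2.0e-4
    u[18] = 0.55
    u[19] = 9.1
    u[20] = 1.0
    return u


@njit(cache=True)
def step(u, p, dt, istim):  # noqa: C901 - one flat kernel by design
    """Advance the full state in place by dt (ms); istim in pA/pF."""
    v = u[0]
    caj = u[16]
    cai = u[17]
    casr = u[18]
    nai = u[19]

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(KO / KI_FIXED)
    e_ca = 0.5 * RTF * math.log(CAO / cai)

    # --- fast Na+ current
    m_inf = 1.0 / (1.0 + math.exp(-(56.86 + v) / 9.03)) ** 2
    tau_m = 0.1292 * math.exp(-((v + 45.79) / 15.54) ** 2) \
        + 0.06487 * math.exp(-((v - 4.823) / 51.12) ** 2)
    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        aj = (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23)))
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    tau_h = 1.0 / (ah + bh)
    tau_j = 1.0 / (aj + bj)
    j_inf = h_inf
    i_na = p[0] * u[1] ** 3 * u[2] * u[3] * (v - e_na)
    i_nab = p[1] * (v - e_na)

    # --- Na+/K+ pump
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                   + 0.0365 * sigma * math.exp(-v / RTF))
    i_nak = p[2] * f_nak * KO / (KO + 1.5) / (1.0 + (11.0 / nai) ** 4)

    # --- rapid delayed rectifier
    xr_inf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 5.0))
    tau_xr = 550.0 / (1.0 + math.exp(-(22.0 + v) / 9.0)) * 6.0 / (
        1.0 + math.exp((v + 11.0) / 9.0)) + 230.0 / (1.0 + math.exp((v + 40.0) / 20.0))
    r_kr = 1.0 / (1.0 + math.exp((v + 74.0) / 24.0))
    i_kr = p[3] * u[9] * r_kr * (v - e_k)

    # --- slow delayed rectifier
    e_ks = RTF * math.log((KO + 0.01833 * NAO) / (KI_FIXED + 0.01833 * nai))
    xs_inf = 1.0 / (1.0 + math.exp(-(v + 3.8) / 14.25))
    tau_xs = 990.1 / (1.0 + math.exp(-(v + 2.436) / 14.12))
    i_ks = p[4] * u[10] ** 2 * (v - e_ks)

    # --- fast transient outward
    xto_inf = 1.0 / (1.0 + math.exp(-(v + 1.0) / 11.0))
    tau_xto = 3.5 * math.exp(-((v / 30.0) ** 2)) + 1.5
    yto_inf = 1.0 / (1.0 + math.exp((v + 40.5) / 11.5))
    tau_yto = 25.635 * math.exp(-(((v + 52.45) / 15.8827) ** 2)) + 24.14
    i_to = p[5] * u[7] * u[8] * (v - e_k)

    # --- ultra-rapid delayed rectifier (switchable block)
    blk = p[18:18 + N_IKUR_PAR]
    if blk[0] < 0.5:
        a_inf = _sig((v - blk[1]) / blk[2])
        tau_a = 9.0 / (1.0 + math.exp((v + 5.0) / 12.0)) + 0.5
        i_inf = blk[7] * _sig((v - blk[5]) / blk[6]) + blk[8]
        tau_i = 590.0 / (1.0 + math.exp((v + 60.0) / 10.0)) + 3050.0
        i_kur = blk[9] * u[11] * u[12] * (v - e_k)
    else:
        a_inf, tau_a, i_inf, tau_i = new_ikur_rates(v, blk)
        i_kur = new_ikur_g(v, blk) * u[11] * u[12] * (v - e_k)

    # --- inward rectifier
    dvk = v - e_k
    aki = 1.02 / (1.0 + math.exp(0.2385 * (dvk - 59.215)))
    bki = (0.49124 * math.exp(0.08032 * (dvk + 5.476))
           + math.exp(0.06175 * (dvk - 594.31))) / (
        1.0 + math.exp(-0.5143 * (dvk + 4.753)))
    i_k1 = p[6] * aki / (aki + bki) * dvk

    # --- plateau K+ and Cl- currents
    i_kp = p[7] * (v - e_k) / (1.0 + math.exp(7.488 - v / 5.98))
    i_clca = p[8] / (1.0 + 0.1 / cai) * (v - E_CL)
    i_clb = p[9] * (v - E_CL)

    # --- L-type Ca2+ current (GHK driving term on cleft Ca2+)
    z = 2.0 * v / RTF
    if abs(z) < 1e-6:
        driv = 0.5 * RTF * 0.341 * (caj - CAO)
    else:
        driv = v * 0.341 * (caj * math.exp(z) - CAO) / (math.exp(z) - 1.0)
    d_inf = 1.0 / (1.0 + math.exp(-(v + 9.0) / 6.0))
    if abs(v + 9.0) < 1e-10:
        tau_d = d_inf / 0.035 / 6.0
    else:
        tau_d = d_inf * (1.0 - math.exp(-(v + 9.0) / 6.0)) / (0.035 * (v + 9.0))
    f_inf = 1.0 / (1.0 + math.exp((v + 30.0) / 7.0)) \
        + 0.2 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_f = 1.0 / (0.0197 * math.exp(-((0.0337 * (v + 14.5)) ** 2)) + 0.02)
    # slow voltage-dependent inactivation: accumulates over sustained
    # plateaus (bounds EAD salvos), recovers within a diastolic interval
    f2_inf = 0.005 + 0.995 / (1.0 + math.exp((v + 45.0) / 4.0))
    tau_f2 = 150.0 + F2_TAU_PLATEAU / (1.0 + math.exp(-(v + 55.0) / 8.0))
    i_cal = p[10] * driv * u[4] * u[5] * u[20] * (1.0 - u[6])

    # --- Na+/Ca2+ exchange (allosteric Ca2+ activation)
    ka = 1.0 / (1.0 + (3.84e-4 / caj) ** 2)
    ez = math.exp(0.35 * v / RTF)
    ez1 = math.exp((0.35 - 1.0) * v / RTF)
    s1 = ez * nai ** 3 * CAO
    s2 = ez1 * NAO ** 3 * cai
    s3 = 3.59e-3 * NAO ** 3 * (1.0 + (nai / 12.29) ** 3) \
        + 87.5 ** 3 * cai * (1.0 + cai / 3.59e-3) \
        + 1.3 * nai ** 3 + nai ** 3 * CAO + NAO ** 3 * cai
    i_ncx = p[11] * ka * (s1 - s2) / (s3 * (1.0 + 0.27 * ez1))

    # --- sarcolemmal Ca2+ pump and backgrounds
    i_pmca = p[12] * cai ** 1.6 / (5.0e-4 ** 1.6 + cai ** 1.6)
    i_cab = p[13] * (v - e_ca)

    # --- SR fluxes
    qf = (cai / p[15]) ** 1.787
    qr = (casr / p[16]) ** 1.787
    j_up = p[14] * (qf - qr) / (1.0 + qf + qr)
    j_leak = SR_LEAK * (casr - cai)
    # flux-gated Ca2+-induced Ca2+ release: activation gate u driven by the
    # net Ca2+ influx trigger (L-type + exchanger) plus release feedback,
    # flux-inactivation gate vv, voltage-refractoriness gate w.  Strictly
    # triggered and self-terminating: no diastolic-leak fixed point.
    j_rel = p[17] * u[13] * u[13] * u[14] * u[15] * (casr - caj)  # cleft-ref.
    fn = 0.5 * j_rel - (0.5 * i_cal - 0.2 * i_ncx)
    urel_inf = 1.0 / (1.0 + math.exp(-(fn - 0.6) / 0.12))
    vrel_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 0.12) / 0.012))
    tau_vrel = 1.91 + 2.09 * urel_inf
    if abs(v - 7.9) < 1e-10:
        tau_wrel = 0.9231
    else:
        ewr = math.exp(-(v - 7.9) / 5.0)
        tau_wrel = 6.0 * (1.0 - ewr) / ((1.0 + 0.3 * ewr) * (v - 7.9))
    wrel_inf = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))

    # --- membrane potential
    i_ion = (i_na + i_nab + i_nak + i_kr + i_ks + i_to + i_kur + i_k1 + i_kp
             + i_clca + i_clb + i_cal + i_ncx + i_pmca + i_cab)
    u[0] = v + dt * (-(i_ion + istim))

    # --- Rush-Larsen gates
    u[1] = m_inf + (u[1] - m_inf) * math.exp(-dt / tau_m)
    u[2] = h_inf + (u[2] - h_inf) * math.exp(-dt / tau_h)
    u[3] = j_inf + (u[3] - j_inf) * math.exp(-dt / tau_j)
    u[4] = d_inf + (u[4] - d_inf) * math.exp(-dt / tau_d)
    u[5] = f_inf + (u[5] - f_inf) * math.exp(-dt / tau_f)
    u[6] = u[6] + dt * (1.7 * caj * (1.0 - u[6]) - 11.9e-3 * u[6])
    u[7] = xto_inf + (u[7] - xto_inf) * math.exp(-dt / tau_xto)
    u[8] = yto_inf + (u[8] - yto_inf) * math.exp(-dt / tau_yto)
    u[9] = xr_inf + (u[9] - xr_inf) * math.exp(-dt / tau_xr)
    u[10] = xs_inf + (u[10] - xs_inf) * math.exp(-dt / tau_xs)
    u[11] = a_inf + (u[11] - a_inf) * math.exp(-dt / tau_a)
    u[12] = i_inf + (u[12] - i_inf) * math.exp(-dt / tau_i)
    u[13] = urel_inf + (u[13] - urel_inf) * math.exp(-dt / 8.0)
    u[14] = vrel_inf + (u[14] - vrel_inf) * math.exp(-dt / tau_vrel)
    u[15] = wrel_inf + (u[15] - wrel_inf) * math.exp(-dt / tau_wrel)

    # --- Ca2+ pools (buffered, semi-implicit cleft coupling)
    beta_j = 1.0 / (1.0 + BMAX_J * KM_J / (KM_J + caj) ** 2)
    src_j = -i_cal * CONV_JUNC + j_rel * 1.0
    # implicit treatment of the fast cleft-cytosol equilibration
    rate = beta_j * dt / TAU_JDIFF
    u[16] = (caj + dt * beta_j * src_j + rate * cai) / (1.0 + rate)

    beta_i = 1.0 / (1.0 + 0.07 * 6.0e-4 / (6.0e-4 + cai) ** 2
                    + 0.024 * 7.0e-3 / (7.0e-3 + cai) ** 2
                    + 0.0171 * 8.7e-4 / (8.7e-4 + cai) ** 2)
    src_i = -(i_cab + i_pmca - 2.0 * i_ncx) * CONV_MYO \
        - j_up + j_leak + (u[16] - cai) / TAU_JDIFF * VJ_VM
    u[17] = cai + dt * beta_i * src_i

    beta_sr = 1.0 / (1.0 + BMAX_CSQN * KM_CSQN / (KM_CSQN + casr) ** 2)
    src_sr = (j_up - j_leak) * VM_VSR - j_rel / VSR_VJ * 1.0
    u[18] = casr + dt * beta_sr * src_sr

    u[19] = nai + dt * (-(i_na + i_nab + 3.0 * i_nak + 3.0 * i_ncx) * CONV_MYO_NA)
    u[20] = f2_inf + (u[20] - f2_inf) * math.exp(-dt / tau_f2)


# ---------------------------------------------------------------------------
# Table-driven fast kernel (see the Courtemanche module for the rationale)
# ---------------------------------------------------------------------------

V_MIN = -150.0
V_STEP = 0.05
N_V = int(round((100.0 - V_MIN) / V_STEP)) + 1
N_TAB = 35


def make_tables(dt: float) -> np.ndarray:
    """Voltage tables for ``step_fast`` at a fixed time step."""
    v = V_MIN + V_STEP * np.arange(N_V)
    tab = np.empty((N_V, N_TAB))

    def dec(tau):
        return np.exp(-dt / tau)

    m_inf = 1.0 / (1.0 + np.exp(-(56.86 + v) / 9.03)) ** 2
    tau_m = 0.1292 * np.exp(-((v + 45.79) / 15.54) ** 2) \
        + 0.06487 * np.exp(-((v - 4.823) / 51.12) ** 2)
    h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    hi = v >= -40.0
    ah = np.where(hi, 0.0, 0.057 * np.exp(-(v + 80.0) / 6.8))
    bh = np.where(hi, 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
                  2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v))
    aj = np.where(hi, 0.0,
                  (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
                  * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
    bj = np.where(hi, 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
                  0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))))
    tab[:, 0] = m_inf
    tab[:, 1] = dec(tau_m)
    tab[:, 2] = h_inf
    tab[:, 3] = dec(1.0 / (ah + bh))
    tab[:, 4] = h_inf
    tab[:, 5] = dec(1.0 / (aj + bj))

    d_inf = 1.0 / (1.0 + np.exp(-(v + 9.0) / 6.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_d = np.where(np.abs(v + 9.0) < 1e-10, d_inf / 0.035 / 6.0,
                         d_inf * (1.0 - np.exp(-(v + 9.0) / 6.0)) / (0.035 * (v + 9.0)))
    f_inf = 1.0 / (1.0 + np.exp((v + 30.0) / 7.0)) \
        + 0.2 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_f = 1.0 / (0.0197 * np.exp(-((0.0337 * (v + 14.5)) ** 2)) + 0.02)
    f2_inf = 0.005 + 0.995 / (1.0 + np.exp((v + 45.0) / 4.0))
    tau_f2 = 150.0 + F2_TAU_PLATEAU / (1.0 + np.exp(-(v + 55.0) / 8.0))
    tab[:, 6] = d_inf
    tab[:, 7] = dec(tau_d)
    tab[:, 8] = f_inf
    tab[:, 9] = dec(tau_f)
    tab[:, 10] = f2_inf
    tab[:, 11] = dec(tau_f2)

    tab[:, 12] = 1.0 / (1.0 + np.exp(-(v + 1.0) / 11.0))
    tab[:, 13] = dec(3.5 * np.exp(-((v / 30.0) ** 2)) + 1.5)
    tab[:, 14] = 1.0 / (1.0 + np.exp((v + 40.5) / 11.5))
    tab[:, 15] = dec(25.635 * np.exp(-(((v + 52.45) / 15.8827) ** 2)) + 24.14)

    tab[:, 16] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 5.0))
    tau_xr = 550.0 / (1.0 + np.exp(-(22.0 + v) / 9.0)) * 6.0 / (
        1.0 + np.exp((v + 11.0) / 9.0)) + 230.0 / (1.0 + np.exp((v + 40.0) / 20.0))
    tab[:, 17] = dec(tau_xr)
    tab[:, 18] = 1.0 / (1.0 + np.exp(-(v + 3.8) / 14.25))
    tab[:, 19] = dec(990.1 / (1.0 + np.exp(-(v + 2.436) / 14.12)))

    tab[:, 20] = dec(9.0 / (1.0 + np.exp((v + 5.0) / 12.0)) + 0.5)
    tab[:, 21] = dec(590.0 / (1.0 + np.exp((v + 60.0) / 10.0)) + 3050.0)

    from kcna5.ikur import KQ10 as _KQ10
    tau_a_new = (45.67 / (1.0 + np.exp((v + 11.23) / 11.53)) + 4.27) * (
        0.26 / (1.0 + np.exp((v + 35.87) / -3.88)) + 0.29) / _KQ10
    tau_i_new = (2328.0 / (1.0 + np.exp((v - 9.44) / 3.58)) + 1739.14) / _KQ10
    tab[:, 22] = dec(tau_a_new)
    tab[:, 23] = dec(tau_i_new)
    tab[:, 24] = 0.64 * (4.51 + 1.90 / (1.0 + np.exp((v - 20.52) / -8.27))) / 100.0

    e_k = RTF * math.log(KO / KI_FIXED)
    dvk = v - e_k
    aki = 1.02 / (1.0 + np.exp(0.2385 * (dvk - 59.215)))
    bki = (0.49124 * np.exp(0.08032 * (dvk + 5.476))
           + np.exp(0.06175 * (dvk - 594.31))) / (
        1.0 + np.exp(-0.5143 * (dvk + 4.753)))
    tab[:, 25] = aki / (aki + bki) * dvk
    tab[:, 26] = 1.0 / (1.0 + np.exp((v + 74.0) / 24.0))
    tab[:, 27] = 1.0 / (1.0 + np.exp(7.488 - v / 5.98))
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    tab[:, 28] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                        + 0.0365 * sigma * np.exp(-v / RTF))
    tab[:, 29] = np.exp(0.35 * v / RTF)
    tab[:, 30] = np.exp((0.35 - 1.0) * v / RTF)

    z = 2.0 * v / RTF
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ez = np.exp(z)
        driv_a = np.where(np.abs(z) < 1e-6, 0.341 * 0.5 * RTF,
                          v * 0.341 * ez / (ez - 1.0))
        driv_b = np.where(np.abs(z) < 1e-6, 0.341 * 0.5 * RTF * CAO,
                          v * 0.341 * CAO / (ez - 1.0))
    tab[:, 31] = driv_a
    tab[:, 32] = driv_b

    ewr = np.exp(-(v - 7.9) / 5.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_w = np.where(np.abs(v - 7.9) < 1e-10, 0.9231,
                         6.0 * (1.0 - ewr) / ((1.0 + 0.3 * ewr) * (v - 7.9)))
    tab[:, 33] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))
    tab[:, 34] = dec(tau_w)
    return tab


@njit(cache=True)
def step_fast(u, p, tab, dt, istim):  # noqa: C901
    """Table-driven variant of :func:`step` (same state/parameter layout)."""
    v = u[0]
    caj = u[16]
    cai = u[17]
    casr = u[18]
    nai = u[19]

    pos = (v - V_MIN) / V_STEP
    if pos < 0.0:
        pos = 0.0
    elif pos > N_V - 2:
        pos = N_V - 2.0
    ii = int(pos)
    w = pos - ii
    r0 = tab[ii]
    r1 = tab[ii + 1]

    def _lk(c):
        return r0[c] + w * (r1[c] - r0[c])

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(KO / KI_FIXED)
    e_ca = 0.5 * RTF * math.log(CAO / cai)

    i_na = p[0] * u[1] ** 3 * u[2] * u[3] * (v - e_na)
    i_nab = p[1] * (v - e_na)
    f_nak = _lk(28)
    i_nak = p[2] * f_nak * KO / (KO + 1.5) / (1.0 + (11.0 / nai) ** 4)
    i_kr = p[3] * u[9] * _lk(26) * (v - e_k)
    e_ks = RTF * math.log((KO + 0.01833 * NAO) / (KI_FIXED + 0.01833 * nai))
    i_ks = p[4] * u[10] ** 2 * (v - e_ks)
    i_to = p[5] * u[7] * u[8] * (v - e_k)

    blk = p[18:18 + N_IKUR_PAR]
    a_inf = _sig((v - blk[1]) / blk[2])
    if blk[0] >= 0.5 and blk[4] != 0.0:
        a_inf *= _sig((v - blk[3]) / blk[4])
    i_inf = blk[7] * _sig((v - blk[5]) / blk[6]) + blk[8]
    if blk[0] < 0.5:
        dec_a = _lk(20)
        dec_i = _lk(21)
        i_kur = blk[9] * u[11] * u[12] * (v - e_k)
    else:
        dec_a = _lk(22)
        dec_i = _lk(23)
        i_kur = _lk(24) * blk[9] * u[11] * u[12] * (v - e_k)

    i_k1 = p[6] * _lk(25)
    i_kp = p[7] * (v - e_k) * _lk(27)
    i_clca = p[8] / (1.0 + 0.1 / cai) * (v - E_CL)
    i_clb = p[9] * (v - E_CL)

    driv = _lk(31) * caj - _lk(32)
    i_cal = p[10] * driv * u[4] * u[5] * u[20] * (1.0 - u[6])

    ka = 1.0 / (1.0 + (3.84e-4 / caj) ** 2)
    ez = _lk(29)
    ez1 = _lk(30)
    s1 = ez * nai ** 3 * CAO
    s2 = ez1 * NAO ** 3 * cai
    s3 = 3.59e-3 * NAO ** 3 * (1.0 + (nai / 12.29) ** 3) \
        + 87.5 ** 3 * cai * (1.0 + cai / 3.59e-3) \
        + 1.3 * nai ** 3 + nai ** 3 * CAO + NAO ** 3 * cai
    i_ncx = p[11] * ka * (s1 - s2) / (s3 * (1.0 + 0.27 * ez1))
    i_pmca = p[12] * cai ** 1.6 / (5.0e-4 ** 1.6 + cai ** 1.6)
    i_cab = p[13] * (v - e_ca)

    qf = (cai / p[15]) ** 1.787
    qr = (casr / p[16]) ** 1.787
    j_up = p[14] * (qf - qr) / (1.0 + qf + qr)
    j_leak = SR_LEAK * (casr - cai)
    j_rel = p[17] * u[13] * u[13] * u[14] * u[15] * (casr - caj)
    fn = 0.5 * j_rel - (0.5 * i_cal - 0.2 * i_ncx)
    urel_inf = 1.0 / (1.0 + math.exp(-(fn - 0.6) / 0.12))
    vrel_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 0.12) / 0.012))
    tau_vrel = 1.91 + 2.09 * urel_inf

    i_ion = (i_na + i_nab + i_nak + i_kr + i_ks + i_to + i_kur + i_k1 + i_kp
             + i_clca + i_clb + i_cal + i_ncx + i_pmca + i_cab)
    u[0] = v + dt * (-(i_ion + istim))

    # table gate order m h j d f f2 xto yto xkr xks -> slots 1-5, 20, 7-10
    for g in range(10):
        c = 2 * g
        inf = r0[c] + w * (r1[c] - r0[c])
        de = r0[c + 1] + w * (r1[c + 1] - r0[c + 1])
        if g < 5:
            slot = g + 1
        elif g == 5:
            slot = 20
        else:
            slot = g + 1
        u[slot] = inf + (u[slot] - inf) * de
    u[6] = u[6] + dt * (1.7 * caj * (1.0 - u[6]) - 11.9e-3 * u[6])
    u[11] = a_inf + (u[11] - a_inf) * dec_a
    u[12] = i_inf + (u[12] - i_inf) * dec_i
    u[13] = urel_inf + (u[13] - urel_inf) * math.exp(-dt / 8.0)
    u[14] = vrel_inf + (u[14] - vrel_inf) * math.exp(-dt / tau_vrel)
    wrel_inf = _lk(33)
    u[15] = wrel_inf + (u[15] - wrel_inf) * _lk(34)

    beta_j = 1.0 / (1.0 + BMAX_J * KM_J / (KM_J + caj) ** 2)
    src_j = -i_cal * CONV_JUNC + j_rel
    rate = beta_j * dt / TAU_JDIFF
    u[16] = (caj + dt * beta_j * src_j + rate * cai) / (1.0 + rate)

    beta_i = 1.0 / (1.0 + 0.07 * 6.0e-4 / (6.0e-4 + cai) ** 2
                    + 0.024 * 7.0e-3 / (7.0e-3 + cai) ** 2
                    + 0.0171 * 8.7e-4 / (8.7e-4 + cai) ** 2)
    src_i = -(i_cab + i_pmca - 2.0 * i_ncx) * CONV_MYO \
        - j_up + j_leak + (u[16] - cai) / TAU_JDIFF * VJ_VM
    u[17] = cai + dt * beta_i * src_i

    beta_sr = 1.0 / (1.0 + BMAX_CSQN * KM_CSQN / (KM_CSQN + casr) ** 2)
    src_sr = (j_up - j_leak) * VM_VSR - j_rel / VSR_VJ
    u[18] = casr + dt * beta_sr * src_sr

    u[19] = nai + dt * (-(i_na + i_nab + 3.0 * i_nak + 3.0 * i_ncx) * CONV_MYO_NA)
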