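"""Fitting of steady-state Boltzmann curves and activation time constants.

Mirrors the analysis chain applied to the experimental Kv1.5 recordings:
steady-state activation/availability points are fitted to Boltzmann
functions (activation: 1/(1+exp((V-V1/2)/k)); availability:
(1-MA)/(1+exp((V-V1/2)/k)) + MA with minimum availability MA), activation
phases of current traces are fitted to a mono-exponential to estimate the
activation time constant, and room-temperature time constants are corrected
to physiological temperature by division with a Q10 factor.  Differencing
two fitted variants yields the relative-change record of a mutant
(the inverse of building a mutant model from such a record).

All fits are bounded nonlinear least squares with deterministic multi-start
(coarse grids over the sigmoid midpoint and slope) to avoid the local minima
of sigmoid fitting.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from kcna5.clamp import CurrentTrace
from kcna5.ikur import MutantDelta

__all__ = [
    "BoltzmannFit",
    "FitError",
    "fit_boltzmann_activation",
    "fit_boltzmann_inactivation",
    "fit_monoexp_tau",
    "default_activation_window",
    "apply_q10",
    "derive_relative_changes",
]

_XTOL = 1e-14


class FitError(RuntimeError):
    """Non-convergence or degenerate input of a curve fit."""


@dataclass
class BoltzmannFit:
    """Result of one Boltzmann fit.

    ``amplitude`` is the fitted sigmoid span; for activation fits with a free
    amplitude it absorbs the unknown conductance scale (and may exceed 1).
    ``warnings`` carries identifiability flags (e.g. on flat input) without
    aborting batch fits.
    """

    v_half: float
    slope_k: float
    amplitude: float
    floor_ma: float
    rss: float
    n_points: int
    converged: bool
    warnings: tuple[str, ...] = ()

    def __call__(self, v):
        return self.amplitude * expit(
            -(np.asarray(v, dtype=float) - self.v_half) / self.slope_k) + self.floor_ma


def _as_points(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        # accept DataFrames with v_mV/value columns
        try:
            pts = np.column_stack([points["v_mV"], points["value"]])
        except Exception as exc:  # noqa: BLE001
            raise ValueError("points must be an (n, 2) table of (mV, fraction)") from exc
    order = np.argsort(pts[:, 0])
    return pts[order, 0], pts[order, 1]


def _multistart(resid, jac, starts, bounds):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(resid, x0=x0, jac=jac, bounds=bounds,
                                xtol=_XTOL, ftol=_XTOL, gtol=_XTOL)
        except Exception:  # noqa: BLE001 - keep scanning starts
            continue
        if sol.success and (best is None or sol.cost < best.cost - 0.0):
            best = sol
    if best is None:
        raise FitError("Boltzmann fit failed to converge from every start")
    interior = np.all(best.x > bounds[0]) and np.all(best.x < bounds[1])
    if interior:
        try:  # unconstrained Levenberg-Marquardt polish to machine precision
            pol = least_squares(resid, x0=best.x, jac=jac, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if pol.success and pol.cost <= best.cost + 1e-30 and np.all(
                    pol.x >= bounds[0]) and np.all(pol.x <= bounds[1]):
                best = pol
        except Exception:  # noqa: BLE001
            pass
    return best


def fit_boltzmann_activation(points, free_amplitude: bool = False) -> BoltzmannFit:
    """Fit normalised activation points to a rising Boltzmann.

    By default amplitude is fixed at 1 and floor at 0.  With
    ``free_amplitude`` the span is a third parameter, which recovers the
    relative maximal conductance when the input is conductance-scaled rather
    than normalised.
    """
    v, y = _as_points(points)
    n_free = 3 if free_amplitude else 2
    if v.size < max(4, n_free + 1):
        raise FitError(f"need at least {max(4, n_free + 1)} points, got {v.size}")
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        raise FitError("degenerate activation input: all points equal")

    vh_grid = np.quantile(v, [0.2, 0.35, 0.5, 0.65, 0.8])
    amp0 = float(np.max(y)) if free_amplitude else 1.0
    if free_amplitude:
        starts = [np.array([vh, -8.0, amp0]) for vh in vh_grid]
        bounds = ([v.min() - 100.0, -60.0, 1e-9], [v.max() + 100.0, -1e-3, 100.0])

        def resid(p):
            return p[2] * expit(-(v - p[0]) / p[1]) - y

        def jac(p):
            sg = expit(-(v - p[0]) / p[1])
            core = p[2] * sg * (1.0 - sg)
            return np.column_stack([core / p[1],
                                    core * (v - p[0]) / p[1] ** 2, sg])
    else:
        starts = [np.array([vh, -8.0]) for vh in vh_grid]
        bounds = ([v.min() - 100.0, -60.0], [v.max() + 100.0, -1e-3])

        def resid(p):
            return expit(-(v - p[0]) / p[1]) - y

        def jac(p):
            sg = expit(-(v - p[0]) / p[1])
            core = sg * (1.0 - sg)
            return np.column_stack([core / p[1],
                                    core * (v - p[0]) / p[1] ** 2])

    sol = _multistart(resid, jac, starts, bounds)
    amp = float(sol.x[2]) if free_amplitude else 1.0
    return BoltzmannFit(v_half=float(sol.x[0]), slope_k=float(sol.x[1]),
                        amplitude=amp, floor_ma=0.0, rss=float(2.0 * sol.cost),
                        n_points=int(v.size), converged=True)


def fit_boltzmann_inactivation(points, unnormalised: bool = True) -> BoltzmannFit:
    """Fit availability points to a falling Boltzmann with a floor.

    ``unnormalised`` (default) fits the 4-parameter form
    amplitude/(1+exp((V-V1/2)/k)) + floor; otherwise amplitude is tied to
    1 - floor (the normalised reported form).  Flat input returns
    floor = mean, amplitude ~ 0 with a 'v_half unidentifiable' warning.
    """
    v, y = _as_points(points)
    if v.size < 5:
        raise FitError(f"need at least 5 points, got {v.size}")
    if np.ptp(y) < 1e-9 * max(1.0, np.max(np.abs(y))):
        return BoltzmannFit(
            v_half=float(np.mean(v)), slope_k=7.5, amplitude=0.0,
            floor_ma=float(np.mean(y)), rss=float(np.sum((y - np.mean(y)) ** 2)),
            n_points=int(v.size), converged=True,
            warnings=("v_half unidentifiable: flat availability data",))

    vh_grid = np.quantile(v, [0.2, 0.35, 0.5, 0.65, 0.8])
    floor0 = float(np.clip(np.min(y), 0.0, 0.95))
    span0 = float(max(np.ptp(y), 1e-3))
    if unnormalised:
        starts = [np.array([vh, 8.0, span0, floor0]) for vh in vh_grid]
        bounds = ([v.min() - 100.0, 1e-3, 1e-9, 0.0],
                  [v.max() + 100.0, 60.0, 10.0, 1.0])

        def resid(p):
            return p[2] * expit(-(v - p[0]) / p[1]) + p[3] - y

        def jac(p):
            sg = expit(-(v - p[0]) / p[1])
            core = p[2] * sg * (1.0 - sg)
            return np.column_stack([core / p[1],
                                    core * (v - p[0]) / p[1] ** 2,
                                    sg, np.ones_like(v)])
    else:
        starts = [np.array([vh, 8.0, floor0]) for vh in vh_grid]
        bounds = ([v.min() - 100.0, 1e-3, 0.0], [v.max() + 100.0, 60.0, 1.0])

        def resid(p):
            return (1.0 - p[2]) * expit(-(v - p[0]) / p[1]) + p[2] - y

        def jac(p):
            sg = expit(-(v - p[0]) / p[1])
            core = (1.0 - p[2]) * sg * (1.0 - sg)
            return np.column_stack([core / p[1],
                                    core * (v - p[0]) / p[1] ** 2, 1.0 - sg])

    sol = _multistart(resid, jac, starts, bounds)
    if unnormalised:
        amp, floor = float(sol.x[2]), float(sol.x[3])
    else:
        floor = float(sol.x[2])
        amp = 1.0 - floor
    return BoltzmannFit(v_half=float(sol.x[0]), slope_k=float(sol.x[1]),
                        amplitude=amp, floor_ma=floor, rss=float(2.0 * sol.cost),
                        n_points=int(v.size), converged=True)


def default_activation_window(trace: CurrentTrace) -> tuple[float, float]:
    """Window from 5% to 95% of the step's current rise.

    Avoids the stimulus edge and the slow-inactivation contamination of the
    late phase.
    """
    cur = trace.current
    lo, hi = cur[0], np.max(np.abs(cur)) * np.sign(cur[np.argmax(np.abs(cur))])
    rise = hi - lo
    t5 = trace.time[np.argmax(np.abs(cur - lo) >= 0.05 * abs(rise))]
    t95 = trace.time[np.argmax(np.abs(cur - lo) >= 0.95 * abs(rise))]
    if t95 <= t5:
        t95 = trace.time[-1]
    return float(t5), float(t95)


def fit_monoexp_tau(trace: CurrentTrace, window: tuple[float, float]) -> float:
    """Least-squares mono-exponential time constant (ms) within a window.

    Fits y = a + b*exp(-t/tau); the sign of b distinguishes the activation
    form A*(1-exp(-t/tau))+C from the decay form A*exp(-t/tau)+C.  Signals a
    non-monotone window (beyond a noise allowance) and non-convergence.
    """
    t0, t1 = window
    if t0 < trace.time[0] - 1e-9 or t1 > trace.time[-1] + 1e-9 or t1 <= t0:
        raise ValueError(f"window {window} outside trace span")
    sel = (trace.time >= t0) & (trace.time <= t1)
    t = trace.time[sel] - trace.time[sel][0]
    y = trace.current[sel]
    if t.size < 5:
        raise FitError("window contains fewer than 5 samples")

    k = max(1, t.size // 20)
    smooth = np.convolve(y, np.ones(2 * k + 1) / (2 * k + 1), mode="valid")
    d = np.diff(smooth)
    span = np.ptp(smooth)
    if span <= 0:
        raise FitError("flat trace within window")
    up, down = d[d > 0].sum(), -d[d < 0].sum()
    if min(up, down) > 0.25 * span:
        raise FitError("non-monotone current within the fitting window")
    rising = up >= down

    b0 = -np.ptp(y) if rising else np.ptp(y)
    tau0 = max((t1 - t0) / 3.0, 1e-3)

    def resid(p):
        return p[0] + p[1] * np.exp(-t / p[2]) - y

    best = None
    for tau_start in (tau0 / 4, tau0, tau0 * 4):
        sol = least_squares(resid, x0=[y[-1], b0, tau_start],
                            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e7]),
                            xtol=_XTOL, ftol=_XTOL, gtol=_XTOL)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("mono-exponential fit failed to converge")
    return float(best.x[2])


def apply_q10(tau_experimental: float, kq10: float) -> float:
    """Correct a room-temperature time constant to 37 C: tau / KQ10."""
    if tau_experimental <= 0 or kq10 <= 0:
        raise ValueError("tau and kq10 must be positive")
    return tau_experimental / kq10


def derive_relative_changes(
    wt_act: BoltzmannFit, wt_inact: BoltzmannFit, g_wt: float,
    mut_act: BoltzmannFit, mut_inact: BoltzmannFit, g_mut: float,
) -> MutantDelta:
    """Relative-change record between two fitted variants (mutant vs WT).

    Additive half-voltage and minimum-availability differences, multiplicative
    slope and conductance ratios -- the inverse of constructing a mutant model
    from such a record.
    """
    for fit in (wt_act, wt_inact, mut_act, mut_inact):
        if not fit.converged:
            raise FitError("cannot difference non-converged fits")
        if fit.warnings:
            _warnings.warn("; ".join(fit.warnings), stacklevel=2)
    if wt_act.slope_k == 0 or wt_inact.slope_k == 0:
        raise ZeroDivisionError("WT slope is zero")
    if g_wt == 0:
        raise ZeroDivisionError("WT conductance is zero")
    return MutantDelta(
        d_vhalf_act=mut_act.v_half - wt_act.v_half,
        k_act_factor=mut_act.slope_k / wt_act.slope_k,
        d_vhalf_inact=mut_inact.v_half - wt_inact.v_half,
        k_inact_factor=mut_inact.slope_k / wt_inact.slope_k,
        d_ma=mut_inact.floor_ma - wt_inact.floor_ma,
        g_factor=g_mut / g_wt,
    )
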