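"""1D monodomain tissue: conduction velocity, vulnerability windows, SAN patterns.

The transmembrane potential obeys the monodomain reaction-diffusion equation
dV/dt = div(D grad V) - I_ion/C_m with no-flux boundaries, discretised by
explicit finite differences (harmonic-mean face diffusivities for
heterogeneous interfaces, mirrored ghost nodes at the ends) and operator
splitting: one diffusion update followed by one reaction step of the cell
kernel per time step (Rush-Larsen gates inside the kernel keep dt = 0.02 ms
stable).

Protocol-level operations:

* ``measure_cv``: conduction velocity from upstroke times (-40 mV rising
  crossings) between two fractional positions of the strand.
* ``calibrate_diffusion``: bisection on the scalar diffusion coefficient to a
  target conduction velocity (the fibre-direction physiological value is
  1.3 m/s).
* ``s1s2_outcome`` / ``vulnerability_window``: the S1-S2 protocol at the
  heterogeneous crista terminalis / pectinate muscle junction -- 7 S1 at
  500 ms plus one S2 at the same site; the vulnerability window is the range
  of S2 intervals producing wave break in one direction but not both.
  The post-S1 state is cached and reused across S2 trials; boundaries are
  located by a coarse scan plus bisection to 1 ms.
* ``san_conduction_pattern``: a pacemaker surrogate (periodic suprathreshold
  stimulation of a designated segment) driving flanking regions, with
  per-beat conducted/blocked classification per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from kcna5.cells import courtemanche, grandi
from kcna5.cells.base import build_cell, get_tables, run_cell

__all__ = [
    "CableConfig",
    "CableStimulus",
    "SpaceTimeRecord",
    "PropagationOutcome",
    "VulnerabilityWindow",
    "ConductionBlockError",
    "ct_pm_strand",
    "build_cable",
    "solve_cable",
    "measure_cv",
    "calibrate_diffusion",
    "s1s2_outcome",
    "vulnerability_window",
    "san_conduction_pattern",
]


class ConductionBlockError(RuntimeError):
    """Propagation failed inside the measurement segment."""


@dataclass(frozen=True)
class CableStimulus:
    """Rectangular current pulse applied to a node range [lo, hi)."""

    lo: int
    hi: int
    onset: float
    amplitude: float = 40.0
    duration: float = 2.0


@dataclass
class CableConfig:
    """1D strand: per-node region labels, diffusion profile and cell variant.

    ``iso`` may be a scalar flag or a per-node boolean mask (heterogeneous
    beta-adrenergic stimulation).  ``d`` may be a scalar (mm^2/ms) or a
    per-node profile.
    """

    model_id: str = "courtemanche_newIKur"
    n_nodes: int = 200
    dx: float = 0.25
    d: float | np.ndarray = 0.3
    regions: str | np.ndarray = "RA"
    mutation: str | None = None
    caf: bool = False
    iso: bool | np.ndarray = False
    stim_amplitude: float = 40.0
    stim_duration: float = 2.0
    precondition_beats: int = 100
    precondition_cl: float = 1000.0
    dt: float = 0.02

    def __post_init__(self) -> None:
        if self.n_nodes < 50:
            raise ValueError("n_nodes must be >= 50")
        if not (0.1 <= self.dx <= 0.5):
            raise ValueError("dx must be within [0.1, 0.5] mm")
        if np.any(np.asarray(self.d) < 0):
            raise ValueError("diffusion must be non-negative")

    @property
    def length_mm(self) -> float:
        return self.n_nodes * self.dx

    def region_array(self) -> np.ndarray:
        if isinstance(self.regions, str):
            return np.full(self.n_nodes, self.regions, dtype=object)
        regions = np.asarray(self.regions, dtype=object)
        if regions.size != self.n_nodes:
            raise ValueError("regions length must equal n_nodes")
        return regions

    def iso_array(self) -> np.ndarray:
        if isinstance(self.iso, (bool, np.bool_)):
            return np.full(self.n_nodes, bool(self.iso))
        mask = np.asarray(self.iso, dtype=bool)
        if mask.size != self.n_nodes:
            raise ValueError("iso mask length must equal n_nodes")
        return mask

    def d_array(self) -> np.ndarray:
        d = np.asarray(self.d, dtype=float)
        if d.ndim == 0:
            return np.full(self.n_nodes, float(d))
        if d.size != self.n_nodes:
            raise ValueError("d profile length must equal n_nodes")
        return d.copy()


def ct_pm_strand(model_id: str = "grandi", mutation: str | None = None,
                 iso: bool | np.ndarray = False, n_nodes: int = 200,
                 dx: float = 0.25, d: float | np.ndarray = 0.3,
                 **kw) -> CableConfig:
    """Half crista terminalis / half pectinate muscle strand (CT at low x)."""
    regions = np.array(["CT"] * (n_nodes // 2) + ["PM"] * (n_nodes - n_nodes // 2),
                       dtype=object)
    return CableConfig(model_id=model_id, n_nodes=n_nodes, dx=dx, d=d,
                       regions=regions, mutation=mutation, iso=iso, **kw)


@dataclass
class SpaceTimeRecord:
    """Sampled space-time voltage plus the final full state."""

    t: np.ndarray          # (n_t,)
    x: np.ndarray          # (n_nodes,) mm
    v: np.ndarray          # (n_t, n_nodes)
    final_state: np.ndarray  # (n_nodes, n_state)


@dataclass(frozen=True)
class PropagationOutcome:
    """Classification of one S2 trial at a junction."""

    label: str  # bidirectional_conduction | bidirectional_block |
    #             unidirectional_block_A | unidirectional_block_B
    reached_a: bool
    reached_b: bool

    @property
    def unidirectional(self) -> bool:
        return self.reached_a != self.reached_b


@dataclass(frozen=True)
class VulnerabilityWindow:
    """S2 range producing unidirectional block; width 0 encodes none found."""

    s2_low: float
    s2_high: float
    resolution: float
    non_monotone: bool = False

    @property
    def width(self) -> float:
        return max(self.s2_high - self.s2_low, 0.0)


def _make_cable_kernel(step):
    @njit(cache=False)
    def kernel(U, P, tab, d_face, dx, dt, n_steps, t0,
               stim_lo, stim_hi, stim_on, stim_dur, stim_amp,
               rec_stride, out_v):
        n = U.shape[0]
        inv_dx2 = 1.0 / (dx * dx)
        lap = np.empty(n)
        for k in range(n_steps):
            t = t0 + k * dt
            if k % rec_stride == 0:
                row = k // rec_stride
                if row < out_v.shape[0]:
                    for i in range(n):
                        out_v[row, i] = U[i, 0]
            # diffusion (no-flux: boundary faces carry zero conductance)
            for i in range(n):
                left = d_face[i] * (U[i - 1, 0] - U[i, 0]) if i > 0 else 0.0
                right = d_face[i + 1] * (U[i + 1, 0] - U[i, 0]) if i < n - 1 else 0.0
                lap[i] = (left + right) * inv_dx2
            for i in range(n):
                U[i, 0] += dt * lap[i]
            # reaction
            for i in range(n):
                istim = 0.0
                for s in range(stim_on.size):
                    if stim_on[s] <= t < stim_on[s] + stim_dur[s] \
                            and stim_lo[s] <= i < stim_hi[s]:
                        istim -= stim_amp[s]
                step(U[i], P[i], tab, dt, istim)
            if k % 5000 == 0:
                for i in range(n):
                    if not np.isfinite(U[i, 0]):
                        return k * 1000000 + i
        return -1

    return kernel


_KERNELS = {
    "courtemanche": _make_cable_kernel(courtemanche.step_fast),
    "courtemanche_newIKur": _make_cable_kernel(courtemanche.step_fast),
    "grandi": _make_cable_kernel(grandi.step_fast),
}

# preconditioned single-cell states, keyed by the full variant description
_PRECOND_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _variant_cell(model_id, region, mutation, caf, iso, beats, cl):
    key = (model_id, region, mutation, caf, iso, beats, cl)
    if key not in _PRECOND_CACHE:
        cell = build_cell(model_id, region=region, mutation=mutation,
                          caf=caf, iso=iso)
        if beats > 0:
            run_cell(cell, beats * cl, np.arange(beats) * cl,
                     dt=0.005, record_dt=cl)
        _PRECOND_CACHE[key] = (cell.params.copy(), cell.state.copy())
    return _PRECOND_CACHE[key]


def build_cable(config: CableConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(initial state matrix, parameter matrix, face diffusivities).

    Each distinct (region, ISO) variant is built once and preconditioned as a
    single cell at 1 Hz; its steady state seeds every node of that variant.
    """
    regions = config.region_array()
    iso = config.iso_array()
    mod = {"courtemanche": courtemanche, "courtemanche_newIKur": courtemanche,
           "grandi": grandi}[config.model_id]
    U = np.empty((config.n_nodes, mod.N_STATE))
    P = np.empty((config.n_nodes, mod.N_PAR))
    for reg in np.unique(regions.astype(str)):
        for flag in (False, True):
            sel = (regions.astype(str) == reg) & (iso == flag)
            if not np.any(sel):
                continue
            params, state = _variant_cell(
                config.model_id, reg, config.mutation, config.caf, flag,
                config.precondition_beats, config.precondition_cl)
            U[sel] = state
            P[sel] = params
    d = config.d_array()
    d_face = np.zeros(config.n_nodes + 1)
    d_face[1:-1] = 2.0 * d[:-1] * d[1:] / np.maximum(d[:-1] + d[1:], 1e-300)
    return U, P, d_face


def solve_cable(
    config: CableConfig,
    stimuli: list[CableStimulus],
    duration: float,
    record_dt: float = 1.0,
    state: np.ndarray | None = None,
    t0: float = 0.0,
) -> SpaceTimeRecord:
    """Integrate the strand; optionally continue from a cached state."""
    U, P, d_face = build_cable(config)
    if state is not None:
        U = state.copy()
    dmax = float(np.max(config.d_array()))
    if dmax > 0 and config.dt > config.dx ** 2 / (2.0 * dmax):
        raise ValueError(
            f"dt={config.dt} violates the stability bound "
            f"dx^2/(2 max D) = {config.dx ** 2 / (2 * dmax):.4f} ms")
    n_steps = int(round(duration / config.dt))
    stride = max(1, int(round(record_dt / config.dt)))
    out = np.empty((n_steps // stride + 1, config.n_nodes))
    status = _KERNELS[config.model_id](
        U, P, get_tables(config.model_id, config.dt),
        d_face, config.dx, config.dt, n_steps, t0,
        np.array([s.lo for s in stimuli], dtype=np.int64),
        np.array([s.hi for s in stimuli], dtype=np.int64),
        np.array([s.onset for s in stimuli], dtype=float),
        np.array([s.duration for s in stimuli], dtype=float),
        np.array([s.amplitude for s in stimuli], dtype=float),
        stride, out)
    if status >= 0:
        k, i = divmod(status, 1000000)
        raise FloatingPointError(
            f"tissue blow-up at t={t0 + k * config.dt:.2f} ms, node {i}")
    if n_steps % stride == 0:
        out[n_steps // stride] = U[:, 0]  # final state row
    t = t0 + np.arange(out.shape[0]) * stride * config.dt
    x = np.arange(config.n_nodes) * config.dx
    return SpaceTimeRecord(t=t, x=x, v=out, final_state=U)


def save_spacetime(rec: SpaceTimeRecord, path) -> None:
    """Write a space-time record to HDF5 (datasets: time, x, voltage, state)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=rec.t)
        f.create_dataset("x_mm", data=rec.x)
        f.create_dataset("voltage_mV", data=rec.v)
        f.create_dataset("final_state", data=rec.final_state)


def export_site_traces(rec: SpaceTimeRecord, nodes, path) -> None:
    """CSV export of selected node traces (time_ms, v_node<k> columns)."""
    import pandas as pd

    frame = pd.DataFrame({"time_ms": rec.t})
    for n in nodes:
        frame[f"v_node{n}_mV"] = rec.v[:, n]
    frame.to_csv(path, index=False)


def activation_time(rec: SpaceTimeRecord, node: int,
                    after: float = -np.inf) -> float:
    """First rising -40 mV crossing time of a node (linear interpolation).

    Returns NaN when the node never activates after ``after``.
    """
    v = rec.v[:, node]
    t = rec.t
    ok = t >= after
    vv, tt = v[ok], t[ok]
    hits = np.where((vv[1:] > -40.0) & (vv[:-1] <= -40.0))[0]
    if hits.size == 0:
        return float("nan")
    i = int(hits[0])
    frac = (-40.0 - vv[i]) / (vv[i + 1] - vv[i])
    return float(tt[i] + frac * (tt[i + 1] - tt[i]))


def measure_cv(rec: SpaceTimeRecord, from_fraction: float = 0.25,
               to_fraction: float = 0.75, after: float = -np.inf) -> float:
    """Conduction velocity (m/s) between two fractional strand positions."""
    n = rec.v.shape[1]
    i0 = int(round(from_fraction * (n - 1)))
    i1 = int(round(to_fraction * (n - 1)))
    t_a = activation_time(rec, i0, after)
    t_b = activation_time(rec, i1, after)
    if not (np.isfinite(t_a) and np.isfinite(t_b)) or t_b == t_a:
        raise ConductionBlockError(
            f"wave blocked between nodes {i0} and {i1}")
    return float(abs(rec.x[i1] - rec.x[i0]) / abs(t_b - t_a))  # mm/ms == m/s


def strand_cv(config: CableConfig, d: float | None = None,
              sim_ms: float = 300.0, record_dt: float = 0.5) -> float:
    """CV of a single end-stimulated beat from the preconditioned state."""
    cfg = replace(config, d=d) if d is not None else config
    stim = [CableStimulus(0, 4, onset=5.0, amplitude=cfg.stim_amplitude,
                          duration=cfg.stim_duration)]
    rec = solve_cable(cfg, stim, sim_ms, record_dt=record_dt)
    return measure_cv(rec)


def calibrate_diffusion(
    config: CableConfig,
    target_cv: float = 1.3,
    tolerance: float = 0.005,
    bracket: tuple[float, float] = (0.02, 1.2),
    max_iter: int = 40,
) -> tuple[float, float]:
    """Bisection on the scalar diffusion coefficient to a target CV.

    Returns (calibrated D in mm^2/ms, achieved CV in m/s).  Raises if the
    bracket does not straddle the target.
    """
    lo, hi = bracket
    cv_lo = strand_cv(config, lo)
    cv_hi = strand_cv(config, hi)
    if not (cv_lo < target_cv < cv_hi):
        raise ValueError(
            f"target {target_cv} m/s outside bracket CVs [{cv_lo:.3f}, {cv_hi:.3f}]")
    d, cv = hi, cv_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cv = strand_cv(config, mid)
        d = mid
        if abs(cv - target_cv) <= tolerance:
            break
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
    return d, cv


# ---------------------------------------------------------------------------
# S1-S2 vulnerability at the CT/PM junction
# ---------------------------------------------------------------------------

#: S1/S2 stimulus radius (mm): the spherical stimulated region of the
#: source protocol mapped onto the strand.
STIM_RADIUS_MM = 3.3

S1_CL = 500.0
N_S1 = 7


def _junction_stim_nodes(config: CableConfig) -> tuple[int, int]:
    centre = config.n_nodes // 2
    half = max(1, int(round(STIM_RADIUS_MM / config.dx)))
    return max(0, centre - half), min(config.n_nodes, centre + half)


def measure_diastolic_threshold(
    config: CableConfig,
    site: tuple[int, int] | None = None,
    duration: float = 2.0,
    bracket: tuple[float, float] = (2.0, 80.0),
    resolution: float = 1.0,
) -> float:
    """Diastolic capture threshold (pA/pF) of a 2 ms pulse at a site.

    Bisection on the pulse amplitude from the preconditioned resting state;
    capture = an activation 5 mm outside the stimulated segment within
    60 ms.  The S1/S2 protocols use twice this threshold.
    """
    if site is None:
        site = _junction_stim_nodes(config)
    lo_amp, hi_amp = bracket
    probe = min(config.n_nodes - 1, site[1] + int(round(5.0 / config.dx)))

    def captures(amp: float) -> bool:
        rec = solve_cable(config, [CableStimulus(site[0], site[1], onset=5.0,
                                                 amplitude=amp,
                                                 duration=duration)],
                          65.0, record_dt=0.5)
        return bool(np.isfinite(activation_time(rec, probe)))

    if captures(lo_amp):
        return lo_amp
    if not captures(hi_amp):
        raise ValueError("no capture within the amplitude bracket")
    while hi_amp - lo_amp > resolution:
        mid = 0.5 * (lo_amp + hi_amp)
        if captures(mid):
            hi_amp = mid
        else:
            lo_amp = mid
    return hi_amp


def with_threshold_stimulus(config: CableConfig,
                            site: tuple[int, int] | None = None) -> CableConfig:
    """Copy of the config with the stimulus set to 2x diastolic threshold."""
    thr = measure_diastolic_threshold(config, site)
    return replace(config, stim_amplitude=2.0 * thr)


def post_s1_state(config: CableConfig) -> tuple[np.ndarray, float]:
    """Integrate the 7-beat S1 train once; return (state, cache time).

    The cache time is the end of the final S1 stimulus, so an S2 delivered at
    coupling interval s2 (from the final S1 onset) starts at
    s2 - stim_duration in the continuation run.
    """
    lo, hi = _junction_stim_nodes(config)
    stims = [CableStimulus(lo, hi, onset=k * S1_CL,
                           amplitude=config.stim_amplitude,
                           duration=config.stim_duration)
             for k in range(N_S1)]
    t_cache = (N_S1 - 1) * S1_CL + config.stim_duration
    rec = solve_cable(config, stims, t_cache, record_dt=S1_CL)
    return rec.final_state, t_cache


def s1s2_outcome(
    config: CableConfig,
    s2: float,
    cached: tuple[np.ndarray, float] | None = None,
    follow_ms: float = 400.0,
) -> PropagationOutcome:
    """Outcome of one S2 coupling interval at the junction.

    End A is the low-x (crista terminalis) end, end B the high-x end.
    """
    if cached is None:
        cached = post_s1_state(config)
    state, t_cache = cached
    lo, hi = _junction_stim_nodes(config)
    t_s2 = (N_S1 - 1) * S1_CL + s2
    if t_s2 <= t_cache:
        raise ValueError(f"s2={s2} ms lies inside the S1 train")
    stim = [CableStimulus(lo, hi, onset=t_s2, amplitude=config.stim_amplitude,
                          duration=config.stim_duration)]
    rec = solve_cable(config, stim, t_s2 - t_cache + follow_ms,
                      record_dt=0.5, state=state, t0=t_cache)
    edge = max(3, int(round(1.0 / config.dx)))
    reached_a = np.isfinite(activation_time(rec, edge, after=t_s2))
    reached_b = np.isfinite(activation_time(rec, config.n_nodes - 1 - edge,
                                            after=t_s2))
    if reached_a and reached_b:
        label = "bidirectional_conduction"
    elif not reached_a and not reached_b:
        label = "bidirectional_block"
    elif reached_b:
        label = "unidirectional_block_A"
    else:
        label = "unidirectional_block_B"
    return PropagationOutcome(label=label, reached_a=reached_a,
                              reached_b=reached_b)


def _bisect_boundary(config, cached, s2_in, s2_out, resolution, follow_ms):
    """Bisect between a unidirectional s2 (s2_in) and a non-unidirectional one."""
    while abs(s2_out - s2_in) > resolution:
        mid = round(0.5 * (s2_in + s2_out))
        if mid in (s2_in, s2_out):
            break
        if s1s2_outcome(config, mid, cached, follow_ms).unidirectional:
            s2_in = mid
        else:
            s2_out = mid
    return s2_in


def vulnerability_window(
    config: CableConfig,
    scan: tuple[float, float] = (150.0, 800.0),
    coarse_step: float = 10.0,
    resolution: float = 1.0,
    follow_ms: float = 400.0,
) -> VulnerabilityWindow:
    """Locate the unidirectional-block S2 range at the junction.

    A coarse scan locates the unidirectional S2 set; the window is its
    range (smallest to largest unidirectional S2) with each boundary
    bisected to ``resolution`` against the adjacent non-unidirectional
    outcome.  Outcomes are assumed monotone (block, unidirectional,
    conduction as S2 grows); interior violations of that ordering are
    reported via ``non_monotone`` rather than silently dropped.
    """
    cached = post_s1_state(config)
    grid = np.arange(scan[0], scan[1] + 0.5 * coarse_step, coarse_step)
    uni = np.array([s1s2_outcome(config, s2, cached, follow_ms).unidirectional
                    for s2 in grid])
    if not np.any(uni):
        return VulnerabilityWindow(s2_low=0.0, s2_high=0.0,
                                   resolution=resolution)
    idx = np.where(uni)[0]
    i0, i1 = int(idx[0]), int(idx[-1])
    non_monotone = not np.all(uni[i0:i1 + 1])

    low = grid[i0]
    if i0 > 0:
        low = _bisect_boundary(config, cached, grid[i0], grid[i0 - 1],
                               resolution, follow_ms)
    high = grid[i1]
    if i1 < len(grid) - 1:
        high = _bisect_boundary(config, cached, grid[i1], grid[i1 + 1],
                                resolution, follow_ms)
    return VulnerabilityWindow(s2_low=float(low), s2_high=float(high),
                               resolution=resolution,
                               non_monotone=non_monotone)


def conduction_boundary(
    config: CableConfig,
    bracket: tuple[float, float] = (150.0, 600.0),
    resolution: float = 2.0,
    cached: tuple[np.ndarray, float] | None = None,
) -> float:
    """Smallest S2 (ms) with bidirectional conduction at the junction.

    The refractory boundary of the S1-S2 protocol.  When the unidirectional
    window is narrower than any practical scan step, the shift of this
    boundary still quantifies how a channel variant moves the S2 range over
    which wave break occurs.
    """
    if cached is None:
        cached = post_s1_state(config)
    lo, hi = bracket

    def conducts(s2):
        o = s1s2_outcome(config, s2, cached)
        return o.reached_a and o.reached_b

    if conducts(lo):
        return lo
    if not conducts(hi):
        raise ValueError("upper bracket does not conduct")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if conducts(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# SAN-surrogate conduction patterns
# ---------------------------------------------------------------------------

def san_conduction_pattern(
    config: CableConfig,
    n_beats: int = 6,
    cycle_length: float = 750.0,
    segment_mm: float = 3.0,
    follow_ms: float = 350.0,
) -> list[dict]:
    """Per-beat conduction record for a central pacemaker-surrogate segment.

    The sinoatrial driver is represented by periodic suprathreshold
    stimulation of a central segment (a detailed pacemaker cell model is out
    of scope); each sinus beat is classified as conducted or blocked into
    each flank.
    """
    centre = config.n_nodes // 2
    half = max(1, int(round(0.5 * segment_mm / config.dx)))
    stims = [CableStimulus(centre - half, centre + half, onset=50.0 + k * cycle_length,
                           amplitude=config.stim_amplitude,
                           duration=config.stim_duration)
             for k in range(n_beats)]
    rec = solve_cable(config, stims, 50.0 + (n_beats - 1) * cycle_length + follow_ms,
                      record_dt=1.0)
    edge = max(3, int(round(1.0 / config.dx)))
    out = []
    for k in range(n_beats):
        t_on = 50.0 + k * cycle_length
        t_next = t_on + min(cycle_length, follow_ms)
        conducted = {}
        for side, node in (("A", edge), ("B", config.n_nodes - 1 - edge)):
            t_act = activation_time(rec, node, after=t_on)
            conducted[side] = bool(np.isfinite(t_act) and t_act < t_next)
        out.append({"beat": k, "onset_ms": t_on,
                    "conducted_a": conducted["A"],
                    "conducted_b": conducted["B"]})
    return out
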