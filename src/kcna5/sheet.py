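"""2D monodomain sheet: phase-distribution re-entry and dominant frequency.

A homogeneous square sheet replaces the anatomical 3D atria as a desk-scale
substrate for re-entrant dynamics.  Re-entry is initiated by the
phase-distribution method: full-state snapshots are taken at uniform times
across one paced AP cycle of the single cell (a "phase library") and mapped
onto the sheet by a spatial phase layout -- linear (phase proportional to x)
or archimedean (phase proportional to the angle about a centre), the latter
seeding a single rotor without any stimulus sequence.

The diffusion coefficient is expressed as ``d_scale`` times a control value
calibrated to the physiological conduction velocity; lowering it emulates
gap-junction/structural remodelling (100% control down to 40%).  Dominant
frequencies of the resulting activity are measured by Fourier analysis of
single-site voltage traces at >= 9 distributed sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import periodogram

from kcna5.cells import courtemanche, grandi
from kcna5.cells.base import build_cell, get_tables, run_cell

__all__ = [
    "SheetConfig",
    "PhaseLibrary",
    "ReentryMetrics",
    "build_phase_library",
    "init_sheet_phase_map",
    "run_reentry",
    "dominant_frequency",
]

_MODULES = {"courtemanche": courtemanche, "courtemanche_newIKur": courtemanche,
            "grandi": grandi}


@dataclass
class SheetConfig:
    """Square monodomain sheet of one cell variant."""

    model_id: str = "courtemanche_newIKur"
    nx: int = 150
    ny: int = 150
    dx: float = 0.25
    d_control: float = 0.3     # mm^2/ms at 100% coupling
    d_scale: float = 1.0
    mutation: str | None = None
    caf: bool = False
    iso: bool = False
    region: str = "RA"
    dt: float = 0.02
    phase_center: tuple[float, float] | None = None  # node coordinates

    def __post_init__(self) -> None:
        if self.nx * self.ny > 10 ** 6:
            raise ValueError("sheet larger than 1e6 nodes")
        if not (0.0 < self.d_scale <= 1.0):
            raise ValueError("d_scale must lie in (0, 1]")
        d = self.d_control * self.d_scale
        if self.dt > self.dx ** 2 / (4.0 * d):
            raise ValueError(
                f"dt={self.dt} violates the 2D stability bound "
                f"dx^2/(4D) = {self.dx ** 2 / (4 * d):.4f} ms")

    @property
    def d(self) -> float:
        return self.d_control * self.d_scale


@dataclass
class PhaseLibrary:
    """Full-state snapshots at uniform phases of one paced AP cycle."""

    snapshots: np.ndarray  # (n_snapshots, n_state)
    cycle_length: float
    params: np.ndarray

    def __post_init__(self) -> None:
        if self.snapshots.shape[0] < 2:
            raise ValueError("degenerate phase library: need >= 2 snapshots "
                             "(>= 32 for re-entry initiation)")

    @property
    def n(self) -> int:
        return int(self.snapshots.shape[0])


@dataclass
class ReentryMetrics:
    """Outcome of one re-entry run."""

    dominant_frequencies: np.ndarray  # Hz per recording site
    sustained: bool
    lifetime: float                   # ms of last activation
    window: float                     # ms analysed
    site_traces: np.ndarray           # (n_t, n_sites)
    t: np.ndarray

    @property
    def dominant_frequency(self) -> float:
        """Median of the per-site dominant frequencies."""
        return float(np.median(self.dominant_frequencies))


def build_phase_library(cell, cycle_length: float = 1000.0,
                        n_snapshots: int = 64, n_precondition: int = 20,
                        dt: float = 0.005) -> PhaseLibrary:
    """Snapshot the full state at uniform times over the final paced cycle.

    The cell is paced to (approximate) steady state first; snapshots span
    the entire cycle so that phase 0 and phase 1 nearly coincide.
    """
    work = cell.copy()
    if n_precondition > 0:
        run_cell(work, n_precondition * cycle_length,
                 np.arange(n_precondition) * cycle_length,
                 dt=dt, record_dt=cycle_length)
    snaps = np.empty((n_snapshots, work.state.size))
    interval = cycle_length / n_snapshots
    # final stimulated cycle, sampled segment by segment
    run_cell(work, 1e-9, np.zeros(1), dt=dt, record_dt=1.0)  # arm stimulus
    mod = work.module
    u, p = work.state, work.params
    n_sub = int(round(interval / dt))
    t = 0.0
    for k in range(n_snapshots):
        snaps[k] = u
        for _ in range(n_sub):
            istim = -20.0 if t < 2.0 else 0.0
            mod.step(u, p, dt, istim)
            t += dt
    return PhaseLibrary(snapshots=snaps, cycle_length=cycle_length,
                        params=work.params.copy())


def init_sheet_phase_map(config: SheetConfig, library: PhaseLibrary,
                         layout: str = "archimedean") -> np.ndarray:
    """Initial state field from a phase layout.

    ``linear``: phase proportional to x (a planar wave).  ``archimedean``:
    phase proportional to the angle about ``phase_center``, seeding a single
    rotor.  ``uniform``: every node at phase 0 (control; no wave develops).
    """
    if library.n < 32 and layout != "uniform":
        raise ValueError("re-entry initiation needs >= 32 phase snapshots")
    nx, ny = config.nx, config.ny
    if layout == "uniform":
        idx = np.zeros((ny, nx), dtype=np.int64)
    elif layout == "linear":
        x = np.arange(nx) / max(nx - 1, 1)
        idx = np.tile((x * (library.n - 1)).astype(np.int64), (ny, 1))
    elif layout in ("archimedean", "archimedean_mirror"):
        cx, cy = config.phase_center or ((nx - 1) / 2.0, (ny - 1) / 2.0)
        yy, xx = np.mgrid[0:ny, 0:nx]
        ang = np.arctan2(yy - cy, xx - cx)
        if layout == "archimedean_mirror":
            ang = -ang
        phase = (ang + np.pi) / (2.0 * np.pi)
        idx = np.minimum((phase * library.n).astype(np.int64), library.n - 1)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    field = library.snapshots[idx.ravel()]
    return field.reshape(ny * nx, -1).copy()


def _make_sheet_kernel(step):
    @njit(cache=False)
    def kernel(U, p, tab, nx, ny, d, dx, dt, n_steps, sites, rec_stride, out_v,
               stim_on, stim_dur, stim_amp, stim_nodes):
        inv_dx2 = d / (dx * dx)
        n = nx * ny
        lap = np.empty(n)
        for k in range(n_steps):
            t = k * dt
            if k % rec_stride == 0:
                row = k // rec_stride
                if row < out_v.shape[0]:
                    for s in range(sites.size):
                        out_v[row, s] = U[sites[s], 0]
            for j in range(ny):
                base = j * nx
                for i in range(nx):
                    c = base + i
                    vc = U[c, 0]
                    acc = 0.0
                    if i > 0:
                        acc += U[c - 1, 0] - vc
                    if i < nx - 1:
                        acc += U[c + 1, 0] - vc
                    if j > 0:
                        acc += U[c - nx, 0] - vc
                    if j < ny - 1:
                        acc += U[c + nx, 0] - vc
                    lap[c] = acc * inv_dx2
            stim_active = False
            for s in range(stim_on.size):
                if stim_on[s] <= t < stim_on[s] + stim_dur[s]:
                    stim_active = True
            for c in range(n):
                U[c, 0] += dt * lap[c]
                istim = 0.0
                if stim_active and stim_nodes[c]:
                    for s in range(stim_on.size):
                        if stim_on[s] <= t < stim_on[s] + stim_dur[s]:
                            istim -= stim_amp[s]
                step(U[c], p, tab, dt, istim)
            if k % 10000 == 0 and not np.isfinite(U[0, 0]):
                return k
        return -1

    return kernel


_SHEET_KERNELS = {
    "courtemanche": _make_sheet_kernel(courtemanche.step_fast),
    "courtemanche_newIKur": _make_sheet_kernel(courtemanche.step_fast),
    "grandi": _make_sheet_kernel(grandi.step_fast),
}


def _recording_sites(config: SheetConfig, n_side: int = 3) -> np.ndarray:
    xs = np.linspace(0.15, 0.85, n_side) * (config.nx - 1)
    ys = np.linspace(0.15, 0.85, n_side) * (config.ny - 1)
    return np.array([int(round(y)) * config.nx + int(round(x))
                     for y in ys for x in xs], dtype=np.int64)


def run_reentry(
    config: SheetConfig,
    initial: np.ndarray,
    duration: float = 5000.0,
    record_dt: float = 1.0,
    stimuli: list | None = None,
) -> ReentryMetrics:
    """Integrate the sheet and measure sustained-activity metrics.

    ``initial`` is a (nx*ny, n_state) field (e.g. from
    :func:`init_sheet_phase_map`).  ``sustained`` is true iff any recording
    site shows an activation (rising -40 mV crossing) within the final
    250 ms; ``lifetime`` is the time of the last activation anywhere on the
    recorded sites.
    """
    cell = build_cell(config.model_id, region=config.region,
                      mutation=config.mutation, caf=config.caf, iso=config.iso)
    U = initial.copy()
    if U.shape != (config.nx * config.ny, cell.state.size):
        raise ValueError("initial state field has the wrong shape")
    sites = _recording_sites(config)
    n_steps = int(round(duration / config.dt))
    stride = max(1, int(round(record_dt / config.dt)))
    out = np.empty((n_steps // stride + 1, sites.size))
    stim_on = np.array([s[0] for s in (stimuli or [])], dtype=float)
    stim_dur = np.array([s[1] for s in (stimuli or [])], dtype=float)
    stim_amp = np.array([s[2] for s in (stimuli or [])], dtype=float)
    stim_nodes = np.zeros(config.nx * config.ny, dtype=np.bool_)
    if stimuli:
        for s in stimuli:
            stim_nodes[np.asarray(s[3], dtype=np.int64)] = True
    status = _SHEET_KERNELS[config.model_id](
        U, cell.params, get_tables(config.model_id, config.dt),
        config.nx, config.ny, config.d, config.dx,
        config.dt, n_steps, sites, stride, out,
        stim_on, stim_dur, stim_amp, stim_nodes)
    if status >= 0:
        raise FloatingPointError(f"sheet blow-up at t={status * config.dt:.1f} ms")
    if n_steps % stride == 0:
        out[n_steps // stride] = U[sites, 0]  # final state row
    t = np.arange(out.shape[0]) * stride * config.dt

    rising = (out[1:] > -40.0) & (out[:-1] <= -40.0)
    act_rows, _ = np.nonzero(rising)
    lifetime = float(t[1 + act_rows.max()]) if act_rows.size else 0.0
    sustained = bool(act_rows.size and t[1 + act_rows.max()] >= duration - 250.0)
    dfs = np.array([dominant_frequency(t, out[:, s],
                                       window=(0.0, duration))
                    for s in range(sites.size)])
    return ReentryMetrics(dominant_frequencies=dfs, sustained=sustained,
                          lifetime=lifetime, window=duration,
                          site_traces=out, t=t)


def dominant_frequency(t, v, window: tuple[float, float] | None = None,
                       fmin: float = 0.5) -> float:
    """Dominant frequency (Hz) of a voltage trace by Fourier analysis.

    Mean removal and Hann tapering; the spectral peak is searched above
    ``fmin`` (DC and slow drift excluded).  A quiescent trace (no -40 mV
    crossings) reports 0 Hz.  Frequency resolution is 1/window.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if t.size < 16:
        return 0.0
    crossings = np.any((v[1:] > -40.0) & (v[:-1] <= -40.0))
    if not crossings and np.ptp(v) < 1.0:
        return 0.0
    fs = 1000.0 / float(t[1] - t[0])  # Hz
    freqs, power = periodogram(v - np.mean(v), fs=fs, window="hann")
    band = freqs >= fmin
    if not np.any(band) or np.all(power[band] == 0):
        return 0.0
    return float(freqs[band][np.argmax(power[band])])
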