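"""Building and pacing human atrial cell model instances.

``build_cell`` assembles a parameter vector and initial state for one of the
model lineages:

* ``courtemanche`` -- the Courtemanche-lineage model with its native I_Kur;
* ``courtemanche_newIKur`` -- the same membrane model with the new I_Kur
  formulation swapped in (the "updated" lineage used for channel-level work);
* ``grandi`` -- the Grandi-lineage model (native EAD susceptibility under
  beta-adrenergic stimulation).

Mutations enter the first two via the new formulation's mutant models and
the native lineages via the published relative changes applied to the native
I_Kur Boltzmann curves.  Regional (RA/CT/PM), chronic-AF and ISO variants
are multiplicative conductance scalings from :mod:`kcna5.cells.variants`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kcna5.cells import courtemanche, grandi
from kcna5.cells.ikurshared import N_IKUR_PAR, ikur_param_block
from kcna5.cells.integrate import make_run
from kcna5.ikur import TABLE1_DELTAS, canonical_mutant_label, mutant_model, wt_model
from kcna5.cells.variants import (
    CAF_SCALINGS,
    ISO_SCALINGS,
    REGION_SCALINGS,
    VALID_REGIONS,
)

__all__ = [
    "MODEL_IDS",
    "CellInstance",
    "PacingProtocol",
    "build_cell",
    "run_cell",
    "pace",
    "steady_pace",
    "record_beat_with_ikur",
]

MODEL_IDS = ("courtemanche", "courtemanche_newIKur", "grandi")

_MODULES = {
    "courtemanche": courtemanche,
    "courtemanche_newIKur": courtemanche,
    "grandi": grandi,
}

_RUNNERS = {
    "courtemanche": make_run(courtemanche.step_fast),
    "courtemanche_newIKur": make_run(courtemanche.step_fast),
    "grandi": make_run(grandi.step_fast),
}

_TABLE_CACHE: dict[tuple, np.ndarray] = {}


def get_tables(model_id: str, dt: float) -> np.ndarray:
    """Per-(model, dt) cache of the voltage lookup tables."""
    key = (_MODULES[model_id].__name__, float(dt))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _MODULES[model_id].make_tables(float(dt))
    return _TABLE_CACHE[key]


@dataclass
class PacingProtocol:
    """S1(-S2) stimulation: ``n_s1`` beats at ``s1_cl`` ms, optional S2."""

    n_s1: int = 10
    s1_cl: float = 1000.0
    s2: float | None = None
    stim_amplitude: float = 20.0  # pA/pF
    stim_duration: float = 2.0    # ms

    def __post_init__(self) -> None:
        if self.s1_cl <= self.stim_duration:
            raise ValueError("s1_cl must exceed stim_duration")
        if self.s2 is not None and self.s2 <= 0:
            raise ValueError("s2 must be positive")

    def onsets(self) -> np.ndarray:
        t = [k * self.s1_cl for k in range(self.n_s1)]
        if self.s2 is not None:
            t.append((self.n_s1 - 1) * self.s1_cl + self.s2)
        return np.asarray(t, dtype=float)


@dataclass
class CellInstance:
    """One configured cell: parameter vector plus mutable state."""

    model_id: str
    region: str
    mutation: str | None
    caf: bool
    iso: bool
    params: np.ndarray
    state: np.ndarray

    @property
    def module(self):
        return _MODULES[self.model_id]

    def copy(self) -> "CellInstance":
        return CellInstance(self.model_id, self.region, self.mutation, self.caf,
                            self.iso, self.params.copy(), self.state.copy())


def _apply_scalings(p: np.ndarray, par_index: dict, scal: dict[str, float]) -> None:
    ik0 = par_index["ikur"]
    for key, factor in scal.items():
        if key == "g_kur":
            p[ik0 + 9] *= factor
        elif key == "serca_affinity":
            # higher affinity = lower half-saturation constant
            p[par_index["serca_km"]] /= factor
        else:
            if key not in par_index:
                raise KeyError(f"unknown scaling target {key!r}")
            p[par_index[key]] *= factor


def build_cell(
    model_id: str,
    region: str = "RA",
    mutation: str | None = None,
    caf: bool = False,
    iso: bool = False,
) -> CellInstance:
    """Assemble a cell instance; raises on unknown model/region/mutation."""
    if model_id not in MODEL_IDS:
        raise KeyError(f"unknown model_id {model_id!r}; valid: {MODEL_IDS}")
    if region not in VALID_REGIONS:
        raise KeyError(f"unknown region {region!r}; valid: {VALID_REGIONS}")
    mod = _MODULES[model_id]
    p = mod.default_params()
    idx = mod.PAR_INDEX
    _apply_scalings(p, idx, REGION_SCALINGS[region])
    if caf:
        _apply_scalings(p, idx, CAF_SCALINGS)
    if iso:
        _apply_scalings(p, idx, ISO_SCALINGS)

    label = canonical_mutant_label(mutation) if mutation is not None else None
    ik0 = idx["ikur"]
    variant_gkur = p[ik0 + 9]  # region/caf/iso scalings accumulated so far
    if model_id == "courtemanche_newIKur":
        channel = wt_model() if label in (None, "WT") else mutant_model(label)
        p[ik0:ik0 + N_IKUR_PAR] = ikur_param_block(channel, g_factor=variant_gkur)
    elif label is not None and label != "WT":
        d = TABLE1_DELTAS[label]
        blk = p[ik0:ik0 + N_IKUR_PAR]
        blk[1] += d.d_vhalf_act
        blk[2] *= d.k_act_factor
        blk[5] += d.d_vhalf_inact
        blk[6] *= d.k_inact_factor
        floor = float(np.clip(blk[8] + d.d_ma, 0.0, 1.0 - 1e-12))
        blk[7] = 1.0 - floor
        blk[8] = floor
        blk[9] *= d.g_factor
    return CellInstance(model_id=model_id, region=region, mutation=label,
                        caf=caf, iso=iso, params=p, state=mod.initial_state())


def run_cell(
    cell: CellInstance,
    duration: float,
    stim_onsets: np.ndarray,
    stim_amplitude: float = 20.0,
    stim_duration: float = 2.0,
    dt: float = 0.005,
    record_dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the cell in place for ``duration`` ms; return (t, V)."""
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    out = np.empty(n_steps // stride + 1)
    status = _RUNNERS[cell.model_id](
        cell.state, cell.params, get_tables(cell.model_id, dt), dt, n_steps,
        np.asarray(stim_onsets, dtype=float), stim_amplitude, stim_duration,
        stride, out)
    if status >= 0:
        raise FloatingPointError(
            f"non-finite state at t = {status * dt:.3f} ms "
            f"({cell.model_id}/{cell.region}/{cell.mutation}/caf={cell.caf}/"
            f"iso={cell.iso})")
    t = np.arange(out.size) * stride * dt
    return t, out


def pace(
    cell: CellInstance,
    protocol: PacingProtocol,
    dt: float = 0.005,
    record_dt: float = 0.1,
    tail: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply an S1(-S2) protocol; returns the full (t, V) recording."""
    onsets = protocol.onsets()
    duration = float(onsets[-1]) + tail
    return run_cell(cell, duration, onsets, protocol.stim_amplitude,
                    protocol.stim_duration, dt, record_dt)


def steady_pace(
    cell: CellInstance,
    n_beats: int = 100,
    cl: float = 1000.0,
    dt: float = 0.005,
    record_dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Precondition at a fixed cycle length; returns the final-beat trace.

    The cell's state is left at the end of the final cycle, ready for S2
    delivery or snapshotting.
    """
    if n_beats > 1:
        run_cell(cell, (n_beats - 1) * cl,
                 np.arange(n_beats - 1) * cl, dt=dt, record_dt=cl)
    return run_cell(cell, cl, np.zeros(1), dt=dt, record_dt=record_dt)


def record_beat_with_ikur(
    cell: CellInstance,
    cl: float = 1000.0,
    dt: float = 0.005,
    record_dt: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stimulated beat recording (t, V, I_Kur) from the current state.

    Python-level loop around the jitted step kernel, evaluating the I_Kur
    current from the recorded gates at every sample.
    """
    from kcna5.cells.ikurshared import new_ikur_g  # jitted; fine to call

    mod = cell.module
    idx = mod.PAR_INDEX["ikur"]
    blk = cell.params[idx:idx + N_IKUR_PAR]
    sv = mod.STATE_INDEX
    u, p = cell.state, cell.params
    n_steps = int(round(cl / dt))
    stride = max(1, int(round(record_dt / dt)))
    ts, vs, iks = [], [], []
    rtf = 26.712832  # mV at 310 K
    for k in range(n_steps):
        t = k * dt
        if k % stride == 0:
            v = u[sv["v"]]
            a, i = u[sv["a_kur"]], u[sv["i_kur"]]
            ki = u[sv["ki"]] if "ki" in sv else mod.KI_FIXED
            e_k = rtf * np.log(mod.KO / ki)
            if blk[0] < 0.5:
                if cell.model_id == "grandi":
                    ikur = blk[9] * a * i * (v - e_k)
                else:
                    g = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
                    ikur = g * blk[9] * a ** 3 * i * (v - e_k)
            else:
                ikur = new_ikur_g(v, blk) * a * i * (v - e_k)
            ts.append(t)
            vs.append(v)
            iks.append(ikur)
        istim = -20.0 if t < 2.0 else 0.0
        mod.step(u, p, dt, istim)
    return np.asarray(ts), np.asarray(vs), np.asarray(iks)
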