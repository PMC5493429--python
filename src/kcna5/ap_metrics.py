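"""Action-potential metrics, EAD detection and S1-S2 restitution.

Conventions
-----------
* Upstroke time: first rising crossing of -40 mV after the stimulus.
* Diastolic reference: the voltage immediately before the beat's stimulus
  (robust under rate changes).
* APD_x: time from upstroke to x% repolarisation between the AP peak and
  the diastolic reference; reported at the 0.1 ms recording resolution
  (at least the 1 ms measurement accuracy used throughout).
* Plateau potential: voltage at 50% of APD90 after the upstroke.
* EAD: a local voltage minimum followed by a local maximum with >= 2 mV
  prominence, between the AP peak and the terminal -40 mV downward crossing
  (or the end of the beat window when the AP has not repolarised by then).
  Depolarisation reversals whose maximum falls within the first 100 ms
  after the upstroke are not counted: the spike-notch-dome complex of
  Courtemanche-type morphologies produces exactly one such early reversal
  as part of the *normal* AP and must not register as an EAD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from kcna5.cells.base import CellInstance, run_cell

__all__ = ["APMetrics", "NoUpstrokeError", "measure_ap", "detect_eads",
           "ead_count_steady", "restitution", "RestitutionCurve"]

#: min-max reversals peaking within this window after the upstroke are the
#: notch-dome complex, not EADs
DOME_GUARD_MS = 100.0


class NoUpstrokeError(ValueError):
    """The beat window contains no rising -40 mV crossing."""


@dataclass
class APMetrics:
    """Scalar descriptors of one action potential."""

    rmp: float
    peak_v: float
    max_dvdt: float
    apd30: float
    apd90: float
    plateau_v: float
    ead_count: int

    def __post_init__(self) -> None:
        if np.isfinite(self.apd30) and np.isfinite(self.apd90) \
                and self.apd30 > self.apd90 + 1e-9:
            raise ValueError("APD30 cannot exceed APD90")


def _beat_window(t, stim_times, beat):
    stim_times = np.sort(np.asarray(stim_times, dtype=float))
    if beat < 0:
        beat = len(stim_times) + beat
    if not (0 <= beat < len(stim_times)):
        raise IndexError(f"beat {beat} outside the {len(stim_times)}-beat protocol")
    t0 = stim_times[beat]
    t1 = stim_times[beat + 1] if beat + 1 < len(stim_times) else t[-1]
    i0 = int(np.searchsorted(t, t0 - 1e-9))
    i1 = int(np.searchsorted(t, t1 - 1e-9))
    return i0, i1


def _upstroke_index(v, start):
    above = (v[start + 1:] > -40.0) & (v[start:-1] <= -40.0)
    hits = np.where(above)[0]
    if hits.size == 0:
        raise NoUpstrokeError("no rising -40 mV crossing in beat window")
    return start + 1 + int(hits[0])


def detect_eads(t, v, stim_times, beat: int = -1,
                prominence: float = 2.0) -> int:
    """Count EADs on one beat (see module docstring for the definition)."""
    i0, i1 = _beat_window(t, stim_times, beat)
    try:
        iup = _upstroke_index(v, i0)
    except NoUpstrokeError:
        if i1 <= i0 + 2 or v[i0] <= -40.0:
            return 0  # empty or quiescent window: nothing to count
        # the previous beat never repolarised (ongoing EAD salvo): count
        # every prominent depolarisation reversal in the window
        seg = v[i0:i1]
        ipk = int(np.argmax(seg))
        peaks, _ = find_peaks(seg[ipk:], prominence=prominence)
        return max(int(peaks.size), 1)
    seg = v[iup:i1]
    ipk = int(np.argmax(seg))
    below = np.where(seg[ipk:] < -40.0)[0]
    iend = ipk + (int(below[0]) if below.size else seg.size - ipk)
    window = seg[ipk:iend]
    if window.size < 3:
        return 0
    peaks, _ = find_peaks(window, prominence=prominence)
    t_up = t[iup]
    times = t[iup + ipk + peaks] - t_up
    return int(np.sum(times >= DOME_GUARD_MS))


def ead_count_steady(t, v, stim_times, n_final: int = 2,
                     prominence: float = 2.0) -> int:
    """Steady-pacing EAD count: maximum over the final ``n_final`` beats.

    EAD-bearing cells paced near their EAD-prolonged AP duration settle into
    2:1 alternation (an EAD-salvo beat followed by a short recovered beat),
    so a single-beat count depends on beat parity; the maximum over one
    alternation cycle is the parity-robust readout.
    """
    n = len(np.asarray(stim_times))
    beats = range(max(0, n - n_final), n)
    return max(detect_eads(t, v, stim_times, beat=b, prominence=prominence)
               for b in beats)


def measure_ap(t, v, stim_times, beat: int = -1) -> APMetrics:
    """Measure one beat of a voltage recording.

    ``stim_times`` are the stimulus onsets of the protocol that produced the
    trace; the beat window runs from its stimulus to the next (or trace end).
    Raises :class:`NoUpstrokeError` when the stimulus did not elicit an AP.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    i0, i1 = _beat_window(t, stim_times, beat)
    iup = _upstroke_index(v, i0)
    diastolic = v[max(i0 - 1, 0)] if i0 > 0 else v[0]
    seg = v[iup:i1]
    tseg = t[iup:i1]
    ipk = int(np.argmax(seg))
    peak = float(seg[ipk])
    dvdt = float(np.max(np.diff(v[i0:i1]) / np.diff(t[i0:i1])))

    def apd(frac):
        thr = peak - frac * (peak - diastolic)
        below = np.where(seg[ipk:] < thr)[0]
        if below.size == 0:
            return float("nan")
        return float(tseg[ipk + below[0]] - tseg[0])

    apd30, apd90 = apd(0.30), apd(0.90)
    if np.isfinite(apd90):
        iplat = int(np.searchsorted(tseg, tseg[0] + 0.5 * apd90))
        plateau = float(seg[min(iplat, seg.size - 1)])
    else:
        plateau = float("nan")
    return APMetrics(
        rmp=float(diastolic), peak_v=peak, max_dvdt=dvdt,
        apd30=apd30, apd90=apd90, plateau_v=plateau,
        ead_count=detect_eads(t, v, stim_times, beat),
    )


@dataclass
class RestitutionCurve:
    """APD90 of the S2 beat versus the S2 coupling interval."""

    table: pd.DataFrame  # columns: s2_ms, apd90_ms, captured

    def __post_init__(self) -> None:
        s2 = self.table["s2_ms"].to_numpy()
        if not np.all(np.diff(s2) > 0):
            raise ValueError("s2 values must be strictly increasing")

    def captured(self) -> pd.DataFrame:
        return self.table[self.table["captured"]]


def restitution(
    cell: CellInstance,
    s2_grid,
    n_s1: int = 100,
    s1_cl: float = 1000.0,
    stim_amplitude: float = 20.0,
    stim_duration: float = 2.0,
    dt: float = 0.005,
) -> RestitutionCurve:
    """S1-S2 APD restitution.

    The cell is conditioned once with ``n_s1`` S1 beats; the post-train state
    is reused for every S2 (the S2 is delivered after the final S1).  S2
    values that fail to capture are flagged, not dropped.
    """
    s2_grid = np.sort(np.asarray(s2_grid, dtype=float))
    cond = cell.copy()
    if n_s1 > 1:  # all S1 beats except the final one, which the trial delivers
        run_cell(cond, (n_s1 - 1) * s1_cl, np.arange(n_s1 - 1) * s1_cl,
                 stim_amplitude, stim_duration, dt=dt, record_dt=s1_cl)
    rows = []
    for s2 in s2_grid:
        trial = cond.copy()
        onsets = np.array([0.0, s2])
        t, v = run_cell(trial, s2 + 800.0, onsets,
                        stim_amplitude, stim_duration, dt=dt, record_dt=0.1)
        try:
            m = measure_ap(t, v, onsets, beat=1)
            captured = m.peak_v > -10.0
            apd = m.apd90 if captured else float("nan")
        except NoUpstrokeError:
            captured, apd = False, float("nan")
        rows.append({"s2_ms": s2, "apd90_ms": apd, "captured": captured})
    return RestitutionCurve(table=pd.DataFrame(rows))
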