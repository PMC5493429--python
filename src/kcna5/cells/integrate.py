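"""Numba driver factories shared by the cell models.

Each cell model exposes an in-place ``step(u, p, dt, istim)`` kernel; the
factories below close over it to build jitted single-cell pacing loops.
Stimuli are rectangular current pulses (pA/pF, depolarising = negative in
the membrane equation, passed here as positive amplitudes).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["make_run"]


def make_run(step):
    """Jitted single-cell run loop for one model's table-driven step kernel.

    Records the membrane voltage every ``rec_stride`` steps into ``out_v``.
    Returns -1 on success or the step index at which the state became
    non-finite (integration blow-up).
    """

    @njit(cache=False)
    def run(u, p, tab, dt, n_steps, stim_onsets, stim_amp, stim_dur, rec_stride, out_v):
        idx = 0
        n_on = stim_onsets.size
        for k in range(n_steps):
            t = k * dt
            while idx < n_on and t >= stim_onsets[idx] + stim_dur:
                idx += 1
            istim = 0.0
            if idx < n_on and stim_onsets[idx] <= t < stim_onsets[idx] + stim_dur:
                istim = -stim_amp
            if k % rec_stride == 0:
                out_v[k // rec_stride] = u[0]
            step(u, p, tab, dt, istim)
            if k % 2000 == 0 and not np.isfinite(u[0]):
                return k
        if n_steps % rec_stride == 0 and out_v.size > n_steps // rec_stride:
            out_v[n_steps // rec_stride] = u[0]
        if not np.isfinite(u[0]):
            return n_steps
        return -1

    return run
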