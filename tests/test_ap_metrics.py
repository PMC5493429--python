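"""AP measurement, EAD detection and restitution on synthetic and model traces."""

import numpy as np
import pytest

from kcna5.ap_metrics import (
    APMetrics,
    NoUpstrokeError,
    detect_eads,
    ead_count_steady,
    measure_ap,
    restitution,
)
from kcna5.cells.base import PacingProtocol, build_cell, pace, steady_pace


def _trapezoid_ap(rest=-80.0, peak=20.0, upstroke_ms=1.0, plateau_ms=50.0,
                  repol_ms=300.0, total_ms=600.0, dt=0.1):
    """Piecewise-linear synthetic AP with closed-form APD."""
    t = np.arange(0.0, total_ms, dt)
    v = np.full(t.size, rest)
    stim = 5.0
    up = (t >= stim) & (t < stim + upstroke_ms)
    v[up] = rest + (peak - rest) * (t[up] - stim) / upstroke_ms
    plat = (t >= stim + upstroke_ms) & (t < stim + upstroke_ms + plateau_ms)
    v[plat] = peak
    rep = (t >= stim + upstroke_ms + plateau_ms) \
        & (t < stim + upstroke_ms + plateau_ms + repol_ms)
    v[rep] = peak - (peak - rest) * (t[rep] - (stim + upstroke_ms + plateau_ms)) / repol_ms
    return t, v, stim, upstroke_ms, plateau_ms, repol_ms, rest, peak


class TestMeasureAP:
    def test_trapezoid_apd90_matches_analytic_geometry(self):
        t, v, stim, up_ms, plat_ms, rep_ms, rest, peak = _trapezoid_ap()
        m = measure_ap(t, v, np.array([stim]))
        # upstroke (-40 crossing) happens at stim + 0.4*up_ms; 90% repol at
        # plateau end + 0.9*rep_ms
        t_up = stim + up_ms * (rest + 40.0) / (rest - peak) * -1.0
        t_up = stim + up_ms * ((-40.0 - rest) / (peak - rest))
        t90 = stim + up_ms + plat_ms + 0.9 * rep_ms
        assert m.apd90 == pytest.approx(t90 - t_up, abs=1.0)
        assert m.apd30 == pytest.approx(stim + up_ms + plat_ms + 0.3 * rep_ms - t_up,
                                        abs=1.0)
        assert m.peak_v == pytest.approx(20.0)
        assert m.rmp == pytest.approx(-80.0)
        assert m.ead_count == 0

    def test_no_upstroke_raises(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = np.full(t.size, -80.0)
        with pytest.raises(NoUpstrokeError):
            measure_ap(t, v, np.array([5.0]))

    def test_apmetrics_invariant(self):
        with pytest.raises(ValueError):
            APMetrics(rmp=-80, peak_v=20, max_dvdt=100, apd30=200.0,
                      apd90=100.0, plateau_v=-20, ead_count=0)


class TestDetectEads:
    def test_monotone_repolarisation_counts_zero(self):
        t, v, stim, *_ = _trapezoid_ap()
        assert detect_eads(t, v, np.array([stim])) == 0

    def test_single_plateau_bump_counts_one(self):
        t, v, stim, *_ = _trapezoid_ap()
        # 10 mV bump well after the dome-guard window
        bump = (t > 170) & (t < 210)
        v2 = v.copy()
        v2[bump] += 10.0 * np.sin(np.pi * (t[bump] - 170) / 40.0)
        assert detect_eads(t, v2, np.array([stim])) == 1

    def test_early_dome_reversal_not_counted(self):
        # the spike-notch-dome of Courtemanche-type APs is not an EAD
        t, v, stim, *_ = _trapezoid_ap()
        bump = (t > 20) & (t < 60)
        v2 = v.copy()
        v2[bump] += 8.0 * np.sin(np.pi * (t[bump] - 20) / 40.0)
        assert detect_eads(t, v2, np.array([stim])) == 0

    def test_sub_prominence_ripple_ignored(self):
        t, v, stim, *_ = _trapezoid_ap()
        ripple = (t > 150) & (t < 250)
        v2 = v.copy()
        v2[ripple] += 0.8 * np.sin((t[ripple]) * 0.9)
        assert detect_eads(t, v2, np.array([stim])) == 0

    def test_steady_count_is_max_over_final_beats(self):
        # two-beat window covers 2:1 alternation of EAD-bearing beats
        t = np.arange(0.0, 2000.0, 0.5)
        v = np.full(t.size, -80.0)
        onsets = np.array([0.0, 1000.0])
        for start, with_ead in ((0.0, True), (1000.0, False)):
            up = (t >= start + 5) & (t < start + 400)
            v[up] = 10.0 - 80.0 * (t[up] - start - 5) / 395.0
            if with_ead:
                bump = (t > start + 150) & (t < start + 190)
                v[bump] += 12.0
        assert ead_count_steady(t, v, onsets, n_final=2) >= 1


class TestRestitution:
    @pytest.fixture(scope="class")
    def cell(self):
        return build_cell("courtemanche_newIKur")

    def test_s2_equal_to_s1_matches_steady_apd(self, cell):
        from kcna5.ap_metrics import measure_ap

        work = cell.copy()
        proto = PacingProtocol(n_s1=20, s1_cl=1000.0)
        t, v = pace(work, proto, tail=1000.0)
        steady = measure_ap(t, v, proto.onsets(), beat=-1).apd90

        rc = restitution(cell.copy(), [1000.0], n_s1=20, s1_cl=1000.0)
        assert rc.table["apd90_ms"].iloc[0] == pytest.approx(steady, abs=2.0)

    def test_monotone_non_decreasing_at_long_coupling(self, cell):
        rc = restitution(cell.copy(), [400.0, 600.0, 800.0, 1000.0], n_s1=15)
        apds = rc.captured()["apd90_ms"].to_numpy()
        assert apds.size >= 3
        assert np.all(np.diff(apds) >= -0.5)

    def test_below_capture_flagged_not_dropped(self, cell):
        rc = restitution(cell.copy(), [120.0, 800.0], n_s1=10)
        tab = rc.table
        assert tab.shape[0] == 2
        assert not tab["captured"].iloc[0]
        assert tab["captured"].iloc[1]
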