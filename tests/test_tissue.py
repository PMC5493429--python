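"""Monodomain strand: solver invariants, CV measurement, S1-S2 machinery."""

import numpy as np
import pytest

from kcna5.cells.base import build_cell, run_cell
from kcna5.tissue import (
    CableConfig,
    CableStimulus,
    ConductionBlockError,
    SpaceTimeRecord,
    activation_time,
    ct_pm_strand,
    measure_cv,
    s1s2_outcome,
    solve_cable,
    strand_cv,
)


@pytest.fixture(scope="module")
def small_cfg():
    return CableConfig(model_id="courtemanche_newIKur", n_nodes=60, dx=0.25,
                       d=0.3, precondition_beats=20)


class TestSolver:
    def test_zero_coupling_matches_isolated_cell(self):
        """With D = 0 every node evolves exactly like the single cell."""
        cfg = CableConfig(model_id="courtemanche", n_nodes=50, dx=0.25, d=0.0,
                          precondition_beats=0, dt=0.02)
        rec = solve_cable(cfg, [CableStimulus(0, 50, onset=5.0)], 100.0,
                          record_dt=1.0)
        cell = build_cell("courtemanche")
        t, v = run_cell(cell, 100.0, np.array([5.0]), stim_amplitude=40.0,
                        stim_duration=2.0, dt=0.02, record_dt=1.0)
        for node in (0, 10, 49):
            assert np.max(np.abs(rec.v[:, node] - v[: rec.v.shape[0]])) < 1e-9

    def test_zero_coupling_confines_local_stimulus(self):
        cfg = CableConfig(model_id="courtemanche", n_nodes=50, dx=0.25, d=0.0,
                          precondition_beats=0, dt=0.02)
        rec = solve_cable(cfg, [CableStimulus(0, 3, onset=5.0)], 60.0,
                          record_dt=1.0)
        assert rec.v[:, 0].max() > 0.0
        assert rec.v[:, 10].max() < -60.0

    def test_midpoint_stimulus_is_symmetric(self, small_cfg):
        n = small_cfg.n_nodes
        rec = solve_cable(small_cfg, [CableStimulus(n // 2 - 2, n // 2 + 2,
                                                    onset=5.0)], 80.0,
                          record_dt=0.5)
        for off in (5, 10, 20):
            ta = activation_time(rec, n // 2 - 1 - off)
            tb = activation_time(rec, n // 2 + off)
            assert ta == pytest.approx(tb, abs=small_cfg.dt + 0.5)

    def test_stability_bound_enforced(self):
        with pytest.raises(ValueError):
            solve_cable(CableConfig(n_nodes=60, d=2.5, dt=0.02,
                                    precondition_beats=0),
                        [CableStimulus(0, 3, onset=5.0)], 10.0)


class TestCV:
    def test_synthetic_linear_ramp_gives_unit_velocity(self):
        # activation time grows 1 ms per mm -> 1 m/s; a finite-slope upstroke
        # makes the interpolated -40 mV crossing exact
        x = np.arange(100) * 0.25
        t = np.arange(0.0, 60.0, 0.1)
        phase = t[:, None] - (5.0 + x[None, :] / 1.0)
        v = -80.0 + 100.0 * np.clip(phase / 2.0, 0.0, 1.0)
        rec = SpaceTimeRecord(t=t, x=x, v=v, final_state=np.zeros((100, 1)))
        assert measure_cv(rec) == pytest.approx(1.0, rel=1e-3)

    def test_blocked_wave_raises(self):
        x = np.arange(100) * 0.25
        t = np.arange(0.0, 60.0, 0.1)
        v = np.full((t.size, x.size), -80.0)
        v[:, :10] = 20.0
        rec = SpaceTimeRecord(t=t, x=x, v=v, final_state=np.zeros((100, 1)))
        with pytest.raises(ConductionBlockError):
            measure_cv(rec)

    def test_cv_scales_as_sqrt_of_diffusion(self):
        cfg = CableConfig(model_id="courtemanche_newIKur", n_nodes=200,
                          dx=0.25, precondition_beats=30)
        cv1 = strand_cv(cfg, 0.6)
        cv2 = strand_cv(cfg, 0.15)
        assert cv1 / cv2 == pytest.approx(2.0, rel=0.10)

    def test_cv_converges_in_dx(self):
        cvs = []
        for dx, n in ((0.25, 200), (0.125, 400)):
            cfg = CableConfig(model_id="courtemanche_newIKur", n_nodes=n,
                              dx=dx, d=0.6, dt=0.01, precondition_beats=30)
            cvs.append(strand_cv(cfg))
        assert abs(cvs[1] - cvs[0]) / cvs[1] < 0.03

    def test_strand_cv_is_deterministic(self):
        cfg = CableConfig(model_id="courtemanche_newIKur", n_nodes=100,
                          dx=0.25, precondition_beats=20)
        assert strand_cv(cfg, 0.5) == strand_cv(cfg, 0.5)


class TestS1S2:
    @pytest.fixture(scope="class")
    def homogeneous(self):
        from kcna5.tissue import post_s1_state

        cfg = CableConfig(model_id="courtemanche_newIKur", n_nodes=120,
                          dx=0.25, d=0.6, precondition_beats=20)
        return cfg, post_s1_state(cfg)

    def test_homogeneous_strand_never_unidirectional(self, homogeneous):
        cfg, cached = homogeneous
        for s2 in (180.0, 260.0, 420.0):
            out = s1s2_outcome(cfg, s2, cached)
            assert not out.unidirectional, s2

    def test_long_s2_conducts_and_short_s2_blocks(self, homogeneous):
        cfg, cached = homogeneous
        assert s1s2_outcome(cfg, 450.0, cached).label == "bidirectional_conduction"
        assert s1s2_outcome(cfg, 120.0, cached).label == "bidirectional_block"

    def test_s2_inside_s1_train_rejected(self):
        cfg = ct_pm_strand("courtemanche_newIKur", n_nodes=100, d=0.6,
                           precondition_beats=10)
        with pytest.raises(ValueError):
            s1s2_outcome(cfg, 1.0, cached=(np.zeros((100, 21)), 3002.0))


def test_config_validation():
    with pytest.raises(ValueError):
        CableConfig(n_nodes=10)
    with pytest.raises(ValueError):
        CableConfig(dx=0.05)
    with pytest.raises(ValueError):
        CableConfig(d=-0.1)
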