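import math

import numpy as np
import pytest

import homebase as hb
from homebase.endpoints import (AutoThresholdWarning, compute_endpoints,
                                label_progression, room_coverage,
                                transform_value)
from homebase.tracking import Trajectory
from homebase.visits import DistanceSeries


class TestLabelProgression:
    def test_stationary_all_lingering(self):
        t = 0.5 * np.arange(200)
        traj = Trajectory(t, np.full(200, 10.0), np.full(200, 10.0))
        with pytest.warns(AutoThresholdWarning):
            labels, thr = label_progression(traj, "auto")
        assert not labels.any()
        assert thr == 5.0

    def test_constant_motion_all_progression(self):
        t = 0.5 * np.arange(200)
        traj = Trajectory(t, 20.0 * t, np.full(200, 10.0))
        labels, _ = label_progression(traj, speed_threshold=5.0)
        assert labels.all()

    def test_auto_threshold_separates_two_modes(self):
        """Speeds generated at 1 and 20 cm/s: the antimode threshold
        lands between the modes and labels match the generation."""
        rng = np.random.default_rng(9)
        slow = rng.lognormal(np.log(1.0), 0.2, 500)
        fast = rng.lognormal(np.log(20.0), 0.2, 500)
        steps = 0.5 * np.concatenate([slow, fast])
        x = np.concatenate([[0.0], np.cumsum(steps)])
        traj = Trajectory(0.5 * np.arange(len(x)), x, np.zeros(len(x)))
        labels, thr = label_progression(traj, "auto")
        assert 2.0 < thr < 15.0
        # interior of each half labels correctly (gradient mixes edges)
        assert not labels[10:490].any()
        assert labels[510:990].all()


class TestRoomCoverage:
    def test_stationary_covers_one_cell(self, room):
        t = 0.5 * np.arange(10)
        traj = Trajectory(t, np.full(10, 12.3), np.full(10, 45.6))
        assert room_coverage(traj, room) == pytest.approx(1.0 / (365 * 545))

    def test_wall_to_wall_line_rasterized(self, room):
        # straight 545-cm path along a grid line covers ~545 cells
        n = 50
        t = 0.5 * np.arange(n)
        traj = Trajectory(t, np.full(n, 100.5), np.linspace(0.0, 544.9, n))
        cov = room_coverage(traj, room)
        assert cov * 365 * 545 == pytest.approx(545, abs=2)

    def test_coverage_bounds(self, td_session, room):
        traj, _ = td_session
        cov = room_coverage(traj, room)
        assert 0.0 < cov <= 1.0


def _simple_session(near_fraction=0.4, n=1000, dt=0.5):
    """Piecewise trajectory with an exact fraction of samples within
    100 cm of the mother at (182.5, 25)."""
    n_near = int(near_fraction * n)
    x = np.full(n, 182.5)
    y = np.concatenate([np.full(n_near, 50.0), np.full(n - n_near, 300.0)])
    return Trajectory(dt * np.arange(n), x, y, session_id="s")


class TestComputeEndpoints:
    def test_programmed_near_fraction_and_logit(self, room):
        traj = _simple_session(0.4)
        d = hb.distance_to_point(traj, room.mother.center)
        rec = compute_endpoints(traj, room, d, excursions=[], contacts=[],
                                speed_threshold=5.0)
        assert rec.prop_time_near_mother == pytest.approx(0.4)
        assert transform_value(0.4, "logit") == pytest.approx(
            math.log(0.4 / 0.6), abs=1e-9)

    def test_rate_and_sqrt_transform(self):
        assert transform_value(12 / 30.0, "sqrt") == pytest.approx(0.632, abs=5e-4)

    def test_all_near_session_clamped_logit(self, room):
        traj = _simple_session(1.0)
        d = hb.distance_to_point(traj, room.mother.center)
        with pytest.warns(UserWarning, match="never outside"):
            rec = compute_endpoints(traj, room, d, [], [], speed_threshold=5.0)
        assert rec.prop_time_near_mother == 1.0
        assert math.isnan(rec.avg_speed_outside_mother)
        tf = rec.transformed(n_samples=len(traj))["prop_time_near_mother"]
        expected_p = 1.0 - 1.0 / (2 * len(traj))
        assert tf == pytest.approx(math.log(expected_p / (1 - expected_p)))

    def test_monotone_transform_preserves_wilcoxon(self, room, no_maps_config):
        """Ranks are invariant to sqrt/logit, so W computed on raw and
        transformed endpoint values is identical."""
        vals_x, vals_y = [], []
        for seed in range(4):
            traj, _ = hb.simulate_session(hb.td_params(), room, seed=seed)
            r = hb.analyze_session(traj, room, no_maps_config, group="TD")
            vals_x.append(r.endpoints)
        for seed in range(4):
            traj, _ = hb.simulate_session(hb.ntd_params(), room, seed=seed)
            r = hb.analyze_session(traj, room, no_maps_config, group="NTD")
            vals_y.append(r.endpoints)
        raw_x = [v.prop_time_near_mother for v in vals_x]
        raw_y = [v.prop_time_near_mother for v in vals_y]
        tf_x = [v.transformed(3600)["prop_time_near_mother"] for v in vals_x]
        tf_y = [v.transformed(3600)["prop_time_near_mother"] for v in vals_y]
        w_raw, p_raw = hb.wilcoxon_exact(raw_x, raw_y)
        w_tf, p_tf = hb.wilcoxon_exact(tf_x, tf_y)
        assert w_raw == w_tf and p_raw == p_tf
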