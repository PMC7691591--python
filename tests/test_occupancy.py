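import numpy as np
import pytest

import homebase as hb
from homebase.occupancy import (_truncated_gaussian_kernel, DwellMap,
                                annotate_peak_visits, compute_dwell_map,
                                find_peak_places, smooth_dwell_map)
from homebase.tracking import Trajectory
from homebase.visits import RingParams


def stationary_traj(x=100.0, y=200.0, n=100, dt=0.5):
    t = dt * np.arange(n)
    return Trajectory(t, np.full(n, x), np.full(n, y))


class TestComputeDwellMap:
    def test_stationary_mass_in_single_cell(self, room):
        dmap = compute_dwell_map(stationary_traj(), room)
        assert dmap.values[100, 200] == pytest.approx(50.0)
        assert dmap.total == pytest.approx(50.0)
        assert np.count_nonzero(dmap.values) == 1

    def test_total_mass_equals_duration(self, room, td_session):
        traj, _ = td_session
        dmap = compute_dwell_map(traj, room)
        assert dmap.total == pytest.approx(len(traj) * traj.dt)

    def test_alternating_two_cells_equal_mass(self, room):
        t = 0.5 * np.arange(100)
        x = np.where(np.arange(100) % 2 == 0, 10.2, 50.7)
        traj = Trajectory(t, x, np.full(100, 30.0))
        dmap = compute_dwell_map(traj, room)
        assert dmap.values[10, 30] == dmap.values[50, 30] == pytest.approx(25.0)

    def test_invalid_cell_size(self, room):
        with pytest.raises(ValueError):
            compute_dwell_map(stationary_traj(), room, cell_cm=0.0)


class TestSmoothDwellMap:
    def test_kernel_window_extent(self):
        k = _truncated_gaussian_kernel(14.0, 31.0, 1.0)
        assert k.shape == (63, 63)
        assert k.sum() == pytest.approx(1.0)
        # weights beyond the truncation radius are zero
        assert k[0, 0] == 0.0 and k[31, 0] > 0.0

    def test_uniform_map_unchanged_in_interior(self, room):
        vals = np.full((365, 545), 2.0)
        sm = smooth_dwell_map(DwellMap(vals))
        # constants survive wherever no clipped window contributes
        interior = sm.values[62:-62, 62:-62]
        np.testing.assert_allclose(interior, 2.0, rtol=1e-9)

    def test_point_mass_center_value_matches_kernel(self, room):
        vals = np.zeros((365, 545))
        vals[180, 270] = 7.0  # far from all walls
        k = _truncated_gaussian_kernel(14.0, 31.0, 1.0)
        sm = smooth_dwell_map(DwellMap(vals))
        assert sm.values[180, 270] == pytest.approx(7.0 * k[31, 31], rel=1e-9)

    def test_mass_conserved_with_wall_adjacent_dwell(self, room, td_session):
        """Total dwell survives smoothing even though the mother (and
        most of the dwell mass) sits against a wall."""
        traj, _ = td_session
        raw = compute_dwell_map(traj, room)
        sm = smooth_dwell_map(raw)
        assert abs(sm.total - raw.total) / raw.total <= 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            smooth_dwell_map(DwellMap(np.ones((10, 10))), sigma_cm=-1.0)
        with pytest.raises(ValueError):
            smooth_dwell_map(DwellMap(np.ones((10, 10))), sigma_cm=14, truncate_cm=7)


def bump_map(centers_heights, shape=(365, 545), sigma=6.0):
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    vals = np.zeros(shape)
    for (cx, cy), h in centers_heights:
        vals += h * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return DwellMap(vals, smoothed=True)


class TestFindPeakPlaces:
    def test_single_bump_center_retained(self):
        peaks = find_peak_places(bump_map([((120, 300), 5.0)]))
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx((120.5, 300.5), abs=0.6)

    def test_keep_top_four_percent_of_many_maxima(self):
        """With 100 separated maxima of distinct heights the 4% rule
        retains exactly the 4 highest."""
        rng = np.random.default_rng(1)
        heights = rng.permutation(np.linspace(1.0, 2.0, 100))
        centers = [(30 + 60 * (i % 6), 30 + 55 * (i // 6)) for i in range(100)]
        peaks = find_peak_places(bump_map(list(zip(centers, heights)),
                                          shape=(400, 1000), sigma=4.0))
        assert len(peaks) == 4
        top4 = sorted(heights)[-4:]
        assert min(p.value for p in peaks) == pytest.approx(min(top4), rel=0.05)

    def test_equal_height_pair_both_retained(self):
        peaks = find_peak_places(bump_map([((80, 100), 3.0), ((280, 400), 3.0)]))
        assert len(peaks) == 2

    def test_all_zero_map_empty(self):
        assert find_peak_places(DwellMap(np.zeros((50, 50)))) == []

    def test_plateau_collapses_to_centroid(self):
        vals = np.zeros((50, 50))
        vals[10:13, 20:23] = 1.0  # 3x3 plateau
        peaks = find_peak_places(DwellMap(vals))
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx((11.5, 21.5))

    def test_nearby_satellite_suppressed(self):
        peaks = find_peak_places(bump_map([((100, 100), 5.0), ((100, 130), 4.0),
                                           ((300, 400), 3.0)]))
        centers = [p.center for p in peaks]
        assert all(abs(c[1] - 130.5) > 1 for c in centers)  # satellite gone
        assert peaks[0].center == pytest.approx((100.5, 100.5), abs=1.0)


class TestAnnotatePeakVisits:
    def test_never_approached_peak_has_zero_visits(self, room):
        traj = stationary_traj(x=50, y=50)
        peaks = find_peak_places(bump_map([((300, 500), 2.0)]))
        annotate_peak_visits(traj, peaks)
        assert peaks[0].n_visits == 0

    def test_programmed_approaches_counted(self, room):
        # three approaches below 30 cm separated by retreats beyond 50 cm
        target = np.array([200.0, 300.0])
        path = []
        for _ in range(3):
            path += [target + [0, 150]] * 5 + [target + [0, 10]] * 5
        path += [target + [0, 150]] * 5
        path = np.array(path)
        traj = Trajectory(0.5 * np.arange(len(path)), path[:, 0], path[:, 1])
        peaks = [hb.PeakPlace(center=(200.0, 300.0), value=1.0)]
        annotate_peak_visits(traj, peaks, RingParams(30, 50))
        assert peaks[0].n_visits == 3

    def test_stationary_at_peak_single_opening_visit(self):
        traj = stationary_traj(x=200, y=300)
        peaks = [hb.PeakPlace(center=(200.0, 300.0), value=1.0)]
        annotate_peak_visits(traj, peaks)
        assert peaks[0].n_visits == 1 and not peaks[0].visits[0].complete


class TestArchetypeStructure:
    def test_td_home_base_at_mother(self, room, td_result):
        """TD sessions place the top dwell peak beside mother and that
        peak also collects the most visits (the home-base signature)."""
        top = td_result.peaks[0]
        dist = np.hypot(top.center[0] - room.mother.center[0],
                        top.center[1] - room.mother.center[1])
        assert dist < 50.0
        assert top.n_visits == max(p.n_visits for p in td_result.peaks)

    def test_ntd_top_peak_away_from_mother(self, room, ntd_session):
        traj, _ = ntd_session
        res = hb.analyze_session(traj, room, hb.RunConfig(), group="NTD")
        top = res.peaks[0]
        dist = np.hypot(top.center[0] - room.mother.center[0],
                        top.center[1] - room.mother.center[1])
        assert dist > 100.0
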