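import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import homebase as hb
from homebase.stats import (GroupCurves, bh_adjust, compare_groups,
                            curve_permutation_test, pooled_effect_size,
                            wilcoxon_exact)


def enumeration_oracle(x, y):
    """Naive exact two-sided rank-sum p by brute-force enumeration."""
    pooled = np.concatenate([x, y])
    n, k = len(pooled), len(x)

    def u_stat(xs, ys):
        xs = np.asarray(xs)[:, None]
        return float(np.sum(xs > ys) + 0.5 * np.sum(xs == ys))

    u_obs = u_stat(x, np.asarray(y))
    us = []
    for idx in combinations(range(n), k):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        us.append(u_stat(pooled[sel], pooled[~sel]))
    us = np.array(us)
    upper = np.mean(us >= u_obs - 1e-9)
    lower = np.mean(us <= u_obs + 1e-9)
    return u_obs, min(1.0, 2 * min(upper, lower))


class TestWilcoxonExact:
    def test_complete_separation_five_vs_seven(self):
        """Complete separation at n=(5,7): W = 35 and p = 2/792."""
        w, p = wilcoxon_exact([10, 11, 12, 13, 14], [1, 2, 3, 4, 5, 6, 7])
        assert w == 35
        assert p == pytest.approx(2 / 792, abs=1e-12)

    def test_symmetric_interleaving_gives_p_one(self):
        w, p = wilcoxon_exact([1, 4, 5, 8], [2, 3, 6, 7])
        assert w == 8  # null-centred U = n1*n2/2
        assert p == 1.0

    def test_tiny_case_enumerated_by_hand(self):
        # x={3,4}, y={1,2}: only the observed assignment is as extreme
        # in the upper tail; doubling gives 2/6
        _, p = wilcoxon_exact([3, 4], [1, 2])
        assert p == pytest.approx(2 / 6)

    @pytest.mark.parametrize("nx,ny", [(2, 3), (4, 4), (5, 7), (3, 8)])
    def test_matches_scipy_exact(self, nx, ny):
        rng = np.random.default_rng(nx * 100 + ny)
        for _ in range(5):
            x = rng.normal(size=nx)
            y = rng.normal(0.5, size=ny)
            w, p = wilcoxon_exact(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert w == ref.statistic
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_match_enumeration_oracle(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 3.0]
        w, p = wilcoxon_exact(x, y)
        w_ref, p_ref = enumeration_oracle(np.array(x), np.array(y))
        assert (w, p) == (w_ref, pytest.approx(p_ref))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([], [1.0])


class TestPooledEffectSize:
    def test_reported_row_worked_example(self):
        """Samples constructed with means difference 1.98 and pooled SD
        0.987 (the time-near-mother row) give effect size 2.01 (2 d.p.)."""
        x = np.array([1.98 - 0.987, 1.98, 1.98 + 0.987])
        y = np.array([-0.987, 0.0, 0.987])
        diff, sp, es = pooled_effect_size(x, y)
        assert diff == pytest.approx(1.98)
        assert sp == pytest.approx(0.987)
        assert round(es, 2) == 2.01

    def test_effect_size_formula(self):
        diff, sp, es = pooled_effect_size([2.0, 4.0], [1.0, 3.0])
        assert diff == 1.0
        assert sp == pytest.approx(math.sqrt(2))
        assert es == pytest.approx(1 / math.sqrt(2))

    def test_identical_groups_zero_effect(self):
        diff, _, es = pooled_effect_size([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert diff == 0.0 and es == 0.0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            pooled_effect_size([1.0, 1.0], [2.0, 2.0])


class TestBHAdjust:
    def test_seven_endpoint_worked_vector(self):
        """The published seven raw p-values adjust to the published
        column at 4 decimal places."""
        raw = [0.00252, 0.00252, 0.14899, 0.04798, 0.01010, 0.03030, 0.00505]
        expected = [0.0088, 0.0088, 0.1490, 0.0560, 0.0177, 0.0424, 0.0118]
        np.testing.assert_allclose(np.round(bh_adjust(raw), 4), expected)

    def test_single_and_equal_pvalues(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)
        np.testing.assert_allclose(bh_adjust([0.02] * 5), 0.02)

    def test_stepup_properties(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-4, 1, 20)
        q = bh_adjust(p)
        assert np.all(q >= p)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # order preserving
        # idempotent on flat (tied) adjusted vectors
        flat = bh_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(bh_adjust(flat), flat, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCurvePermutationTest:
    def test_identical_groups_p_one(self):
        grid = np.linspace(0, 300, 31)
        g = GroupCurves(grid, np.tile(np.linspace(0, 1, 31), (5, 1)))
        h = GroupCurves(grid, np.tile(np.linspace(0, 1, 31), (7, 1)))
        assert curve_permutation_test(g, h) == 1.0

    def test_complete_separation_enumerated(self):
        """Two constant levels at n=(5,7): only the identity assignment
        attains the maximal area, so the exact p is 1/792."""
        grid = np.linspace(0, 300, 31)
        g1 = GroupCurves(grid, np.full((5, 31), 2.0))
        g2 = GroupCurves(grid, np.full((7, 31), 1.0))
        assert curve_permutation_test(g1, g2) == pytest.approx(1 / 792)

    def test_statistic_symmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        grid = np.arange(10.0)
        g1 = GroupCurves(grid, rng.uniform(size=(5, 10)))
        g2 = GroupCurves(grid, rng.uniform(size=(5, 10)))
        assert curve_permutation_test(g1, g2) == curve_permutation_test(g2, g1)

    def test_mismatched_grids_rejected(self):
        g1 = GroupCurves(np.arange(5.0), np.ones((2, 5)))
        g2 = GroupCurves(np.arange(6.0), np.ones((2, 6)))
        with pytest.raises(ValueError):
            curve_permutation_test(g1, g2)

    def test_max_statistic_variant(self):
        grid = np.arange(5.0)
        g1 = GroupCurves(grid, np.full((3, 5), 1.0))
        g2 = GroupCurves(grid, np.full((3, 5), 0.0))
        p = curve_permutation_test(g1, g2, statistic="max")
        assert 0 < p <= 2 / 20


class TestLevelValidity:
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
    def test_exact_p_is_level_valid_under_null(self, alpha):
        """Under exchangeable null draws P(p <= alpha) stays at or below
        alpha (up to enumeration granularity and binomial noise)."""
        rng = np.random.default_rng(17)
        n_draws = 400
        hits = 0
        for _ in range(n_draws):
            x = rng.normal(size=5)
            y = rng.normal(size=7)
            hits += wilcoxon_exact(x, y)[1] <= alpha
        granularity = 2 / 792
        bound = alpha + granularity + 3 * math.sqrt(alpha * (1 - alpha) / n_draws)
        assert hits / n_draws <= bound


class TestCompareGroups:
    def test_separated_cohort_reports_w35(self, room, no_maps_config):
        records = []
        for i, seed in enumerate(range(5)):
            traj, _ = hb.simulate_session(hb.td_params(), room, seed=seed)
            records.append(hb.analyze_session(traj, room, no_maps_config,
                                              group="TD").endpoints)
        for i, seed in enumerate(range(7)):
            traj, _ = hb.simulate_session(hb.ntd_params(), room, seed=100 + seed)
            records.append(hb.analyze_session(traj, room, no_maps_config,
                                              group="NTD").endpoints)
        rows = {r.endpoint: r for r in compare_groups(records)}
        assert rows["excursions_per_min"].w_statistic == 35
        assert rows["excursions_per_min"].p_value == pytest.approx(2 / 792)
        assert rows["excursions_per_min"].transform == "sqrt"
        assert rows["prop_time_near_mother"].transform == "logit"
        assert all(r.p_adjusted >= r.p_value for r in rows.values())

    def test_single_group_rejected(self, room, no_maps_config):
        traj, _ = hb.simulate_session(hb.td_params(), room, seed=0)
        rec = hb.analyze_session(traj, room, no_maps_config, group="TD").endpoints
        with pytest.raises(ValueError):
            compare_groups([rec, rec])
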