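"""Trajectory statistics against independent brute-force oracles."""

import math

import numpy as np
import pytest

from fishvr.config import ArenaConfig
from oracles import (
    fraction_oracle,
    mean_reduction_oracle,
    ray_hits_disk_oracle,
    si_oracle,
)

from fishvr.metrics import (
    PointGrid,
    average_maps,
    build_point_grid,
    cumulative_distance,
    gh_metrics,
    goal_directed,
    moving_success_rate,
    persistence_map_fraction,
    persistence_map_meanreduction,
    persistence_pvalue_map,
    quadrant_means,
    straightness_index,
    success_conversion_rate,
)


class TestStraightnessIndex:
    def test_straight_path_is_one(self):
        p = np.column_stack([np.linspace(0, 10, 7), np.linspace(0, 5, 7)])
        assert straightness_index(p) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        t = np.linspace(0, 2 * np.pi, 50)
        p = np.column_stack([np.cos(t), np.sin(t)])
        assert straightness_index(p) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_is_two_over_pi(self):
        t = np.linspace(0, np.pi, 2000)
        p = np.column_stack([np.cos(t), np.sin(t)])
        assert straightness_index(p) == pytest.approx(2 / np.pi, abs=1e-4)

    def test_single_point_is_nan(self):
        assert math.isnan(straightness_index(np.zeros((1, 2))))

    def test_stationary_is_zero(self):
        assert straightness_index(np.zeros((5, 2))) == 0.0

    def test_matches_brute_force_oracle_and_stays_in_unit_interval(self, rng):
        for _ in range(100):
            n = rng.integers(2, 13)
            p = rng.normal(scale=50, size=(n, 2))
            si = straightness_index(p)
            assert 0.0 <= si <= 1.0
            assert si == pytest.approx(si_oracle(p.tolist()), abs=1e-9)


class TestCumulativeDistance:
    def test_constant_distance_sum(self):
        p = np.tile([100.0, 0.0], (11, 1))
        assert cumulative_distance(p, (0.0, 0.0), success_index=10) == pytest.approx(1100.0)
        assert cumulative_distance(p[:10], (0.0, 0.0), success_index=9) == pytest.approx(1000.0)

    def test_parked_at_center_is_zero(self):
        p = np.tile([160.0, 160.0], (20, 1))
        assert cumulative_distance(p, (160.0, 160.0)) == 0.0

    def test_linear_approach_arithmetic_series(self):
        n = 114
        d = np.linspace(452.0, 0.0, n)
        p = np.column_stack([d, np.zeros(n)])
        assert cumulative_distance(p, (0.0, 0.0)) == pytest.approx(n * (452.0 + 0.0) / 2)


class TestSuccessConversionRate:
    def test_three_of_four_entries(self):
        s = [True, True, True, False, False]
        e = [True, True, True, True, False]
        assert success_conversion_rate(s, e) == pytest.approx(0.75)

    def test_all_entries_converted(self):
        assert success_conversion_rate([True] * 3, [True] * 3) == 1.0

    def test_no_entries_is_nan(self):
        assert math.isnan(success_conversion_rate([False] * 4, [False] * 4))

    def test_success_without_entry_rejected(self):
        with pytest.raises(ValueError):
            success_conversion_rate([True], [False])


class TestMovingSuccessRate:
    def test_last_value_counts_last_ten(self):
        s = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        assert moving_success_rate(s)[-1] == pytest.approx(0.5)

    def test_all_failures(self):
        assert np.all(moving_success_rate([False] * 25) == 0.0)

    def test_alternating_full_windows_half(self):
        s = [1, 0] * 15
        out = moving_success_rate(s)
        assert np.all(out[9:] == pytest.approx(0.5))

    def test_prefix_uses_available_trials(self):
        out = moving_success_rate([1, 1, 0, 1])
        assert out[0] == 1.0 and out[1] == 1.0
        assert out[2] == pytest.approx(2 / 3) and out[3] == pytest.approx(3 / 4)


class TestPointGrid:
    def test_spacing_ten_gives_3521_points_matching_enumeration(self):
        grid = build_point_grid(335.0, 10.0)
        brute = sum(
            1
            for i in range(-34, 35)
            for j in range(-34, 35)
            if (10 * i) ** 2 + (10 * j) ** 2 < 335**2
        )
        assert len(grid) == brute == 3521

    def test_all_points_strictly_inside(self):
        grid = build_point_grid(335.0, 17.0)
        assert np.all((grid.points**2).sum(axis=1) < 335.0**2)

    def test_zero_radius_empty(self):
        assert len(build_point_grid(0.0, 10.0)) == 0

    def test_spacing_equal_radius(self):
        grid = build_point_grid(335.0, 335.0)
        assert {tuple(p) for p in grid.points} == {(0.0, 0.0)}

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            build_point_grid(335.0, 0.0)


@pytest.fixture
def small_grid():
    return build_point_grid(100.0, 40.0)


class TestPersistenceMaps:
    def test_straight_approach_mean_reduction_equals_step(self, small_grid):
        """Walking straight toward a place at constant step d gives P = d there."""
        place = np.array([40.0, 0.0])
        p = np.column_stack([np.linspace(-80, 30, 12), np.zeros(12)])
        pmap = persistence_map_meanreduction(p, small_grid)
        i = int(np.flatnonzero((small_grid.points == place).all(axis=1))[0])
        assert pmap.values[i] == pytest.approx(10.0)

    def test_stationary_trajectory_zero_everywhere(self, small_grid):
        p = np.tile([10.0, 10.0], (30, 1))
        assert np.all(persistence_map_meanreduction(p, small_grid).values == 0.0)
        assert np.all(persistence_map_fraction(p, small_grid).values == 0.0)

    def test_mean_reduction_matches_oracle(self, rng, small_grid):
        for _ in range(100):
            n = rng.integers(2, 13)
            p = rng.uniform(-90, 90, size=(n, 2))
            pmap = persistence_map_meanreduction(p, small_grid)
            for j in rng.choice(len(small_grid), 3, replace=False):
                want = mean_reduction_oracle(p.tolist(), small_grid.points[j].tolist())
                assert pmap.values[j] == pytest.approx(want, abs=1e-9)

    def test_fraction_matches_oracle_and_range(self, rng, small_grid):
        for _ in range(100):
            n = rng.integers(2, 13)
            p = rng.uniform(-90, 90, size=(n, 2))
            pmap = persistence_map_fraction(p, small_grid)
            assert np.all(pmap.values >= -1.0) and np.all(pmap.values <= 1.0)
            for j in rng.choice(len(small_grid), 3, replace=False):
                want = fraction_oracle(p.tolist(), small_grid.points[j].tolist())
                assert pmap.values[j] == pytest.approx(want, abs=1e-9)

    def test_fraction_endpoint_values(self, small_grid):
        toward = np.column_stack([np.linspace(-80, 0, 9), np.zeros(9)])  # toward (40, 0)
        pmap = persistence_map_fraction(toward, small_grid)
        i = int(np.flatnonzero((small_grid.points == [40.0, 0.0]).all(axis=1))[0])
        assert pmap.values[i] == pytest.approx(1.0)
        away = toward[::-1]
        pmap2 = persistence_map_fraction(away, small_grid)
        assert pmap2.values[i] == pytest.approx(-1.0)

    def test_bad_random_move_prob(self, small_grid):
        with pytest.raises(ValueError):
            persistence_map_fraction(np.zeros((3, 2)), small_grid, random_move_prob=1.0)

    def test_isotropic_walk_persistence_is_rotation_symmetric(self, rng):
        """Isotropic random walks prefer no direction: the mean map value at
        places of equal radius agrees across the orbit (within sampling
        error).  Note the mean is not zero — diffusive spreading makes the
        expected distance change toward any fixed place slightly negative —
        so symmetry, not zero mean, is the correct null here."""
        grid = build_point_grid(300.0, 150.0)
        vals = []
        for _ in range(1000):
            steps = rng.normal(scale=5.0, size=(60, 2))
            p = np.cumsum(steps, axis=0)
            vals.append(persistence_map_meanreduction(p, grid).values)
        vals = np.array(vals)
        n = vals.shape[0]
        pts = grid.points
        for radius2 in (150.0**2, 2 * 150.0**2):
            orbit = np.flatnonzero(np.isclose((pts**2).sum(axis=1), radius2))
            assert orbit.size == 4
            for a in orbit:
                for b in orbit:
                    if a >= b:
                        continue
                    diff = vals[:, a] - vals[:, b]
                    se = diff.std(ddof=1) / math.sqrt(n)
                    assert abs(diff.mean()) < 4.0 * se

    def test_average_maps_is_pointwise_mean(self, rng, small_grid):
        maps = [
            persistence_map_meanreduction(rng.uniform(-90, 90, size=(8, 2)), small_grid)
            for _ in range(5)
        ]
        avg = average_maps(maps)
        brute = np.zeros(len(small_grid))
        for m in maps:
            brute += m.values
        brute /= len(maps)
        assert np.allclose(avg.values, brute)
        same = average_maps([maps[0], maps[0]])
        assert np.array_equal(same.values, maps[0].values)

    def test_map_and_negation_average_to_zero(self, small_grid):
        from fishvr.metrics import PersistenceMap

        m = persistence_map_meanreduction(np.array([[0.0, 0.0], [10.0, 5.0]]), small_grid)
        neg = PersistenceMap(small_grid, -m.values, m.method)
        assert np.allclose(average_maps([m, neg]).values, 0.0)


class TestPValueMaps:
    def test_identical_groups_max_pvalue(self, rng, small_grid):
        maps = [
            persistence_map_meanreduction(rng.uniform(-90, 90, size=(8, 2)), small_grid)
            for _ in range(4)
        ]
        p = persistence_pvalue_map(maps, maps)
        assert np.all(p > 0.99)

    def test_shifted_group_detected(self, rng, small_grid):
        from fishvr.metrics import PersistenceMap

        base = [
            persistence_map_meanreduction(rng.uniform(-90, 90, size=(10, 2)), small_grid)
            for _ in range(20)
        ]
        j = 3
        shifted = []
        for m in base:
            v = m.values.copy()
            v[j] += 10.0
            shifted.append(PersistenceMap(small_grid, v, m.method))
        p = persistence_pvalue_map(shifted, base)
        assert p[j] < 0.01

    def test_small_groups_rejected(self, small_grid):
        m = persistence_map_meanreduction(np.zeros((3, 2)), small_grid)
        with pytest.raises(ValueError):
            persistence_pvalue_map([m], [m, m])


class TestGoalHeadedness:
    def test_ray_through_center(self):
        assert goal_directed((0.0, 0.0), 45.0, (160.0, 160.0), 80.0)

    def test_opposite_heading_misses(self):
        assert not goal_directed((0.0, 0.0), 225.0, (160.0, 160.0), 80.0)

    def test_inside_zone_always_goal_directed(self, rng):
        for h in rng.uniform(0, 360, 20):
            assert goal_directed((150.0, 170.0), float(h), (160.0, 160.0), 80.0)

    def test_matches_dense_ray_sampling_oracle(self, rng):
        center, radius = (160.0, 160.0), 80.0
        checked = 0
        while checked < 100:
            p = rng.uniform(-300, 300, 2)
            h = float(rng.uniform(0, 360))
            # skip near-tangent geometries where sampling density decides
            hx = math.radians(h)
            w = np.array(center) - p
            s = w[0] * math.sin(hx) + w[1] * math.cos(hx)
            perp = math.sqrt(max((w**2).sum() - s**2, 0.0)) if s > 0 else math.inf
            if abs(perp - radius) < 1.0 or abs(s) < 1.0:
                continue
            assert goal_directed(tuple(p), h, center, radius) == ray_hits_disk_oracle(
                p, h, center, radius
            )
            checked += 1

    def test_static_moving_split_and_fractions(self):
        """Parked frames facing the zone count toward GH_static only."""
        x = np.array([0.0, 0.0, 0.0, 10.0, 20.0])
        z = np.zeros(5)
        hdg = np.array([45.0, 45.0, 45.0, 225.0, 45.0])
        res = gh_metrics(x, z, hdg, (160.0, 160.0), 80.0)
        # frames 1..4: static frames 1, 2 (facing zone); moving frames 3 (away), 4 (toward)
        assert res.n_static == 2 and res.n_move == 2
        assert res.gh_static == 1.0
        assert res.gh_move == 0.5

    def test_parked_agent_has_nan_gh_move(self):
        res = gh_metrics([5.0] * 10, [5.0] * 10, [45.0] * 10, (160.0, 160.0), 80.0)
        assert res.gh_static == 1.0 and math.isnan(res.gh_move)

    def test_straight_pass_through_zone_matches_ray_oracle(self):
        n = 40
        x = np.linspace(-300.0, 300.0, n)
        z = np.full(n, 160.0)
        hdg = np.full(n, 90.0)
        res = gh_metrics(x, z, hdg, (160.0, 160.0), 80.0)
        want = sum(
            ray_hits_disk_oracle((xi, 160.0), 90.0, (160.0, 160.0), 80.0) for xi in x[1:]
        ) / (n - 1)
        assert res.gh_move == pytest.approx(want)

    def test_rotation_invariance(self, rng):
        """GH is invariant under a global rotation of trajectory, headings
        and safe zone together."""
        n = 30
        x = rng.uniform(-200, 200, n)
        z = rng.uniform(-200, 200, n)
        hdg = rng.uniform(0, 360, n)
        center = (160.0, 160.0)
        base = gh_metrics(x, z, hdg, center, 80.0)
        theta = math.radians(73.0)  # rotate scene CCW by 73 deg (math sense)
        c, s = math.cos(theta), math.sin(theta)
        xr = c * x - s * z
        zr = s * x + c * z
        # heading is clockwise from +Z; a CCW scene rotation subtracts from it
        hr = (hdg - math.degrees(theta)) % 360.0
        cr = (c * center[0] - s * center[1], s * center[0] + c * center[1])
        rot = gh_metrics(xr, zr, hr, cr, 80.0)
        assert rot.gh_static == base.gh_static or (
            math.isnan(rot.gh_static) and math.isnan(base.gh_static)
        )
        assert rot.gh_move == pytest.approx(base.gh_move)


class TestQuadrantSummaries:
    def test_quadrant_means_partition(self, small_grid):
        from fishvr.metrics import PersistenceMap

        pmap = PersistenceMap(small_grid, np.ones(len(small_grid)), "mean_reduction")
        q = quadrant_means(pmap)
        assert all(v == pytest.approx(1.0) for v in q.values())
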