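import datetime as dt
import math

import numpy as np
import pytest

import pathvol as pv
from pathvol.ppv import (DailyPPV, build_voxel_grid, daily_ppv,
                         ellipsoid_contains, habitat_volume,
                         relative_use_summary, segment_ppv)
from pathvol.preprocess import PathSegment, group_by_fish_day, segmentize
from conftest import make_position


def brute_force_distance_sum(f1, f2, p):
    """Independent distance-sum oracle (no numpy, no shared code path)."""
    d1 = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, f1)))
    d2 = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, f2)))
    return d1 + d2


def full_scan_ppv(segment, grid, v_swim):
    """Exhaustive scan of every voxel center: the segment_ppv oracle."""
    f1 = (segment.p1.x, segment.p1.y, segment.p1.depth)
    f2 = (segment.p2.x, segment.p2.y, segment.p2.depth)
    v_obs = segment.v_obs
    v = pv.adjust_vswim(v_obs, v_swim) if v_obs >= v_swim else v_swim
    budget = v * segment.dt
    cx, cy, cz = grid.axis_centers_real()
    out = []
    nx, ny, nz = grid.dims
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not grid.lake_mask[ix, iy, iz]:
                    continue
                p = (cx[ix], cy[iy], cz[iz])
                if brute_force_distance_sum(f1, f2, p) <= budget:
                    out.append(np.ravel_multi_index((ix, iy, iz), grid.dims))
    return np.array(sorted(out), dtype=np.int64)


class TestVoxelGrid:
    def test_flat_lake_grid_matches_lake_exactly(self, flat_lake, flat_grid):
        assert flat_grid.dims == (5, 5, 50)
        assert flat_grid.voxel_volume == pytest.approx(80.0)
        assert flat_grid.masked_volume == pytest.approx(flat_lake.lake_volume)

    def test_voxel_z_is_length_over_rescale(self, flat_grid):
        assert flat_grid.voxel_z == pytest.approx(
            flat_grid.voxel_length / flat_grid.rescale)

    def test_rejects_bad_parameters(self, flat_lake):
        with pytest.raises(ValueError):
            build_voxel_grid(flat_lake, voxel_length=-1)
        with pytest.raises(ValueError):
            build_voxel_grid(flat_lake, rescale=0.5)


class TestEllipsoidContains:
    def test_midpoint_always_inside(self):
        assert ellipsoid_contains((0, 0, 0), (10, 0, 0), v=1.0, dt=20.0,
                                  p=(5, 0, 0))

    def test_boundary_inclusive(self):
        # point on the major axis where the distance sum equals v*dt exactly
        f1, f2 = (0.0, 0.0, 0.0), (10.0, 0.0, 0.0)
        p = (15.0, 0.0, 0.0)  # |p-f1| + |p-f2| = 15 + 5 = 20 = v*dt
        assert ellipsoid_contains(f1, f2, v=1.0, dt=20.0, p=p)

    def test_degenerate_contract_violation_raises(self):
        with pytest.raises(ValueError, match="adjust_vswim"):
            ellipsoid_contains((0, 0, 0), (30, 0, 0), v=1.0, dt=20.0,
                               p=(5, 0, 0))

    def test_matches_independent_oracle_on_random_tuples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            f1 = rng.uniform(-10, 10, 3)
            sep = rng.uniform(0, 5)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            f2 = f1 + sep * direction
            v = rng.uniform(0.5, 2.0)
            budget_dt = sep / v + rng.uniform(0.1, 10.0)
            p = rng.uniform(-15, 15, 3)
            expected = brute_force_distance_sum(f1, f2, p) <= v * budget_dt
            assert ellipsoid_contains(f1, f2, v, budget_dt, p) == expected


class TestSegmentPPV:
    def _grid(self, flat_lake):
        # 10 x 10 x 100 = 10^4 voxels, 10 m voxels, 0.1 m vertical
        return build_voxel_grid(flat_lake, voxel_length=10.0, rescale=100.0)

    def test_equals_exhaustive_scan_random_segments(self, flat_lake):
        grid = self._grid(flat_lake)
        rng = np.random.default_rng(11)
        for _ in range(20):
            p1 = make_position(t=0.0, x=rng.uniform(10, 90),
                               y=rng.uniform(10, 90),
                               depth=rng.uniform(0.5, 9.5))
            p2 = make_position(t=rng.uniform(100, 600),
                               x=np.clip(p1.x + rng.normal(0, 10), 5, 95),
                               y=np.clip(p1.y + rng.normal(0, 10), 5, 95),
                               depth=np.clip(p1.depth + rng.normal(0, 1),
                                             0.2, 9.8))
            (seg,) = segmentize([p1, p2], max_gap=1e9)
            v_swim = rng.uniform(0.01, 0.1)
            fast = np.sort(segment_ppv(seg, grid, v_swim))
            slow = full_scan_ppv(seg, grid, v_swim)
            np.testing.assert_array_equal(fast, slow)

    def test_stationary_fish_gives_sphere(self, flat_lake):
        grid = self._grid(flat_lake)
        p1 = make_position(t=0.0, x=50, y=50, depth=5.0)
        p2 = make_position(t=300.0, x=50, y=50, depth=5.0)
        seg = PathSegment("f1", p1, p2, dt=300.0, v_obs=0.0)
        v, dtn = 0.05, 300.0
        got = set(segment_ppv(seg, grid, v).tolist())
        cx, cy, cz = grid.axis_centers_real()
        expected = set()
        for ix in range(grid.dims[0]):
            for iy in range(grid.dims[1]):
                for iz in range(grid.dims[2]):
                    if not grid.lake_mask[ix, iy, iz]:
                        continue
                    r = math.dist((cx[ix], cy[iy], cz[iz]), (50, 50, 5.0))
                    if r <= v * dtn / 2:
                        expected.add(int(np.ravel_multi_index(
                            (ix, iy, iz), grid.dims)))
        assert got == expected and got

    def test_fast_segment_nonempty(self, flat_lake):
        # v_obs >= v_swim: adjusted speed exceeds v_obs, PPV must be non-empty
        grid = self._grid(flat_lake)
        p1 = make_position(t=0.0, x=30, y=50, depth=5.0)
        p2 = make_position(t=300.0, x=60, y=50, depth=5.0)
        (seg,) = segmentize([p1, p2], max_gap=1e9)
        assert seg.v_obs == pytest.approx(0.1)
        assert len(segment_ppv(seg, grid, v_swim=0.05)) > 0


class TestDailyPPV:
    def _segment(self, flat_grid):
        p1 = make_position(t=0.0, x=40, y=50, depth=5.0)
        p2 = make_position(t=300.0, x=60, y=50, depth=5.0)
        (seg,) = segmentize([p1, p2], max_gap=1e9)
        return seg

    def test_single_segment_counts_binary(self, flat_grid):
        seg = self._segment(flat_grid)
        day = daily_ppv([seg], flat_grid, v_swim=0.1)
        assert set(day.counts.tolist()) == {1}
        assert habitat_volume(day, flat_grid) == pytest.approx(
            len(segment_ppv(seg, flat_grid, 0.1)) * flat_grid.voxel_volume)

    def test_repeated_segment_doubles_counts_not_volume(self, flat_grid):
        seg = self._segment(flat_grid)
        one = daily_ppv([seg], flat_grid, v_swim=0.1)
        two = daily_ppv([seg, seg], flat_grid, v_swim=0.1)
        assert set(two.counts.tolist()) == {2}
        assert habitat_volume(two, flat_grid) == pytest.approx(
            habitat_volume(one, flat_grid))

    def test_disjoint_segments_add_volumes(self, flat_grid):
        p1 = make_position(t=0.0, x=20, y=20, depth=2.0)
        p2 = make_position(t=100.0, x=22, y=20, depth=2.0)
        p3 = make_position(t=0.0, x=80, y=80, depth=8.0)
        p4 = make_position(t=100.0, x=82, y=80, depth=8.0)
        (s1,) = segmentize([p1, p2], max_gap=1e9)
        (s2,) = segmentize([p3, p4], max_gap=1e9)
        v1 = habitat_volume(daily_ppv([s1], flat_grid, 0.05), flat_grid)
        v2 = habitat_volume(daily_ppv([s2], flat_grid, 0.05), flat_grid)
        both = habitat_volume(daily_ppv([s1, s2], flat_grid, 0.05), flat_grid)
        assert both == pytest.approx(v1 + v2)

    def test_empty_segment_list_gives_no_record(self, flat_grid):
        assert daily_ppv([], flat_grid, 0.05) is None

    def test_counts_bounded_by_n_segments(self, scenario):
        grid = build_voxel_grid(scenario.lake)
        by_day = group_by_fish_day(scenario.positions)
        key = next(iter(by_day))
        segs = segmentize(by_day[key])
        day = daily_ppv(segs, grid, v_swim=0.03)
        assert day.counts.max() <= day.n_segments
        assert np.all(grid.lake_mask.ravel()[day.voxels])


class TestHabitatVolume:
    def _manual(self, counts, dims=(3, 1, 1)):
        counts = np.asarray(counts, dtype=np.int64)
        return DailyPPV("f1", dt.date(2022, 6, 1),
                        voxels=np.arange(len(counts), dtype=np.int64),
                        counts=counts, n_segments=int(counts.max()),
                        v_swim_used=0.03, dims=dims)

    def test_threshold_counts_qualifying_voxels(self, flat_grid):
        day = self._manual([1, 1, 2], dims=flat_grid.dims)
        assert habitat_volume(day, flat_grid, threshold=1) == pytest.approx(240.0)
        assert habitat_volume(day, flat_grid, threshold=2) == pytest.approx(80.0)

    def test_threshold_below_one_is_error(self, flat_grid):
        day = self._manual([1], dims=flat_grid.dims)
        with pytest.raises(ValueError):
            habitat_volume(day, flat_grid, threshold=0)

    def test_volume_matches_binary_union(self, flat_grid):
        day = self._manual([3, 1, 2], dims=flat_grid.dims)
        binary = len(np.unique(day.voxels))
        assert habitat_volume(day, flat_grid, 1) == pytest.approx(
            binary * flat_grid.voxel_volume)


class TestRelativeUse:
    def test_fractions(self, flat_grid):
        day = DailyPPV("f1", dt.date(2022, 6, 1),
                       voxels=np.array([0, 1], dtype=np.int64),
                       counts=np.array([5, 1], dtype=np.int64),
                       n_segments=10, v_swim_used=0.03, dims=flat_grid.dims)
        s = relative_use_summary(day, flat_grid, denominator="lake")
        n_lake = flat_grid.n_lake_voxels
        assert s.fraction_zero == pytest.approx(1 - 2 / n_lake)
        assert s.fraction_ge5 == pytest.approx(1 / n_lake)
        assert s.max_segment_fraction == pytest.approx(0.5)

    def test_single_segment_max_fraction_is_one(self, flat_grid):
        day = DailyPPV("f1", dt.date(2022, 6, 1),
                       voxels=np.array([0], dtype=np.int64),
                       counts=np.array([1], dtype=np.int64),
                       n_segments=1, v_swim_used=0.03, dims=flat_grid.dims)
        s = relative_use_summary(day, flat_grid)
        assert s.max_segment_fraction == 1.0

    def test_footprint_denominator_smaller_than_lake(self, flat_grid):
        day = DailyPPV("f1", dt.date(2022, 6, 1),
                       voxels=np.array([0, 51], dtype=np.int64),
                       counts=np.array([1, 1], dtype=np.int64),
                       n_segments=2, v_swim_used=0.03, dims=flat_grid.dims)
        foot = relative_use_summary(day, flat_grid, denominator="footprint")
        lake = relative_use_summary(day, flat_grid, denominator="lake")
        assert foot.n_denominator_voxels <= lake.n_denominator_voxels
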