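"""CoG, plane projection, spline area, overlap and ratio metrics."""

import numpy as np
import pytest

from mapkit.mapping import (AreaResult, EmptyMapError, MotorMap, compute_cog,
                            hand_arm_analysis, interpolate_area,
                            maps_from_session, overlap_percent,
                            project_to_plane, ratio_metrics)
from mapkit.synthetic import GroupSpec, generate_cohort


def simple_map(points, amps):
    return MotorMap("s", "L", "APB", np.asarray(points, float),
                    np.asarray(amps, float))


class TestCoG:
    def test_equal_weights_midpoint(self):
        cog = compute_cog(simple_map([(0, 0, 0), (10, 0, 0)], [100, 100]))
        np.testing.assert_allclose(cog.coordinate, [5, 0, 0])

    def test_weighted_mean(self):
        cog = compute_cog(simple_map([(0, 0, 0), (10, 0, 0)], [100, 300]))
        np.testing.assert_allclose(cog.coordinate, [7.5, 0, 0])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            pts = rng.uniform(-30, 30, size=(20, 3))
            amps = rng.uniform(0, 500, size=20)
            m = simple_map(pts, amps)
            keep = amps >= 50
            if not keep.any():
                continue
            oracle = np.zeros(3)
            tot = 0.0
            for p, a in zip(pts[keep], amps[keep]):
                oracle += a * p
                tot += a
            oracle /= tot
            np.testing.assert_allclose(compute_cog(m).coordinate, oracle,
                                       atol=1e-9)

    def test_sub_criterion_sites_excluded(self):
        cog = compute_cog(simple_map([(0, 0, 0), (10, 0, 0)], [100, 49.9]))
        np.testing.assert_allclose(cog.coordinate, [0, 0, 0])

    def test_empty_map_error(self):
        with pytest.raises(EmptyMapError):
            compute_cog(simple_map([(0, 0, 0)], [10.0]))

    def test_unweighted_mode_is_centroid(self):
        cog = compute_cog(simple_map([(0, 0, 0), (10, 0, 0)], [100, 300]),
                          weighted=False)
        np.testing.assert_allclose(cog.coordinate, [5, 0, 0])


class TestPlaneProjection:
    def test_coplanar_zero_residual_and_exact_backprojection(self, rng):
        basis = np.linalg.qr(rng.standard_normal((3, 3)))[0][:, :2].T
        origin = np.array([5.0, -3.0, 10.0])
        uv = rng.uniform(-20, 20, size=(12, 2))
        pts = origin + uv @ basis
        frame, xy = project_to_plane(pts)
        assert frame.residual_rms < 1e-9
        back = frame.origin + xy @ frame.basis
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_in_plane_distances_preserved(self, rng):
        pts = rng.uniform(-20, 20, size=(10, 3))
        pts[:, 2] = 0.0
        _, xy = project_to_plane(pts)
        d3 = np.linalg.norm(pts[0] - pts[1])
        d2 = np.linalg.norm(xy[0] - xy[1])
        assert d2 == pytest.approx(d3, rel=1e-9)

    def test_collinear_cloud_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            project_to_plane(pts)


class TestInterpolatedArea:
    def test_disc_area_recovered(self, disc_map):
        res = interpolate_area(disc_map(5.0))
        assert res.area == pytest.approx(4.0, rel=0.10)
        res = interpolate_area(disc_map(2.5))
        assert res.area == pytest.approx(4.0, rel=0.03)

    def test_all_subthreshold_zero_area(self):
        pts = np.column_stack([np.arange(9) % 3 * 5.0, np.arange(9) // 3 * 5.0,
                               np.zeros(9)])
        res = interpolate_area(MotorMap("s", "L", "APB", pts, np.full(9, 30.0)))
        assert res.fallback and res.area == 0.0

    def test_area_scales_quadratically_with_coordinates(self, disc_map):
        m = disc_map(5.0)
        doubled = MotorMap(m.subject_id, m.hemisphere, m.muscle_set,
                           m.points * 2.0, m.amplitudes)
        a1 = interpolate_area(m).area
        a2 = interpolate_area(doubled).area
        assert a2 / a1 == pytest.approx(4.0, rel=0.05)

    def test_fallback_counts_accepted_sites(self):
        pts = np.array([(0, 0, 0), (5, 0, 0), (0, 5, 0)], float)
        res = interpolate_area(MotorMap("s", "L", "APB", pts,
                                        np.array([100.0, 100.0, 40.0])))
        assert res.fallback
        assert res.area == pytest.approx(2 * 25.0 / 100.0)

    def test_area_bounded_by_padded_bounding_box(self, disc_map):
        res = interpolate_area(disc_map(5.0))
        span_x = res.grid_x[-1] - res.grid_x[0]
        span_y = res.grid_y[-1] - res.grid_y[0]
        assert res.area <= span_x * span_y / 100.0


def square_mask(x0, x1, grid):
    gx, gy = grid
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    return (xx >= x0) & (xx < x1) & (yy >= 0) & (yy < 10)


def area_result(mask, gx, gy):
    return AreaResult(area=float(mask.sum()) * 0.25 / 100, mask=mask,
                      grid_x=gx, grid_y=gy, resolution=0.5, plane=None)


class TestOverlap:
    gx = np.arange(-10, 25, 0.5)
    gy = np.arange(-5, 15, 0.5)

    def make(self, x0, x1):
        return area_result(square_mask(x0, x1, (self.gx, self.gy)),
                           self.gx, self.gy)

    def test_identical_masks_full_overlap(self):
        a = self.make(0, 10)
        assert overlap_percent(a, a) == pytest.approx(100.0)

    def test_disjoint_masks_zero(self):
        assert overlap_percent(self.make(0, 10), self.make(12, 22)) == 0.0

    def test_half_shifted_squares_third(self):
        assert overlap_percent(self.make(0, 10), self.make(5, 15)) == \
            pytest.approx(100.0 / 3.0, rel=1e-6)

    def test_symmetry(self):
        a, b = self.make(0, 10), self.make(5, 15)
        assert overlap_percent(a, b) == pytest.approx(overlap_percent(b, a))

    def test_empty_union_is_error(self):
        empty = area_result(np.zeros((self.gx.size, self.gy.size), bool),
                            self.gx, self.gy)
        with pytest.raises(ValueError, match="empty union"):
            overlap_percent(empty, empty)


class TestRatios:
    def test_equal_areas_unit_ratios(self):
        areas = {(h, s): 5.0 for h in "LR" for s in ("hand", "arm")}
        r = ratio_metrics(areas)
        assert all(v == 1.0 for v in r.hand_arm.values())
        assert all(v == 1.0 for v in r.left_right.values())

    def test_hand_double_arm(self):
        areas = {("L", "hand"): 8.0, ("L", "arm"): 4.0,
                 ("R", "hand"): 8.0, ("R", "arm"): 4.0}
        assert ratio_metrics(areas).hand_arm["L"] == 2.0

    def test_zero_denominator_flagged_nan(self):
        areas = {("L", "hand"): 8.0, ("L", "arm"): 0.0,
                 ("R", "hand"): 8.0, ("R", "arm"): 4.0}
        r = ratio_metrics(areas)
        assert np.isnan(r.hand_arm["L"]) and r.flags


class TestParameterRecovery:
    def test_noise_free_cog_near_field_centre(self):
        flags = {k: False for k in ("arm_area_left", "overlap_left",
                                    "sp_right_shorter", "active_latency_left",
                                    "cog_scatter_left")}
        gspec = GroupSpec(n_per_group=2, asymmetry_flags=flags,
                          mep_noise_sigma=0.0, master_seed=5)
        cohort = generate_cohort(gspec, components=("session",))
        data = cohort[0]
        maps = maps_from_session(data.session, "L")
        for f in data.spec.fields["L"]:
            try:
                cog = compute_cog(maps[f.muscle_name]).coordinate
            except EmptyMapError:
                continue
            # amplitude-weighted centre lands near the generating field centre
            assert np.linalg.norm(cog - f.center) < 2.5
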