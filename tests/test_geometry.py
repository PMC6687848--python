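"""Polygon measures, line fits, circle fits, knee axis and moment arm."""

import numpy as np
import pytest
from scipy.optimize import minimize

from tendonkit import geometry as geo
from tendonkit import synthetic as syn


class TestPolygonAreaCentroid:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        area, c = geo.polygon_area_centroid(sq)
        assert area == pytest.approx(1.0)
        assert np.allclose(c, [0.5, 0.5])

    def test_orientation_invariance(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        area1, c1 = geo.polygon_area_centroid(sq)
        area2, c2 = geo.polygon_area_centroid(sq[::-1])
        assert area1 == area2 and np.allclose(c1, c2)

    def test_64gon_approximates_circle(self):
        """A 64-gon of radius 6.128 mm has area 118 mm^2 within 0.2 %."""
        r = 6.128
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        poly = r * np.column_stack([np.cos(theta), np.sin(theta)])
        area, _ = geo.polygon_area_centroid(poly)
        assert area == pytest.approx(np.pi * r ** 2, rel=2e-3)
        assert area == pytest.approx(118.0, rel=2e-3)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            geo.polygon_area_centroid(np.array([[0, 0], [1, 1], [2, 2]]))


class TestLineOfAction:
    def test_collinear_centroids_exact(self):
        stack, truth = syn.gen_csa_stack(100.0, 20.0, n_slices=6, seed=0)
        line = geo.fit_line_of_action(stack)
        cosang = abs(line.direction @ truth["axis"].direction)
        assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_direction_sign_proximal_to_distal(self):
        stack, truth = syn.gen_csa_stack(100.0, 10.0, n_slices=5, seed=0)
        line = geo.fit_line_of_action(stack)
        assert line.direction @ truth["axis"].direction > 0

    def test_noisy_centroids_within_half_degree(self):
        errs = []
        for seed in range(100):
            stack, truth = syn.gen_csa_stack(118.0, 10.0, n_slices=18,
                                             contour_noise_mm=0.1, seed=seed)
            line = geo.fit_line_of_action(stack)
            cosang = np.clip(abs(line.direction @ truth["axis"].direction), 0, 1)
            errs.append(np.degrees(np.arccos(cosang)))
        assert max(errs) < 0.5

    def test_single_slice_rejected(self):
        stack, _ = syn.gen_csa_stack(100.0, 0.0, n_slices=3, seed=0)
        with pytest.raises(ValueError):
            geo.fit_line_of_action(geo.SegmentationStack(slices=stack.slices[:1]))


class TestReorientCSA:
    def test_aligned_identity(self):
        stack, _ = syn.gen_csa_stack(118.0, 0.0, n_slices=4, seed=0)
        line = geo.fit_line_of_action(stack)
        for s in stack.slices:
            assert geo.reorient_csa(s, line) == pytest.approx(s.area_mm2())

    def test_60deg_halves_area(self):
        stack, _ = syn.gen_csa_stack(50.0, 60.0, n_slices=4, seed=0)
        line = geo.fit_line_of_action(stack)
        for s in stack.slices:
            assert geo.reorient_csa(s, line) == pytest.approx(0.5 * s.area_mm2(), rel=1e-9)

    def test_tilted_cylinder_recovers_true_area(self):
        stack, truth = syn.gen_csa_stack(118.0, 10.0, n_slices=18, seed=0)
        line = geo.fit_line_of_action(stack)
        for s in stack.slices:
            assert geo.reorient_csa(s, line) == pytest.approx(118.0, rel=5e-3)

    def test_never_exceeds_inplane_area(self):
        stack, _ = syn.gen_csa_stack(80.0, 35.0, n_slices=6, contour_noise_mm=0.2, seed=1)
        line = geo.fit_line_of_action(stack)
        for s in stack.slices:
            assert geo.reorient_csa(s, line) <= s.area_mm2() + 1e-12


class TestRegionalCSA:
    def test_uniform_cylinder_all_regions_equal(self):
        stack, _ = syn.gen_csa_stack(118.0, 5.0, n_slices=18, seed=0)
        line = geo.fit_line_of_action(stack)
        vals = [geo.regional_csa(stack, line, r) for r in ("proximal40", "distal40", "full")]
        assert vals[0] == pytest.approx(vals[1], rel=1e-9)
        assert vals[0] == pytest.approx(vals[2], rel=1e-9)

    def test_tapering_stack_ordering_matches_integral(self):
        """Linear radius taper: region means match the closed-form area integral."""
        n, spacing = 41, 1.0
        r0, r1 = 8.0, 4.0
        slices = []
        ex, ey = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        for k in range(n):
            r = r0 + (r1 - r0) * k / (n - 1)
            poly = r * np.column_stack([np.cos(theta), np.sin(theta)])
            slices.append(geo.Slice(polygon=poly, origin_mm=[0, 0, k * spacing],
                                    normal=[0, 0, 1], in_plane_basis=[ex, ey]))
        stack = geo.SegmentationStack(slices=slices)
        line = geo.fit_line_of_action(stack)
        prox = geo.regional_csa(stack, line, "proximal40")
        full = geo.regional_csa(stack, line, "full")
        dist = geo.regional_csa(stack, line, "distal40")
        assert prox > full > dist
        # mean of pi r(t)^2 over t in [0, 0.4]: discretization-level agreement
        ts = np.linspace(0, 1, 100001)
        rr = r0 + (r1 - r0) * ts

        def band_mean(sel):
            return np.pi * np.mean(rr[sel] ** 2)

        assert prox == pytest.approx(band_mean(ts <= 0.4), rel=2e-2)
        assert dist == pytest.approx(band_mean(ts >= 0.6), rel=2e-2)
        assert full == pytest.approx(band_mean(slice(None)), rel=2e-2)

    def test_plateau_regional_means(self):
        """Proximal 118 / distal 119 mm^2 plateaus reproduce Table-1-scale values."""
        slices = []
        ex, ey = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        for k in range(10):
            area = 118.0 if k < 5 else 119.0
            r = np.sqrt(area / np.pi)
            poly = r * np.column_stack([np.cos(theta), np.sin(theta)])
            slices.append(geo.Slice(polygon=poly, origin_mm=[0, 0, 3.0 * k],
                                    normal=[0, 0, 1], in_plane_basis=[ex, ey]))
        stack = geo.SegmentationStack(slices=slices)
        line = geo.fit_line_of_action(stack)
        assert geo.regional_csa(stack, line, "proximal40") == pytest.approx(118.0, rel=1e-3)
        assert geo.regional_csa(stack, line, "distal40") == pytest.approx(119.0, rel=1e-3)


class TestCircleFit:
    def test_exact_points_recovered(self):
        pts, _ = syn.gen_condyle_contours((3.0, -2.0), 21.0, 360.0, 12, 0.0)
        fit = geo.fit_circle(pts)
        assert np.allclose(fit.center_mm, [3.0, -2.0], atol=1e-9)
        assert fit.radius_mm == pytest.approx(21.0, abs=1e-9)
        assert not fit.condition_flag

    def test_three_points_circumcircle(self):
        """Three points: the fit equals the closed-form circumcircle."""
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 6.0]])
        fit = geo.fit_circle(pts)
        # circumcenter of a right triangle is the hypotenuse midpoint
        assert np.allclose(fit.center_mm, [2.0, 3.0], atol=1e-8)
        assert fit.radius_mm == pytest.approx(np.hypot(2.0, 3.0), abs=1e-8)

    def test_noisy_half_arc_center_error(self):
        errs = []
        for seed in range(100):
            pts, truth = syn.gen_condyle_contours((10.0, 5.0), 20.0, 180.0, 40,
                                                  0.05, seed=seed)
            fit = geo.fit_circle(pts)
            errs.append(np.linalg.norm(fit.center_mm - truth["center_mm"]))
        assert np.mean(errs) < 0.05

    def test_short_arc_sets_condition_flag(self):
        pts, _ = syn.gen_condyle_contours((0.0, 0.0), 20.0, 10.0, 3, 0.0)
        assert geo.fit_circle(pts).condition_flag

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            geo.fit_circle(np.column_stack([np.arange(5.0), 2 * np.arange(5.0)]))


class TestKneeAxisAndMomentArm:
    @staticmethod
    def _axis_from_synthetic(seed=0, noise=0.0):
        basis = np.array([[1.0, 0, 0], [0, 0, 1.0]])  # sagittal planes
        med_pts, med_truth = syn.gen_condyle_contours((10.0, 30.0), 21.0, 150.0,
                                                      30, noise, seed=seed)
        lat_pts, lat_truth = syn.gen_condyle_contours((10.0, 30.0), 20.0, 150.0,
                                                      30, noise, seed=seed + 1)
        med_place = geo.PlanePlacement(origin_mm=[0, -40.0, 0], basis=basis)
        lat_place = geo.PlanePlacement(origin_mm=[0, 40.0, 0], basis=basis)
        axis = geo.knee_axis(geo.fit_circle(med_pts), med_place,
                             geo.fit_circle(lat_pts), lat_place)
        return axis, med_place.to_3d(med_truth["center_mm"]), lat_place.to_3d(
            lat_truth["center_mm"])

    def test_axis_through_known_centers(self):
        axis, p_med, p_lat = self._axis_from_synthetic()
        d_true = (p_lat - p_med) / np.linalg.norm(p_lat - p_med)
        assert abs(abs(axis.direction @ d_true) - 1.0) < 1e-9
        assert np.linalg.norm(np.cross(axis.point_mm - p_med, d_true)) < 1e-6

    def test_swapping_condyles_keeps_moment_arm(self):
        axis, p_med, p_lat = self._axis_from_synthetic()
        line = geo.LineOfAction(point_mm=[0, 0, 100.0], direction=[0.1, 0, 1.0])
        swapped = geo.LineOfAction(point_mm=p_lat, direction=p_med - p_lat)
        assert geo.moment_arm(line, axis).value_mm == pytest.approx(
            geo.moment_arm(line, swapped).value_mm, abs=1e-9)

    def test_textbook_skew_lines(self):
        """Orthogonal skew lines 54.1 mm apart give a 54.1 mm moment arm."""
        l1 = geo.LineOfAction(point_mm=[0, 0, 0], direction=[1, 0, 0])
        l2 = geo.LineOfAction(point_mm=[0, 0, 54.1], direction=[0, 1, 0])
        assert geo.moment_arm(l1, l2).value_mm == pytest.approx(54.1)

    def test_intersecting_lines_zero_with_warning(self):
        l1 = geo.LineOfAction(point_mm=[0, 0, 0], direction=[1, 0, 0])
        l2 = geo.LineOfAction(point_mm=[0, 0, 0], direction=[0, 1, 0])
        with pytest.warns(UserWarning):
            assert geo.moment_arm(l1, l2).value_mm == 0.0

    def test_parallel_lines_point_distance(self):
        l1 = geo.LineOfAction(point_mm=[0, 0, 0], direction=[1, 0, 0])
        l2 = geo.LineOfAction(point_mm=[5.0, 3.0, 4.0], direction=[1, 0, 0])
        assert geo.moment_arm(l1, l2).value_mm == pytest.approx(5.0)

    def test_formula_matches_numerical_minimization(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            l1 = geo.LineOfAction(rng.normal(size=3) * 10, rng.normal(size=3))
            l2 = geo.LineOfAction(rng.normal(size=3) * 10, rng.normal(size=3))
            got = geo.moment_arm(l1, l2).value_mm

            def sqdist(ts):
                p = l1.point_mm + ts[0] * l1.direction
                q = l2.point_mm + ts[1] * l2.direction
                return np.sum((p - q) ** 2)

            res = minimize(sqdist, [0.0, 0.0], method="Nelder-Mead",
                           options={"xatol": 1e-13, "fatol": 1e-18, "maxiter": 20000})
            assert abs(got - np.sqrt(res.fun)) <= 1e-8

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        l1 = geo.LineOfAction(rng.normal(size=3) * 10, rng.normal(size=3))
        l2 = geo.LineOfAction(rng.normal(size=3) * 10, rng.normal(size=3))
        base = geo.moment_arm(l1, l2).value_mm
        for _ in range(100):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            t = rng.normal(size=3) * 50
            m1 = geo.LineOfAction(q @ l1.point_mm + t, q @ l1.direction)
            m2 = geo.LineOfAction(q @ l2.point_mm + t, q @ l2.direction)
            assert abs(geo.moment_arm(m1, m2).value_mm - base) <= 1e-9
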