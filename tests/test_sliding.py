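"""Sliding-scan signals, pulse detection, ray segmentation, reconstruction."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

import palpsim as ps
from palpsim.phantom import (CIRCLE_RADIUS, HS_R_IN, HS_R_OUT, PhantomSpec,
                             Shape)
from palpsim.sliding import (DEFAULT_STEP_MM, detect_events, reconstruct,
                             segment, simulate_ray)

PRINTED_PAIRS = [  # (|area error| mm^2, printed precision, true area)
    (1.99, 0.842, 12.57), (0.08, 0.994, 12.57),
    (2.25, 0.712, 7.79), (0.20, 0.974, 7.79),
    (3.14, 0.602, 7.88), (0.19, 0.976, 7.88),
]


def ray_crossings_oracle(stiff_map, origin, angle, resolution=1e-4):
    """Independent geometric oracle: dense membership sampling along the ray."""
    from palpsim.sliding import _arc_to_boundary
    s_max = _arc_to_boundary(stiff_map, origin, angle)
    s = np.arange(0.0, s_max, resolution)
    m = stiff_map.membership(origin[0] + s * np.cos(angle),
                             origin[1] + s * np.sin(angle))
    idx = np.nonzero(np.diff(m) != 0)[0]
    return [(0.5 * (s[k] + s[k + 1]), int(m[k + 1] - m[k])) for k in idx]


def raster_area(contour, inner=None, pitch=0.01):
    """Rasterized area oracle: count 0.01-mm cells inside the contour."""
    allpts = contour if inner is None else np.vstack([contour, inner])
    x0, y0 = allpts.min(axis=0) - 0.1
    x1, y1 = allpts.max(axis=0) + 0.1
    xs = np.arange(x0, x1, pitch)
    ys = np.arange(y0, y1, pitch)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(contour).contains_points(pts)
    if inner is not None:
        inside &= ~MplPath(inner).contains_points(pts)
    return inside.sum() * pitch * pitch


class TestSimulateRay:
    def test_homogeneous_soft_map_is_flat(self):
        spec = PhantomSpec(shape=Shape.CIRCLE, inclusion_area=0.5,
                           inclusion_center=(5.0, 5.0))
        m = ps.make_phantom(spec)
        sig = simulate_ray(m, (8.0, 8.0), angle=np.pi / 3)  # misses inclusion
        assert np.ptp(sig.intensity) < 1e-9
        assert detect_events(sig) == []

    def test_center_ray_single_exit_at_radius(self, circle):
        sig = simulate_ray(circle, (5.0, 5.0), angle=0.7)
        events = detect_events(sig)
        assert len(events) == 1
        assert events[0].polarity == +1
        assert abs(events[0].s - CIRCLE_RADIUS) <= 2 * DEFAULT_STEP_MM

    def test_diametric_ray_polarities_entry_then_exit(self, circle):
        sig = simulate_ray(circle, (5.0, 0.5), angle=np.pi / 2)
        events = detect_events(sig)
        assert [e.polarity for e in events] == [-1, +1]
        assert events[0].s == pytest.approx(4.5 - 2.0, abs=2 * DEFAULT_STEP_MM)
        assert events[1].s == pytest.approx(4.5 + 2.0, abs=2 * DEFAULT_STEP_MM)

    def test_notch_ray_sees_entry_and_exit(self, phantoms):
        m = phantoms["horseshoe"]
        sig = simulate_ray(m, m.true_centroid, angle=np.pi)  # into material
        events = detect_events(sig)
        assert len(events) >= 2
        assert events[0].polarity == -1

    def test_origin_outside_workspace_rejected(self, circle):
        with pytest.raises(ValueError):
            simulate_ray(circle, (12.0, 5.0), angle=0.0)

    @pytest.mark.parametrize("shape", ["circle", "rectangle", "horseshoe"])
    def test_event_positions_match_geometric_oracle(self, phantoms, shape):
        m = phantoms[shape]
        origin = m.true_centroid
        for k in range(16):
            theta = 2 * np.pi * k / 16
            expected = ray_crossings_oracle(m, origin, theta)
            got = detect_events(simulate_ray(m, origin, theta))
            assert len(got) == len(expected)
            for ev, (s_true, dm) in zip(got, expected):
                assert abs(ev.s - s_true) <= 2 * DEFAULT_STEP_MM
                assert ev.polarity == (-1 if dm > 0 else +1)

    def test_noise_reproducible(self, circle):
        a = simulate_ray(circle, (5.0, 5.0), 0.3, noise_sd=5.0, rng=11)
        b = simulate_ray(circle, (5.0, 5.0), 0.3, noise_sd=5.0, rng=11)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestSegment:
    def test_circle_four_rays_symmetric(self, circle):
        bps = segment(circle, (5.0, 5.0), n_rays=4)
        assert len(bps.outer_points) == 4
        for theta, p in bps.outer_points:
            assert np.hypot(p[0] - 5, p[1] - 5) == pytest.approx(
                CIRCLE_RADIUS, abs=2 * DEFAULT_STEP_MM)

    def test_circle_sixteen_rays_on_radius(self, circle):
        bps = segment(circle, (5.0, 5.0), n_rays=16)
        assert len(bps.outer_points) == 16
        radii = [np.hypot(p[0] - 5, p[1] - 5) for _, p in bps.outer_points]
        np.testing.assert_allclose(radii, CIRCLE_RADIUS,
                                   atol=2 * DEFAULT_STEP_MM)

    def test_square_rays_through_corners_recover_polygon(self):
        # bespoke square phantom: 45-deg rays hit the four corners
        side = 2.0
        spec = PhantomSpec(shape=Shape.RECTANGLE, inclusion_area=side * side,
                           inclusion_center=(5.0, 5.0))
        sq = ps.make_phantom(spec)
        assert sq._rect_sides() != (side, side)  # fixture aspect, same area
        # use the aspect-correct corners instead: compute via membership
        w, h = sq._rect_sides()
        corner_angles = [np.arctan2(sy * h / 2, sx * w / 2)
                         for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1))]
        pts = []
        for th in corner_angles:
            bps = segment(sq, (5.0, 5.0), n_rays=1, phase=th)
            pts.append(bps.outer_points[0][1])
        pts = np.array(pts)
        expected = side * side * 1.0  # rectangle area via shoelace on corners
        from shapely.geometry import Polygon
        assert Polygon(pts).area == pytest.approx(w * h, abs=0.1)

    def test_horseshoe_builds_inner_and_outer_rings(self, phantoms):
        m = phantoms["horseshoe"]
        with pytest.warns(UserWarning):  # gap rays detect nothing
            bps = segment(m, m.true_centroid, n_rays=16)
        assert len(bps.inner_points) >= 3
        assert len(bps.outer_points) >= 3
        assert len(bps.inner_points) < 16  # the opening leaves gaps
        for _, p in bps.inner_points:
            rho = np.hypot(p[0] - 5, p[1] - 5)
            assert rho == pytest.approx(HS_R_IN, abs=0.05)
        for _, p in bps.outer_points:
            rho = np.hypot(p[0] - 5, p[1] - 5)
            assert rho == pytest.approx(HS_R_OUT, abs=0.05)

    def test_diametric_mode_circle(self, circle):
        bps = segment(circle, (5.0, 5.0), n_rays=8, diametric=True)
        assert len(bps.outer_points) == 8
        for _, p in bps.outer_points:
            assert np.hypot(p[0] - 5, p[1] - 5) == pytest.approx(
                CIRCLE_RADIUS, abs=2 * DEFAULT_STEP_MM)


class TestReconstruct:
    def test_rectangle_corner_polygon_exact(self, phantoms):
        m = phantoms["rectangle"]
        w, h = m._rect_sides()
        corner_angles = [np.arctan2(sy * h / 2, sx * w / 2)
                         for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1))]
        from palpsim.sliding import BoundaryPointSet
        corners = [(th, np.array([5 + np.sign(np.cos(th)) * w / 2,
                                  5 + np.sign(np.sin(th)) * h / 2]))
                   for th in corner_angles]
        bps = BoundaryPointSet(centroid=(5.0, 5.0), angles=np.array(corner_angles),
                               outer_points=corners, inner_points=[], events=[])
        est = reconstruct(bps, mode="polygon", true_area=m.analytic_area)
        assert est.area == pytest.approx(7.79, abs=0.01)
        assert est.area_error == pytest.approx(0.0, abs=0.01)

    def test_inscribed_16gon_closed_form(self, circle):
        r = CIRCLE_RADIUS
        th = 2 * np.pi * np.arange(16) / 16
        from palpsim.sliding import BoundaryPointSet
        pts = [(t, np.array([5 + r * np.cos(t), 5 + r * np.sin(t)]))
               for t in th]
        bps = BoundaryPointSet(centroid=(5.0, 5.0), angles=th,
                               outer_points=pts, inner_points=[], events=[])
        est = reconstruct(bps, mode="polygon", true_area=np.pi * r * r)
        expected = 0.5 * 16 * r * r * np.sin(2 * np.pi / 16)
        assert est.area == pytest.approx(expected, rel=1e-9)

    def test_spline_on_16_exact_circle_points(self, circle):
        r = CIRCLE_RADIUS
        th = 2 * np.pi * np.arange(16) / 16
        from palpsim.sliding import BoundaryPointSet
        pts = [(t, np.array([5 + r * np.cos(t), 5 + r * np.sin(t)]))
               for t in th]
        bps = BoundaryPointSet(centroid=(5.0, 5.0), angles=th,
                               outer_points=pts, inner_points=[], events=[])
        est = reconstruct(bps, mode="spline", true_area=np.pi * r * r)
        assert abs(est.area_error) <= 0.25

    def test_too_few_points_rejected(self):
        from palpsim.sliding import BoundaryPointSet
        bps = BoundaryPointSet(centroid=(5.0, 5.0), angles=np.array([0.0]),
                               outer_points=[(0.0, np.array([7.0, 5.0]))],
                               inner_points=[], events=[])
        with pytest.raises(ValueError):
            reconstruct(bps, mode="polygon")

    def test_precision_identity_reproduces_printed_pairs(self):
        """1 - |dA|/A_true reproduces every printed (error, precision) pair."""
        for err, printed_precision, area in PRINTED_PAIRS:
            assert 1 - abs(err) / area == pytest.approx(printed_precision,
                                                        abs=1e-3)


class TestSegmentationBenchmark:
    @pytest.fixture(scope="class")
    def table(self, phantoms):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return ps.segmentation_benchmark(phantoms)

    def test_table_covers_all_cells(self, table):
        assert len(table) == 12
        assert set(table.n_rays) == {4, 8, 12, 16}

    def test_circle_error_monotone_and_small(self, table):
        errs = table[table["shape"] == "circle"].sort_values("n_rays")
        abs_err = errs.area_error.abs().to_numpy()
        assert np.all(np.diff(abs_err) <= 1e-3)  # non-increasing refinement
        assert abs_err[-1] <= 0.25

    def test_spline_convergence_four_to_sixteen(self, circle):
        e4 = ps.reconstruct(ps.segment(circle, (5, 5), n_rays=4),
                            mode="spline", true_area=circle.analytic_area)
        e16 = ps.reconstruct(ps.segment(circle, (5, 5), n_rays=16),
                             mode="spline", true_area=circle.analytic_area)
        assert abs(e16.area_error) <= abs(e4.area_error) + 1e-3

    def test_polygon_mode_strictly_monotone_on_circle(self, circle):
        errs = []
        for n in (4, 8, 12, 16):
            est = ps.reconstruct(ps.segment(circle, (5, 5), n_rays=n),
                                 mode="polygon", true_area=circle.analytic_area)
            errs.append(abs(est.area_error))
        assert np.all(np.diff(errs) < 0)

    def test_areas_agree_with_raster_oracle(self, phantoms):
        import warnings
        for shape in ("circle", "rectangle", "horseshoe"):
            m = phantoms[shape]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                bps = segment(m, m.true_centroid, n_rays=16)
                est = reconstruct(bps, mode="spline",
                                  true_area=m.analytic_area)
            oracle = raster_area(est.contour, est.inner_contour)
            assert est.area == pytest.approx(oracle, rel=0.01)
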