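"""Inscribed-shape fitters: closed forms, feasibility, dominance, equivariance."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from _oracles import best_subset_polygon_area, random_convex_polygon
from morphofit import (convex_volume_from_points, device_polygon, fit_patient,
                       make_box_fixture, make_prism_fixture, max_circle,
                       max_ellipse, max_rectangle, minimal_bounding_box,
                       polygon_area, slice_volume)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
RIGHT_TRI = np.array([[0.0, 0.0], [60.0, 0.0], [0.0, 60.0]])
RECT_40_20 = np.array([[0.0, 0.0], [40.0, 0.0], [40.0, 20.0], [0.0, 20.0]])


def regular_polygon(n, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestMaxCircle:
    def test_unit_square(self):
        c = max_circle(UNIT_SQUARE)
        np.testing.assert_allclose(c.center, [0.5, 0.5], atol=1e-9)
        assert c.radius == pytest.approx(0.5, abs=1e-9)

    def test_right_triangle_incircle(self):
        c = max_circle(RIGHT_TRI)
        assert c.radius == pytest.approx((60 + 60 - 60 * np.sqrt(2)) / 2,
                                         rel=1e-9)

    def test_degenerate_polygon_rejected(self):
        flat = np.array([[0, 0], [1, 0], [2, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            max_circle(flat)

    def test_clockwise_input_accepted(self):
        c = max_circle(UNIT_SQUARE[::-1])
        assert c.radius == pytest.approx(0.5, abs=1e-9)


class TestMaxRectangle:
    def test_rectangle_recovers_itself(self):
        r = max_rectangle(RECT_40_20)
        assert r.area == pytest.approx(800.0, rel=1e-6)

    def test_inscribed_square_of_circle(self):
        r = max_rectangle(regular_polygon(64, r=10.0))
        assert r.area == pytest.approx(200.0, rel=0.01)  # 2 r^2

    def test_axis_aligned_mode(self):
        diamond = np.array([[10.0, 0.0], [20.0, 8.0], [10.0, 16.0],
                            [0.0, 8.0]])
        free = max_rectangle(diamond)
        aligned = max_rectangle(diamond, axis_aligned=True)
        assert aligned.angle == 0.0
        assert aligned.area <= free.area * (1 + 1e-9)
        # axis-aligned optimum of a diamond is half its area
        assert aligned.area == pytest.approx(polygon_area(diamond) / 2,
                                             rel=1e-6)

    def test_aspect_ratio_definition(self):
        r = max_rectangle(RECT_40_20)
        assert r.aspect_ratio == pytest.approx(2.0, rel=1e-4)

    def test_deterministic_given_input(self):
        poly = random_convex_polygon(np.random.default_rng(5), 10)
        a = max_rectangle(poly)
        b = max_rectangle(poly)
        assert a.params() == b.params()


class TestMaxEllipse:
    def test_rectangle_inscribed_ellipse(self):
        e = max_ellipse(RECT_40_20)
        assert e.area == pytest.approx(np.pi * 40 * 20 / 4, rel=1e-6)
        # axes aligned with the rectangle sides
        assert min(e.angle % (np.pi / 2), np.pi / 2 - e.angle % (np.pi / 2)) \
            < 1e-3

    def test_steiner_inellipse_of_triangle(self):
        tri = np.array([[0.0, 0.0], [50.0, 10.0], [15.0, 45.0]])
        e = max_ellipse(tri)
        assert e.area == pytest.approx(
            np.pi / (3 * np.sqrt(3)) * polygon_area(tri), rel=1e-4)

    def test_dominates_circle(self):
        poly = random_convex_polygon(np.random.default_rng(2), 7)
        assert max_ellipse(poly).area >= max_circle(poly).area * (1 - 1e-9)

    def test_semi_axes_ordered(self):
        e = max_ellipse(RECT_40_20)
        assert e.semi_major >= e.semi_minor > 0


class TestDevicePolygon:
    def test_identity_below_limit(self):
        pent = regular_polygon(5, 10.0)
        d = device_polygon(pent)
        assert len(d.vertices) == 5
        assert d.area == pytest.approx(polygon_area(pent), rel=1e-12)

    def test_greedy_12gon_near_exhaustive_best(self):
        poly = regular_polygon(12, 1.0)
        d = device_polygon(poly, max_sides=9)
        assert len(d.vertices) == 9
        assert d.area >= 0.95 * best_subset_polygon_area(poly, 9)

    def test_never_exceeds_slice_area(self, rng):
        for _ in range(5):
            poly = random_convex_polygon(rng, 14)
            d = device_polygon(poly)
            assert d.area <= polygon_area(poly) * (1 + 1e-12)
            assert len(d.vertices) <= 9


class TestFeasibility:
    """Every returned shape lies inside its polygon at 1e-6 mm tolerance."""

    @pytest.mark.parametrize("i", range(6))
    def test_shapes_inside_polygon(self, i):
        poly = random_convex_polygon(np.random.default_rng(100 + i),
                                     int(8 + i))
        P = Polygon(poly).buffer(1e-6)
        c = max_circle(poly)
        assert P.contains(Point(*c.center).buffer(c.radius * (1 - 1e-9)))
        r = max_rectangle(poly)
        assert all(P.contains(Point(*corner)) for corner in r.corners())
        e = max_ellipse(poly)
        assert all(P.contains(Point(*p)) for p in e.boundary(256))


class TestDominance:
    @pytest.mark.parametrize("i", range(4))
    def test_area_ordering(self, i):
        poly = random_convex_polygon(np.random.default_rng(200 + i), 12)
        area = polygon_area(poly)
        c = max_circle(poly)
        e = max_ellipse(poly)
        r = max_rectangle(poly)
        assert c.area <= e.area * (1 + 1e-9)
        assert e.area <= area * (1 + 1e-9)
        assert r.area <= area * (1 + 1e-9)
        # the incircle's inscribed square is a feasible rectangle
        assert r.area >= 2 * c.radius ** 2 * (1 - 1e-6)


class TestScaleEquivariance:
    @pytest.mark.parametrize("s", [2.0, 0.5])
    def test_areas_scale_quadratically(self, s):
        poly = random_convex_polygon(np.random.default_rng(7), 9)
        base = (max_circle(poly).area, max_rectangle(poly).area,
                max_ellipse(poly).area)
        scaled = (max_circle(poly * s).area, max_rectangle(poly * s).area,
                  max_ellipse(poly * s).area)
        for a, b in zip(base, scaled):
            assert b == pytest.approx(a * s ** 2, rel=1e-3)


class TestFitPatient:
    def test_prism_stack_tie_breaks_to_first_slice(self):
        tri = np.array([[0.0, 0.0], [60.0, 0.0], [0.0, 60.0]])
        pts, _ = make_prism_fixture(tri, 4.0)
        vol = convex_volume_from_points(pts)
        secs = slice_volume(vol, minimal_bounding_box(vol))
        fits = fit_patient(secs)
        assert fits.slice_indices() == {"circle": 0, "rectangle": 0,
                                        "ellipse": 0, "polygon": 0}

    def test_box_fixture_closed_forms(self):
        pts, truth = make_box_fixture(40, 20, 0.6)
        vol = convex_volume_from_points(pts)
        secs = slice_volume(vol, minimal_bounding_box(vol))
        fits = fit_patient(secs)
        areas = fits.areas()
        assert areas["circle"] == pytest.approx(np.pi * 100, rel=1e-4)
        assert areas["rectangle"] == pytest.approx(truth["rectangle_area"],
                                                   rel=1e-4)
        assert areas["ellipse"] == pytest.approx(truth["ellipse_area"],
                                                 rel=1e-4)
        assert areas["polygon"] == pytest.approx(truth["slice_area"],
                                                 rel=1e-9)

    def test_synthetic_patient_orderings(self, one_patient_sections):
        _, _, secs = one_patient_sections
        fits = fit_patient(secs, n_starts=4)
        areas = fits.areas()
        max_slice_area = max(s.area for s in secs)
        assert areas["circle"] <= areas["ellipse"] * (1 + 1e-9)
        for shape in ("circle", "rectangle", "ellipse", "polygon"):
            assert areas[shape] <= max_slice_area * (1 + 1e-9)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            fit_patient([])
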