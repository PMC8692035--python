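"""Hull construction, minimal bounding box and slicing: laws and oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import centroid_decomposition_volume
from morphofit import (CohortParams, DegeneracyError, build_prsp,
                       convex_volume_from_points, generate_cohort,
                       largest_slice, make_box_fixture, make_prism_fixture,
                       minimal_bounding_box, slice_volume)


def _rigid(points, seed=0):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
    t = rng.normal(scale=100.0, size=3)
    return points @ R.T + t


class TestHullVolume:
    def test_unit_cube(self):
        pts, _ = make_box_fixture(1, 1, 1)
        assert convex_volume_from_points(pts).volume == pytest.approx(1.0)

    def test_box_fixture(self):
        pts, truth = make_box_fixture(10, 10, 1)
        assert convex_volume_from_points(pts).volume == pytest.approx(
            truth["volume"])

    def test_matches_centroid_decomposition_oracle(self):
        _, landmarks = generate_cohort(CohortParams(n=1, seed=7))
        for side in ("left", "right"):
            vol = build_prsp(landmarks[0], side)
            oracle = centroid_decomposition_volume(landmarks[0].side_points(side))
            assert vol.volume == pytest.approx(oracle, rel=1e-9)

    def test_coplanar_points_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0],
                         [0.3, 0.3, 0]])
        with pytest.raises(DegeneracyError):
            convex_volume_from_points(flat)

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(DegeneracyError):
            convex_volume_from_points(np.eye(3))


class TestMinimalBoundingBox:
    def test_axis_aligned_box_extents(self):
        pts, _ = make_box_fixture(40, 20, 0.6)
        box = minimal_bounding_box(convex_volume_from_points(pts))
        np.testing.assert_allclose(box.extents, [40, 20, 0.6], atol=1e-9)

    def test_rotation_invariance_of_extents(self):
        pts, _ = make_box_fixture(40, 20, 0.6)
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        box = minimal_bounding_box(convex_volume_from_points(pts @ R.T))
        np.testing.assert_allclose(box.extents, [40, 20, 0.6], atol=1e-6)

    def test_never_exceeds_aabb(self, rng):
        pts = rng.normal(size=(50, 3)) * [30, 20, 5]
        vol = convex_volume_from_points(pts)
        aabb = np.prod(pts.max(axis=0) - pts.min(axis=0))
        box = minimal_bounding_box(vol)
        assert box.volume <= aabb * (1 + 1e-9)

    def test_axes_orthonormal_extents_descending(self, rng):
        pts = rng.normal(size=(40, 3)) * [10, 8, 2]
        box = minimal_bounding_box(convex_volume_from_points(pts))
        np.testing.assert_allclose(box.axes @ box.axes.T, np.eye(3),
                                   atol=1e-9)
        assert box.extents[0] >= box.extents[1] >= box.extents[2]

    def test_contains_all_vertices(self, rng):
        pts = rng.normal(size=(40, 3)) * [10, 8, 2]
        vol = convex_volume_from_points(pts)
        box = minimal_bounding_box(vol)
        local = (vol.vertices - box.center) @ box.axes.T
        assert (np.abs(local) <= box.extents / 2 + 1e-6).all()


class TestSlicing:
    def test_thin_box_yields_single_midplane_slice(self):
        pts, _ = make_box_fixture(40, 20, 0.6)
        vol = convex_volume_from_points(pts)
        secs = slice_volume(vol, minimal_bounding_box(vol), spacing=1.0)
        assert len(secs) == 1
        assert secs[0].area == pytest.approx(800.0, rel=1e-9)

    def test_five_slices_in_5mm_box(self):
        pts, _ = make_box_fixture(40, 20, 5)
        vol = convex_volume_from_points(pts)
        secs = slice_volume(vol, minimal_bounding_box(vol), spacing=1.0)
        assert len(secs) == 5
        for s in secs:
            assert s.area == pytest.approx(800.0, rel=1e-9)

    def test_prism_sections_constant(self):
        tri = np.array([[0.0, 0.0], [60.0, 0.0], [0.0, 60.0]])
        pts, truth = make_prism_fixture(tri, 4.0)
        vol = convex_volume_from_points(pts)
        secs = slice_volume(vol, minimal_bounding_box(vol), spacing=1.0)
        assert len(secs) == 4
        for s in secs:
            assert s.area == pytest.approx(truth["slice_area"], rel=1e-6)

    def test_nonpositive_spacing_rejected(self):
        pts, _ = make_box_fixture(10, 10, 1)
        vol = convex_volume_from_points(pts)
        with pytest.raises(ValueError):
            slice_volume(vol, minimal_bounding_box(vol), spacing=0.0)

    def test_slice_vertices_inside_hull(self, one_patient_sections):
        from scipy.spatial import ConvexHull
        vol, box, secs = one_patient_sections
        hull = ConvexHull(vol.vertices)
        A, b = hull.equations[:, :3], -hull.equations[:, 3]
        for s in secs:
            p3 = s.to_3d(s.polygon)
            assert (p3 @ A.T <= b + 1e-6).all()

    def test_non_thin_volume_warns(self):
        pts, _ = make_box_fixture(10, 10, 9)
        vol = convex_volume_from_points(pts)
        with pytest.warns(UserWarning, match="not thin"):
            slice_volume(vol, minimal_bounding_box(vol))


class TestMeshExport:
    def test_off_file_counts_match(self, tmp_path):
        from morphofit.geometry import write_off
        pts, _ = make_box_fixture(10, 20, 3)
        vol = convex_volume_from_points(pts)
        path = write_off(vol, tmp_path / "vol.off")
        lines = path.read_text().splitlines()
        assert lines[0] == "OFF"
        nv, nf, _ = map(int, lines[1].split())
        assert nv == len(vol.vertices) and nf == len(vol.faces)
        assert len(lines) == 2 + nv + nf


class TestLargestSlice:
    def test_constant_stack_tie_breaks_to_first(self):
        tri = np.array([[0.0, 0.0], [60.0, 0.0], [0.0, 60.0]])
        pts, _ = make_prism_fixture(tri, 4.0)
        vol = convex_volume_from_points(pts)
        secs = slice_volume(vol, minimal_bounding_box(vol))
        assert largest_slice(secs).slice_index == 0

    def test_returns_maximum(self, one_patient_sections):
        _, _, secs = one_patient_sections
        best = largest_slice(secs)
        assert all(best.area >= s.area for s in secs)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            largest_slice([])


@pytest.fixture(scope="module")
def patient_points():
    _, landmarks = generate_cohort(CohortParams(n=1, seed=13))
    return landmarks[0].side_points("left")


class TestInvarianceLaws:
    def _pipeline(self, points, spacing=1.0):
        vol = convex_volume_from_points(points)
        box = minimal_bounding_box(vol)
        secs = slice_volume(vol, box, spacing=spacing)
        return vol.volume, np.sort(box.extents), largest_slice(secs).area

    @pytest.mark.parametrize("s", [2.0, 0.5])
    def test_scaling_law(self, patient_points, s):
        v1, e1, a1 = self._pipeline(patient_points)
        v2, e2, a2 = self._pipeline(patient_points * s, spacing=s)
        assert v2 == pytest.approx(v1 * s ** 3, rel=1e-9)
        np.testing.assert_allclose(e2, e1 * s, rtol=1e-9)
        assert a2 == pytest.approx(a1 * s ** 2, rel=1e-9)

    def test_rigid_motion_invariance(self, patient_points):
        v1, e1, a1 = self._pipeline(patient_points)
        v2, e2, a2 = self._pipeline(_rigid(patient_points, seed=5))
        assert v2 == pytest.approx(v1, rel=1e-6)
        np.testing.assert_allclose(e2, e1, rtol=1e-6)
        assert a2 == pytest.approx(a1, rel=1e-6)
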