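import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from radshape.sections import (
    CutPlane,
    LandmarkError,
    Landmarks,
    SectionContour,
    cross_section,
    define_cut_planes,
    detect_landmarks,
    section_morphometrics,
    specimen_morphometrics,
)


class TestCrossSection:
    def test_unit_cube_midplane_is_unit_square(self):
        cube = trimesh.creation.box(extents=[1.0, 1, 1])
        m = section_morphometrics(
            cross_section(cube, CutPlane("middle", [0, 0, 0], [0, 0, 1]))
        )
        assert np.isclose(m.width, 1.0) and np.isclose(m.depth, 1.0)
        assert np.isclose(m.perimeter, 4.0) and np.isclose(m.area, 1.0)

    def test_sphere_offset_cut_is_smaller_circle(self):
        # r=5 cut at z=3 -> circle of radius 4
        sphere = trimesh.creation.icosphere(6, 5.0)  # ~0.2 mm edges
        m = section_morphometrics(
            cross_section(sphere, CutPlane("distal", [0, 0, 3.0], [0, 0, 1]))
        )
        assert abs(m.perimeter - 8 * np.pi) / (8 * np.pi) < 0.005
        assert abs(m.area - 16 * np.pi) / (16 * np.pi) < 0.005

    def test_plane_missing_mesh_raises(self):
        sphere = trimesh.creation.icosphere(2, 5.0)
        with pytest.raises(ValueError, match="misses"):
            cross_section(sphere, CutPlane("distal", [0, 0, 7.0], [0, 0, 1]))

    def test_tangent_plane_degenerate(self):
        sphere = trimesh.creation.icosphere(2, 5.0)
        with pytest.raises(ValueError):
            cross_section(sphere, CutPlane("distal", [0, 0, 5.0], [0, 0, 1]))

    def test_open_chain_from_hole_raises(self):
        sphere = trimesh.creation.icosphere(3, 5.0)
        centers = sphere.triangles.mean(axis=1)
        drop = int(np.abs(centers[:, 2] - 3.0).argmin())
        keep = np.ones(len(sphere.faces), bool)
        keep[drop] = False
        holed = trimesh.Trimesh(sphere.vertices, sphere.faces[keep], process=False)
        with pytest.raises(ValueError):
            cross_section(holed, CutPlane("distal", [0, 0, 3.0], [0, 0, 1]))

    def test_contour_is_counter_clockwise(self, bone):
        contour = cross_section(
            bone.mesh, CutPlane("distal", [0, 0, 60.0], [0, 0, 1])
        )
        x, y = contour.vertices[:, 0], contour.vertices[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0


class TestMorphometrics:
    def test_axis_aligned_unit_square(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        m = section_morphometrics(sq)
        assert (m.width, m.depth, m.perimeter, m.area) == (1.0, 1.0, 4.0, 1.0)

    def test_ellipse_at_reference_male_distal_scale(self):
        """Half-axes 16.5 x 11.9 -> width 33.0, depth 23.8, area pi*a*b."""
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        ellipse = np.column_stack([16.5 * np.cos(t), 11.9 * np.sin(t)])
        m = section_morphometrics(ellipse)
        assert abs(m.width - 33.0) < 1e-3
        assert abs(m.depth - 23.8) < 1e-3
        assert abs(m.area - np.pi * 16.5 * 11.9) / (np.pi * 16.5 * 11.9) < 1e-4

    def test_l_shaped_polygon_hand_oracle(self):
        # shoelace by hand: area 3, perimeter 8, extents 2 x 2
        poly = np.array([[0.0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]])
        m = section_morphometrics(poly)
        assert m.area == 3.0 and m.perimeter == 8.0
        assert m.width == 2.0 and m.depth == 2.0

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            section_morphometrics(np.array([[0.0, 0], [1, 1]]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(4, 40),
    )
    def test_invariants_on_random_star_polygons(self, seed, n):
        """Isoperimetric and bounding-box inequalities hold for any contour."""
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0, 2 * np.pi, n))
        r = rng.uniform(0.5, 3.0, n)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        m = section_morphometrics(poly)
        assert m.width > 0 and m.depth > 0 and m.perimeter > 0
        assert 4 * np.pi * m.area <= m.perimeter**2 * (1 + 1e-12)
        assert m.area <= m.width * m.depth * (1 + 1e-12)
        assert m.perimeter >= 2 * max(m.width, m.depth) * (1 - 1e-12)


class TestLandmarks:
    def test_detection_close_to_generator_truth(self, bone):
        lm = detect_landmarks(bone.mesh)
        edge = np.median(bone.mesh.edges_unique_length)
        for key, detected in (
            ("styloid_tip", lm.styloid_tip),
            ("tubercle_dorsal", lm.tubercle_dorsal),
        ):
            assert np.linalg.norm(detected - bone.truth_landmarks[key]) < 2 * edge

    def test_plain_cylinder_has_no_landmarks(self):
        cyl = trimesh.creation.cylinder(radius=10.0, height=60.0, sections=64)
        with pytest.raises(LandmarkError, match="not identifiable"):
            detect_landmarks(cyl)

    def test_mirrored_bone_gives_mirrored_landmarks(self, bone, bone_left):
        lm_r = detect_landmarks(bone.mesh)
        lm_l = detect_landmarks(bone_left.mesh)
        flip = np.array([-1.0, 1.0, 1.0])
        np.testing.assert_allclose(lm_l.styloid_tip, lm_r.styloid_tip * flip, atol=1e-9)
        np.testing.assert_allclose(
            lm_l.tubercle_dorsal, lm_r.tubercle_dorsal * flip, atol=1e-9
        )

    def test_landmark_ordering_enforced(self):
        with pytest.raises(ValueError, match="distal"):
            Landmarks(styloid_tip=[0, 0, 10.0], tubercle_dorsal=[0, 5.0, 20.0])


class TestCutPlanes:
    def test_plane_positions_from_landmark_arithmetic(self):
        lm = Landmarks(styloid_tip=[2.0, 0, 100.0], tubercle_dorsal=[0, 8.0, 90.0])
        distal, middle, proximal = define_cut_planes(lm)
        assert np.isclose(distal.origin[2], 90.0)
        assert np.isclose(middle.origin[2], 87.5)
        assert np.isclose(proximal.origin[2], 85.0)
        for p in (distal, middle, proximal):
            np.testing.assert_allclose(p.normal, [0, 0, 1.0])

    def test_equidistant_spacing(self):
        lm = Landmarks(styloid_tip=[0, 0, 77.0], tubercle_dorsal=[0, 6.0, 63.0])
        d, m, p = define_cut_planes(lm)
        gap1 = d.origin[2] - m.origin[2]
        gap2 = m.origin[2] - p.origin[2]
        assert np.isclose(gap1, gap2) and np.isclose(gap1, 14.0 / 4)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError):
            Landmarks(styloid_tip=[0, 0, 90.0], tubercle_dorsal=[0, 5.0, 90.0])


def test_translation_along_axis_shifts_planes_not_morphometrics(bone):
    base = specimen_morphometrics(bone.mesh)
    moved = bone.mesh.copy()
    moved.apply_translation([0, 0, 17.3])
    shifted = specimen_morphometrics(moved)
    for label in base:
        for key, val in base[label].as_dict().items():
            assert abs(shifted[label].as_dict()[key] - val) < 1e-9


def test_computed_contours_satisfy_type_invariants(bone):
    lm = detect_landmarks(bone.mesh)
    for plane in define_cut_planes(lm):
        m = section_morphometrics(cross_section(bone.mesh, plane))
        assert 4 * np.pi * m.area <= m.perimeter**2
        assert m.area <= m.width * m.depth
        assert m.perimeter >= 2 * max(m.width, m.depth)
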