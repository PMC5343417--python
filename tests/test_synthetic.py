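import numpy as np
import pytest

from radshape.mesh import validate_mesh
from radshape.sections import CutPlane, cross_section, section_morphometrics
from radshape.synthetic import (
    BoneParams,
    PopulationConfig,
    StationProfile,
    analytic_morphometrics,
    calibrated_bone_params,
    draw_specimen_params,
    generate_bone,
    sample_population,
    superellipse_area,
)


def _cylinder_params(r=10.0, squareness=2.0):
    """Circular profiles everywhere, no prominences, straight axis."""
    return BoneParams(
        axis_length=60.0,
        axial_curvature=0.0,
        styloid_height=0.0,
        tubercle_prominence=0.0,
        station_profiles=(
            StationProfile(0.0, r, r, squareness),
            StationProfile(1.0, r, r, squareness),
        ),
    )


class TestGenerateBone:
    def test_cylinder_sections_match_closed_form(self):
        """Circular r=10 profiles: any shaft section is a circle of d=20 mm."""
        spec = generate_bone(_cylinder_params(), mesh_resolution=0.5)
        for z in (15.0, 30.0, 41.7):
            m = section_morphometrics(
                cross_section(spec.mesh, CutPlane("distal", [0, 0, z], [0, 0, 1]))
            )
            assert abs(m.width - 20.0) / 20.0 < 0.01
            assert abs(m.depth - 20.0) / 20.0 < 0.01
            assert abs(m.perimeter - 20 * np.pi) / (20 * np.pi) < 0.01
            assert abs(m.area - 100 * np.pi) / (100 * np.pi) < 0.01

    def test_proximal_taper_shrinks_section_area(self):
        params = BoneParams(
            axis_length=60.0,
            styloid_height=0.0,
            tubercle_prominence=0.0,
            station_profiles=(
                StationProfile(0.0, 8.0, 8.0, 2.0),
                StationProfile(1.0, 10.0, 10.0, 2.0),
            ),
        )
        prox = analytic_morphometrics(params, 0.0)
        dist = analytic_morphometrics(params, 60.0)
        assert prox["area"] < dist["area"]
        # analytic values agree with the superellipse closed form
        assert abs(dist["area"] - superellipse_area(10, 10, 2)) / dist["area"] < 1e-3

    def test_left_is_exact_mirror_of_right(self):
        right = generate_bone(calibrated_bone_params(side="R"), 1.2)
        left = generate_bone(calibrated_bone_params(side="L"), 1.2)
        assert np.array_equal(
            left.mesh.vertices, right.mesh.vertices * np.array([-1.0, 1.0, 1.0])
        )
        assert left.mesh.volume > 0
        np.testing.assert_allclose(
            left.truth_landmarks["styloid_tip"],
            right.truth_landmarks["styloid_tip"] * np.array([-1.0, 1.0, 1.0]),
        )

    def test_generated_mesh_is_pipeline_ready(self, bone):
        report = validate_mesh(bone.mesh)
        assert report.pipeline_ready
        assert report.n_degenerate_faces == 0

    def test_truth_landmarks_lie_on_surface(self, bone):
        from radshape._geometry import closest_point_on_mesh

        pts = np.vstack(list(bone.truth_landmarks.values()))
        _, dist, _ = closest_point_on_mesh(bone.mesh, pts)
        assert dist.max() < 2 * np.median(bone.mesh.edges_unique_length)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate profile"):
            BoneParams(station_profiles=(
                StationProfile(0.0, 0.0, 5.0, 2.0), StationProfile(1.0, 10.0, 5.0, 2.0),
            ))

    def test_unsorted_stations_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BoneParams(station_profiles=(
                StationProfile(0.5, 10.0, 5.0, 2.0), StationProfile(0.2, 10.0, 5.0, 2.0),
            ))


class TestCalibration:
    """The default parameters reproduce the reference plane statistics."""

    def test_anchor_planes_match_reference_values(self):
        params = calibrated_bone_params()
        z_t = params.tubercle_z
        from radshape.synthetic import truth_landmarks

        lm = truth_landmarks(params)
        d = lm["styloid_tip"][2] - lm["tubercle_dorsal"][2]
        targets = {
            z_t: (29.0, 21.0, 472.6),
            z_t - d / 4: (28.2, 19.5, 427.5),
            z_t - d / 2: (26.3, 17.2, 353.2),
        }
        for z, (w, dep, area) in targets.items():
            m = analytic_morphometrics(params, z)
            assert abs(m["width"] - w) < 0.02
            assert abs(m["depth"] - dep) < 0.06
            assert abs(m["area"] - area) / area < 0.005

    def test_plane_spacing_is_anatomically_plausible(self):
        from radshape.synthetic import truth_landmarks

        lm = truth_landmarks(calibrated_bone_params())
        spacing = (lm["styloid_tip"][2] - lm["tubercle_dorsal"][2]) / 4.0
        assert 2.9 <= spacing <= 4.1  # reference populations: 3.5 +/- 0.6 mm


class TestSamplePopulation:
    def test_determinism_same_seed_same_vertices(self):
        cfg = PopulationConfig(n_per_group=3, seed=7, mesh_resolution=2.0)
        a = sample_population(cfg)
        b = sample_population(cfg)
        assert [s.specimen_id for s in a] == [s.specimen_id for s in b]
        for x, y in zip(a, b):
            assert np.array_equal(x.mesh.vertices, y.mesh.vertices)

    def test_gender_size_ratio_is_planted(self):
        """Male/female mean distal width converges to the planted 33/29 ratio."""
        cfg = PopulationConfig(n_per_group=250, seed=3)
        widths = {"F": [], "M": []}
        for gender, _side, params in draw_specimen_params(cfg):
            widths[gender].append(
                analytic_morphometrics(params, params.tubercle_z * params.global_scale)["width"]
            )
        ratio = np.mean(widths["M"]) / np.mean(widths["F"])
        assert abs(ratio - 33.0 / 29.0) < 0.02

    def test_group_layout(self):
        pop = sample_population(PopulationConfig(n_per_group=2, seed=1, mesh_resolution=2.5))
        labels = {(s.gender, s.side) for s in pop}
        assert labels == {("F", "L"), ("F", "R"), ("M", "L"), ("M", "R")}
        assert len(pop) == 8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_per_group=0)
        with pytest.raises(ValueError):
            PopulationConfig(vertex_noise_sd=-1.0)


def test_mesh_morphometrics_converge_to_analytic():
    """Pipeline measurements on the mesh approach the parametric closed form
    as the mesh is refined (cylinder oracle at 0.5 mm edges, <=1% error)."""
    spec = generate_bone(_cylinder_params(), mesh_resolution=0.5)
    m = section_morphometrics(
        cross_section(spec.mesh, CutPlane("middle", [0, 0, 30.0], [0, 0, 1]))
    )
    truth = analytic_morphometrics(spec.truth_params, 30.0)
    for key in ("width", "depth", "perimeter", "area"):
        assert abs(m.as_dict()[key] - truth[key]) / truth[key] < 0.01
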