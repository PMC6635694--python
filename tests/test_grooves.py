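"""Cross-sections, circle fitting and the rotational groove scan."""

import numpy as np
import pytest
import trimesh

from boneframe import frame as bframe
from boneframe import grooves as gv
from boneframe import mesh as bmesh
from boneframe import synthetic as bsynth
from boneframe.errors import (
    CollinearPointsError,
    DegeneracyWarning,
    EmptySectionError,
    GrooveNotFoundError,
    InputError,
)


class TestFitCircle:
    def test_exact_points(self):
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        pts = np.column_stack([3 + 5 * np.cos(theta), -2 + 5 * np.sin(theta)])
        fit = gv.fit_circle(pts)
        assert fit.radius == pytest.approx(5.0, abs=1e-9)
        assert fit.center == pytest.approx([3.0, -2.0], abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_three_points_circumscribed(self):
        # circumscribed circle of a 3-4-5 right triangle: hypotenuse/2
        fit = gv.fit_circle([(0, 0), (3, 0), (0, 4)])
        assert fit.radius == pytest.approx(2.5, abs=1e-9)
        assert fit.center == pytest.approx([1.5, 2.0], abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(CollinearPointsError):
            gv.fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_noisy_quarter_arc(self, rng):
        errors = []
        for _ in range(20):
            theta = rng.uniform(0, np.pi / 2, 60)
            pts = np.column_stack(
                [10 * np.cos(theta), 10 * np.sin(theta)]
            ) + rng.normal(0, 0.05, (60, 2))
            errors.append(abs(gv.fit_circle(pts).radius - 10.0) / 10.0)
        assert max(errors) < 0.02


class TestFitCircleProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        cx=st.floats(-50, 50),
        cy=st.floats(-50, 50),
        r=st.floats(0.5, 30),
        start=st.floats(0, 2 * np.pi),
        span=st.floats(0.6, 2 * np.pi),
        n=st.integers(5, 40),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_arc_recovered(self, cx, cy, r, start, span, n):
        """The algebraic fit is exact on noiseless points from any arc
        subtending at least ~35 degrees."""
        theta = np.linspace(start, start + span, n)
        pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        fit = gv.fit_circle(pts)
        assert fit.radius == pytest.approx(r, rel=1e-6)
        assert fit.center == pytest.approx([cx, cy], abs=1e-5 * max(1.0, r))


class TestSections:
    def test_cube_mid_section(self):
        cube = bframe.to_body_frame(bmesh.unit_cube())
        sec = gv.section_at(cube, [0, 0, 1], 0.0)
        assert len(sec.contours) == 1
        assert sec.area == pytest.approx(1.0, rel=1e-6)

    def test_cylinder_axial_section_area(self):
        # plane containing the cylinder's (z) axis: an 8 x 20 rectangle
        cyl = bmesh.cylinder(4.0, 20.0, sections=256)
        sec = gv.section_at(cyl, [0, 0, 1], 30.0)
        assert sec.area == pytest.approx(160.0, rel=0.01)

    def test_cylinder_transverse_section_area(self):
        # normal along the cylinder axis: a disc of radius 4
        cyl = bmesh.cylinder(4.0, 20.0, sections=256)
        sec = gv.section_at(cyl, [1, 0, 0], 90.0)
        assert sec.area == pytest.approx(np.pi * 16.0, rel=0.01)

    def test_plane_outside_mesh(self):
        cube = bmesh.unit_cube()
        with pytest.raises(EmptySectionError):
            gv.section_at(cube, [0, 0, 1], 0.0, plane_offset=10.0)

    def test_nested_contours_subtract(self):
        outer = [(0, 0), (4, 0), (4, 4), (0, 4)]
        inner = [(1, 1), (3, 1), (3, 3), (1, 3)]
        assert gv.cross_section_area(
            [np.array(outer, float), np.array(inner, float)]
        ) == pytest.approx(16.0 - 4.0)


class TestBaseLevel:
    def test_box_maximal_section_is_diagonal_plane(self, box_10_4_2):
        """Among planes containing the long axis of a 10x4x2 box, the
        largest section is the diagonal one: 10 x sqrt(4^2 + 2^2)."""
        aligned = bframe.to_body_frame(box_10_4_2)
        angle, area = gv.find_base_level(aligned)
        assert area == pytest.approx(10.0 * np.sqrt(20.0), rel=1e-3)
        diag = np.degrees(np.arctan2(4.0, 2.0))  # 63.43; the mirror twin +90
        assert min(abs(angle - diag), abs(angle - diag - 90.0)) <= 0.5

    def test_sphere_tie_returns_zero(self):
        sphere = bmesh.icosphere(3.0, 3)
        with pytest.warns((DegeneracyWarning, UserWarning)):
            angle, _ = gv.find_base_level(sphere, axis=[1, 0, 0], angular_step=10.0)
        assert angle == 0.0

    def test_invalid_step(self, box_10_4_2):
        with pytest.raises(InputError):
            gv.find_base_level(box_10_4_2, angular_step=0.0)


class TestArcDetection:
    def test_two_arcs_on_head_section(self, body_frame_bone):
        pivots = gv.locate_grooves(body_frame_bone)
        sec = gv.section_at(
            body_frame_bone, [0, 0, 1], 0.0, pivot=pivots["medial"]
        )
        arcs = gv.detect_groove_arcs(sec)
        for arc in (arcs.medial, arcs.lateral):
            fit = gv.fit_circle(arc)
            assert fit.radius == pytest.approx(4.0, rel=0.1)

    def test_convex_contour_has_no_grooves(self):
        cyl = bframe.to_body_frame(bmesh.cylinder(4.0, 20.0, sections=128))
        sec = gv.section_at(cyl, [0, 0, 1], 0.0)
        with pytest.raises(GrooveNotFoundError):
            gv.detect_groove_arcs(sec)

    def test_flip_sides_swaps_labels(self, skewed_bone):
        """Anatomical sidedness is not derivable from inertia, so the
        medial/lateral assignment is a convention; the flip_sides
        override swaps which groove carries which label."""
        _, mesh, _ = skewed_bone
        res = gv.analyze_grooves(mesh)
        res_f = gv.analyze_grooves(mesh, flip_sides=True)
        assert res_f.medial_fit.rotation_angle == pytest.approx(
            res.lateral_fit.rotation_angle, abs=2 * gv.DEFAULT_STEP
        )
        assert res_f.lateral_fit.rotation_angle == pytest.approx(
            res.medial_fit.rotation_angle, abs=2 * gv.DEFAULT_STEP
        )

    def test_mirror_image_gives_identical_results(self, skewed_bone):
        """The deterministic sign convention normalizes handedness: a
        mirrored bone lands in the same body-frame representation, so
        the scan output is mirror-invariant (sidedness must come from
        the flip_sides override, not from the mesh)."""
        _, mesh, _ = skewed_bone
        res = gv.analyze_grooves(mesh)
        res_m = gv.analyze_grooves(mesh.apply_transform(np.diag([1.0, -1.0, 1.0, 1.0])))
        assert res_m.medial_fit.rotation_angle == pytest.approx(
            res.medial_fit.rotation_angle, abs=gv.DEFAULT_STEP
        )
        assert res_m.medial_fit.curvature_diameter == pytest.approx(
            res.medial_fit.curvature_diameter, rel=1e-3
        )


class TestScan:
    def test_recovers_cd_and_skew(self, skewed_bone):
        params, mesh, truth = skewed_bone
        expected = bsynth.groove_truth_in_body_frame(
            params, bframe.principal_frame(mesh)
        )
        aligned = bframe.to_body_frame(mesh)
        pivots = gv.locate_grooves(aligned)
        for side in ("medial", "lateral"):
            fit = gv.scan_groove_cd(aligned, side, pivot=pivots[side])
            assert fit.curvature_diameter == pytest.approx(
                expected[side]["cd"], rel=0.03
            )
            assert fit.rotation_angle == pytest.approx(
                expected[side]["angle"], abs=gv.DEFAULT_STEP
            )
            assert fit.arc_points >= 5
            assert fit.rms_residual < 0.05

    def test_min_cd_is_trace_minimum(self, body_frame_bone):
        fit = gv.scan_groove_cd(body_frame_bone, "medial", angle_range=5.0)
        cds = [cd for _, cd in fit.trace]
        assert fit.curvature_diameter == pytest.approx(min(cds))
        assert fit.curvature_diameter <= min(cds) + 1e-12

    def test_max_scan_at_range_edges(self, body_frame_bone):
        """Oblique cuts fit larger circles, so the max-CD variant lands
        at the far end of the scanned range for a straight groove."""
        fit = gv.scan_groove_cd(
            body_frame_bone, "medial", scan="max_cd", angle_range=5.0
        )
        assert abs(fit.rotation_angle) == pytest.approx(5.0, abs=2 * gv.DEFAULT_STEP)

    def test_invalid_arguments(self, body_frame_bone):
        with pytest.raises(InputError):
            gv.scan_groove_cd(body_frame_bone, "medial", step=0.0)
        with pytest.raises(InputError):
            gv.scan_groove_cd(body_frame_bone, "dorsal")
        with pytest.raises(InputError):
            gv.scan_groove_cd(body_frame_bone, "medial", scan="avg_cd")

    def test_rigid_motion_invariance(self, skewed_bone, rng):
        """The body frame absorbs an arbitrary pre-rotation: recovered
        angles agree within one angular step."""
        _, mesh, _ = skewed_bone
        T = trimesh.transformations.rotation_matrix(
            rng.uniform(0, np.pi), rng.normal(size=3)
        )
        res0 = gv.analyze_grooves(mesh)
        res1 = gv.analyze_grooves(mesh.apply_transform(T))
        assert res1.medial_fit.rotation_angle == pytest.approx(
            res0.medial_fit.rotation_angle, abs=gv.DEFAULT_STEP
        )
        assert res1.lateral_fit.rotation_angle == pytest.approx(
            res0.lateral_fit.rotation_angle, abs=gv.DEFAULT_STEP
        )


def _fit(side, angle, settings=None):
    return gv.GrooveFit(
        side=side,
        rotation_angle=angle,
        circle_center=np.zeros(2),
        curvature_diameter=8.0,
        rms_residual=0.01,
        arc_points=30,
        scan_settings=settings or {"scan": "min_cd", "step": 0.5},
    )


class TestParallelism:
    @pytest.mark.parametrize(
        "medial,lateral,verdict",
        [
            (-2.0, -2.0, "parallel"),       # one common flexion axis
            (-1.0, -3.0, "dis_parallel"),   # axes 2 degrees apart
            (-1.0, -1.5, "parallel"),       # at the tolerance boundary
        ],
    )
    def test_verdicts(self, medial, lateral, verdict):
        result = gv.parallelism_test(_fit("medial", medial), _fit("lateral", lateral))
        assert result.verdict == verdict
        assert result.parallel == (verdict == "parallel")
        assert result.angle_difference == pytest.approx(medial - lateral)

    def test_mismatched_settings_rejected(self):
        with pytest.raises(InputError, match="scan settings"):
            gv.parallelism_test(
                _fit("medial", 0.0),
                _fit("lateral", 0.0, settings={"scan": "min_cd", "step": 1.0}),
            )

    def test_needs_both_sides(self):
        with pytest.raises(InputError):
            gv.parallelism_test(_fit("medial", 0.0), _fit("medial", 0.0))

    def test_negative_tolerance_rejected(self):
        with pytest.raises(InputError):
            gv.parallelism_test(
                _fit("medial", 0.0), _fit("lateral", 0.0), tolerance=-1.0
            )


def test_section_to_svg(tmp_path, body_frame_bone):
    sec = gv.section_at(body_frame_bone, [0, 0, 1], 0.0)
    out = tmp_path / "section.svg"
    gv.section_to_svg(sec, out)
    text = out.read_text()
    assert text.startswith("<svg") and "<polygon" in text
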