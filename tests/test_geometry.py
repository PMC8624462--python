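import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cephrr.dataset import AnnotationDataset
from cephrr.exceptions import (
    DegenerateGeometryError,
    MissingLandmarkError,
    OrientationAmbiguousError,
)
from cephrr.geometry import (
    Frame,
    angle_between_planes,
    build_fh_frame,
    mean_landmark,
    midpoint,
    plane_from_points,
    signed_vertical_distance,
    subject_fh_frame,
    to_frame,
)
from cephrr.simulate import simulate

from conftest import make_truth

finite_coord = st.floats(-200, 200, allow_nan=False)
vec3 = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestPlane:
    def test_axis_aligned_plane(self):
        p = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_hint=(0, 0, 1))
        np.testing.assert_allclose(p.normal, [0, 0, 1], atol=1e-12)

    def test_hint_flips_normal(self):
        # cross((2,0,0), (0,0,3)) points along -y; the hint selects +y
        p = plane_from_points((0, 0, 0), (2, 0, 0), (0, 0, 3), orient_hint=(0, 1, 0))
        np.testing.assert_allclose(p.normal, [0, 1, 0], atol=1e-12)

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            plane_from_points((0, 0, 0), (1, 1, 1), (2, 2, 2))

    def test_orthogonal_hint_rejected(self):
        with pytest.raises(OrientationAmbiguousError):
            plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_hint=(1, 0, 0))

    @given(vec3, vec3, vec3)
    def test_plane_contains_its_points(self, p1, p2, p3):
        area = np.linalg.norm(np.cross(p2 - p1, p3 - p1)) / 2
        if area <= 1e-3:  # stay away from the degeneracy threshold
            return
        plane = plane_from_points(p1, p2, p3)
        for p in (p1, p2, p3):
            assert abs(signed_vertical_distance(plane, p)) <= 1e-9 * max(1, area)

    @given(vec3, vec3, vec3, st.permutations([0, 1, 2]))
    def test_permutation_invariance_with_hint(self, p1, p2, p3, perm):
        pts = [p1, p2, p3]
        area = np.linalg.norm(np.cross(p2 - p1, p3 - p1)) / 2
        if area <= 1e-3:
            return
        base = plane_from_points(*pts)
        hint = base.normal
        a = plane_from_points(*pts, orient_hint=hint)
        b = plane_from_points(*(pts[i] for i in perm), orient_hint=hint)
        np.testing.assert_allclose(a.normal, b.normal, atol=1e-9)


class TestSignedDistance:
    def test_defining_points_have_zero_distance(self):
        plane = plane_from_points((1, 2, 3), (4, 0, 3), (0, 5, -1))
        for p in ((1, 2, 3), (4, 0, 3), (0, 5, -1)):
            assert abs(signed_vertical_distance(plane, p)) < 1e-9

    @pytest.mark.parametrize("point,expected", [((5, 5, 3), 3.0), ((5, 5, -3), -3.0)])
    def test_sign_follows_normal(self, point, expected):
        plane = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_hint=(0, 0, 1))
        assert signed_vertical_distance(plane, point) == pytest.approx(expected)


class TestAngleBetweenPlanes:
    def test_identical_planes(self):
        p = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert angle_between_planes(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_analytic_five_degrees(self):
        a = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0), orient_hint=(0, 0, 1))
        t = np.radians(5.0)
        from cephrr.geometry import Plane

        b = Plane((0, 0, 0), (0, np.sin(t), np.cos(t)))
        assert angle_between_planes(a, b) == pytest.approx(5.0, abs=1e-9)

    def test_antiparallel_normals_give_zero(self):
        from cephrr.geometry import Plane

        a = Plane((0, 0, 0), (0, 0, 1))
        b = Plane((0, 0, 5), (0, 0, -1))
        assert angle_between_planes(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_rigid_invariance(self, rng):
        from cephrr.geometry import Plane

        a = plane_from_points((0, 0, 0), (3, 0, 1), (0, 2, -1))
        b = plane_from_points((1, 1, 1), (4, 0, 0), (0, 3, 2))
        assert angle_between_planes(a, b) == pytest.approx(angle_between_planes(b, a))
        R, t = random_rotation(rng), rng.normal(size=3) * 50
        a2 = Plane(R @ a.anchor + t, R @ a.normal)
        b2 = Plane(R @ b.anchor + t, R @ b.normal)
        assert angle_between_planes(a2, b2) == pytest.approx(
            angle_between_planes(a, b), abs=1e-9
        )


class TestMidpoint:
    def test_examples(self):
        np.testing.assert_allclose(midpoint((0, 0, 0), (2, 4, 6)), [1, 2, 3])
        np.testing.assert_allclose(midpoint((1, 2, 3), (1, 2, 3)), [1, 2, 3])
        np.testing.assert_allclose(
            midpoint((0, 1, 2), (5, -1, 3)), midpoint((5, -1, 3), (0, 1, 2))
        )


class TestFrame:
    def test_canonical_construction(self):
        f = build_fh_frame((-40, 0, 0), (40, 0, 0), (30, -70, 0), (0, 0, 1))
        np.testing.assert_allclose(f.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.z_axis, [0, 0, 1], atol=1e-12)

    def test_porions_land_symmetric_on_x(self, rng):
        por_r, por_l = rng.normal(size=3) * 40, rng.normal(size=3) * 40
        orb_l = rng.normal(size=3) * 40
        f = build_fh_frame(por_r, por_l, orb_l, superior_hint=(0, 0, 1))
        d = np.linalg.norm(por_l - por_r)
        np.testing.assert_allclose(to_frame(f, por_r), [-d / 2, 0, 0], atol=1e-9)
        np.testing.assert_allclose(to_frame(f, por_l), [d / 2, 0, 0], atol=1e-9)
        assert to_frame(f, orb_l)[2] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_hint_rejected(self):
        with pytest.raises(OrientationAmbiguousError):
            build_fh_frame((-40, 0, 0), (40, 0, 0), (30, -70, 0), (0, 1, 0))

    def test_origin_maps_to_zero_and_identity_frame(self):
        f = Frame((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1))
        p = np.array([3.0, -2.0, 7.0])
        np.testing.assert_allclose(to_frame(f, p), p)
        np.testing.assert_allclose(to_frame(f, f.origin), [0, 0, 0])

    @given(vec3, vec3)
    def test_to_frame_is_rigid(self, p, q):
        f = build_fh_frame((-33, 1, 2), (33, -1, 0), (30, -68, -3), (0, 0, 1))
        tp, tq = to_frame(f, p), to_frame(f, q)
        assert np.linalg.norm(tp - tq) == pytest.approx(
            np.linalg.norm(p - q), abs=1e-9
        )


class TestMeanLandmark:
    def test_mean_of_repetitions(self, rng):
        from cephrr.dataset import LandmarkObservation

        pts = rng.normal(size=(6, 3)) * 10
        obs = [
            LandmarkObservation("S01", f"O{k % 3 + 1}", str(k // 3 + 1), "Na", tuple(p))
            for k, p in enumerate(pts)
        ]
        ds = AnnotationDataset.from_observations(obs)
        np.testing.assert_allclose(
            mean_landmark(ds, "S01", "Na"), pts.sum(axis=0) / 6, atol=1e-12
        )

    def test_missing_landmark_raises(self, noise_free_dataset):
        with pytest.raises(MissingLandmarkError):
            mean_landmark(noise_free_dataset, "S01", "nope")  # pragma: no cover


class TestSubjectFrame:
    def test_mean_fh_landmarks_define_the_frame(self, quiet_dataset):
        """After reorientation the mean Po-R/Po-L sit at (-d/2,0,0)/(d/2,0,0)
        and mean Or-L has z = 0."""
        for subject in quiet_dataset.subjects:
            f = subject_fh_frame(quiet_dataset, subject)
            por_r = to_frame(f, mean_landmark(quiet_dataset, subject, "Po-R"))
            por_l = to_frame(f, mean_landmark(quiet_dataset, subject, "Po-L"))
            orb_l = to_frame(f, mean_landmark(quiet_dataset, subject, "Or-L"))
            d = np.linalg.norm(por_l - por_r)
            np.testing.assert_allclose(por_r, [-d / 2, 0, 0], atol=1e-9)
            np.testing.assert_allclose(por_l, [d / 2, 0, 0], atol=1e-9)
            assert abs(orb_l[2]) < 1e-9

    def test_menton_fallback_puts_menton_inferior(self):
        """With a superior hint orthogonal to the FH normal, the frame sign
        is fixed so Menton lies below the plane."""
        dataset, _ = simulate(make_truth(), n_subjects=1, n_operators=1, n_sessions=1)
        plane_normal = build_fh_frame(
            mean_landmark(dataset, "S01", "Po-R"),
            mean_landmark(dataset, "S01", "Po-L"),
            mean_landmark(dataset, "S01", "Or-L"),
        ).z_axis
        hint = np.cross(plane_normal, [1.0, 0.0, 0.0])
        hint /= np.linalg.norm(hint)
        f = subject_fh_frame(dataset, "S01", superior_hint=hint)
        me = to_frame(f, mean_landmark(dataset, "S01", "Me"))
        assert me[2] < 0
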