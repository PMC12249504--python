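"""Median-plane estimation, mirroring, and TPS registration contracts."""

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator
from scipy.spatial.transform import Rotation

from mandrec.errors import (DegenerateGeometryError,
                            InsufficientLandmarksError, LandmarkError)
from mandrec.geometry import Plane
from mandrec.io_formats import Landmark, LandmarkSet
from mandrec.registration import (ThinPlateSpline3D, default_reference,
                                  estimate_median_plane, load_reference,
                                  mirror_landmarks, mirror_mesh,
                                  register_reference, registration_quality,
                                  save_reference)
from mandrec.synthetic_anatomy import MandibleSpec, generate_mandible


class TestMedianPlane:
    def test_symmetric_set_gives_x_equals_zero(self, reference):
        plane = estimate_median_plane(reference.landmarks)
        assert abs(abs(plane.normal[0]) - 1.0) < 1e-3
        assert abs(plane.anchor @ plane.normal) < 0.1

    def test_translation_equivariance(self, reference):
        shifted = LandmarkSet([
            Landmark(e.name, e.position + np.array([10.0, 0.0, 0.0]))
            for e in reference.landmarks])
        plane = estimate_median_plane(shifted)
        # plane passes through x = 10
        assert abs(plane.signed_distance(np.array([10.0, 0.0, 0.0]))) < 0.1

    def test_rotated_set_recovers_rotated_plane(self, reference):
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        rotated = LandmarkSet([Landmark(e.name, R @ e.position)
                               for e in reference.landmarks])
        plane = estimate_median_plane(rotated)
        expected_normal = R @ np.array([1.0, 0.0, 0.0])
        align = abs(plane.normal @ expected_normal)
        assert align > 1.0 - 1e-4

    def test_too_few_pairs_rejected(self):
        lm = LandmarkSet([Landmark("gonion_left", [1, 0, 0]),
                          Landmark("gonion_right", [-1, 0, 0])])
        with pytest.raises(InsufficientLandmarksError):
            estimate_median_plane(LandmarkSet([lm.entries[0]]))


class TestMirroring:
    def test_mirror_twice_is_identity(self, reference):
        plane = Plane([0.3, 1.0, -2.0], [1.0, 0.2, 0.1])
        once = mirror_mesh(reference.mesh, plane)
        twice = mirror_mesh(once, plane)
        assert np.abs(twice.vertices - reference.mesh.vertices).max() < 1e-9

    def test_point_on_plane_is_fixed(self):
        plane = Plane([2.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        p = np.array([2.0, 5.0, -1.0])
        np.testing.assert_allclose(plane.reflect_points(p), p, atol=1e-12)

    def test_signed_volume_preserved(self, reference):
        plane = Plane([0, 0, 0], [1, 0, 0])
        mirrored = mirror_mesh(reference.mesh, plane)
        assert mirrored.volume == pytest.approx(reference.mesh.volume,
                                                rel=1e-9)

    def test_mirror_landmarks_swaps_sides(self, reference):
        plane = Plane([0, 0, 0], [1, 0, 0])
        mirrored = mirror_landmarks(reference.landmarks, plane)
        orig_left = reference.landmarks["gonion_left"].position
        assert np.allclose(mirrored["gonion_right"].position,
                           orig_left * np.array([-1, 1, 1]))


class TestThinPlateSpline:
    def test_identity_input_gives_identity_transform(self, reference, rng):
        pts = reference.landmarks.positions()
        tps = ThinPlateSpline3D(pts, pts)
        probe = rng.normal(0, 30, (40, 3))
        np.testing.assert_allclose(tps(probe), probe, atol=1e-9)
        np.testing.assert_allclose(tps.affine[:, :3], np.eye(3), atol=1e-9)

    def test_interpolation_exactness(self, reference, rng):
        src = reference.landmarks.positions()
        tgt = src + rng.normal(0, 3, src.shape)
        tps = ThinPlateSpline3D(src, tgt)
        assert np.abs(tps(src) - tgt).max() < 1e-6

    def test_matches_scipy_rbf_thin_plate(self, reference, rng):
        # independent oracle: scipy's RBF interpolator with the |r| kernel
        # and a full linear polynomial tail is the same spline family
        src = reference.landmarks.positions()
        tgt = src + rng.normal(0, 4, src.shape)
        mine = ThinPlateSpline3D(src, tgt)
        oracle = RBFInterpolator(src, tgt, kernel="linear", degree=1,
                                 smoothing=0.0)
        probe = rng.normal(0, 40, (60, 3))
        assert np.abs(mine(probe) - oracle(probe)).max() < 1e-8

    def test_coplanar_controls_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                        [2, 1, 0], [1, 2, 0]], float)
        with pytest.raises(DegenerateGeometryError, match="coplanar"):
            ThinPlateSpline3D(src, src + 1.0)


class TestRegisterReference:
    def test_identity_case(self, reference):
        warped, tps = register_reference(reference, reference.landmarks)
        assert np.abs(warped.midline.points
                      - reference.midline.points).max() < 1e-9
        res = np.abs(warped.landmarks.positions()
                     - reference.landmarks.positions()).max()
        assert res < 1e-6

    def test_similarity_transform_oracle(self, reference):
        R = Rotation.from_euler("zyx", [15, -25, 40], degrees=True).as_matrix()
        s, t = 1.1, np.array([12.0, -4.0, 7.0])
        patient = LandmarkSet([Landmark(e.name, s * R @ e.position + t)
                               for e in reference.landmarks])
        warped, _ = register_reference(reference, patient)
        oracle = s * (R @ reference.midline.points.T).T + t
        rms = np.sqrt(np.mean(np.sum((warped.midline.points - oracle) ** 2,
                                     axis=1)))
        assert rms < 0.01

    def test_five_pairs_rejected_six_accepted(self, reference):
        entries = [Landmark(e.name, e.position.copy())
                   for e in reference.landmarks]
        five = LandmarkSet([
            Landmark(e.name, e.position, skipped=(i >= 5))
            for i, e in enumerate(entries)])
        with pytest.raises(InsufficientLandmarksError, match="5"):
            register_reference(reference, five)
        six = LandmarkSet([
            Landmark(e.name, e.position, skipped=(i >= 6))
            for i, e in enumerate(entries)])
        warped, _ = register_reference(reference, six)
        assert warped is not None

    def test_unknown_landmark_name_rejected(self, reference):
        bad = LandmarkSet([Landmark("nose_tip", [0, 0, 0])]
                          + [Landmark(e.name, e.position)
                             for e in reference.landmarks])
        with pytest.raises(LandmarkError, match="nose_tip"):
            register_reference(reference, bad)

    def test_skipped_landmarks_excluded_from_controls(self, reference):
        # corrupt one landmark but skip it: registration must ignore it
        entries = []
        for e in reference.landmarks:
            if e.name == "pogonion":
                entries.append(Landmark(e.name, e.position + 50.0, skipped=True))
            else:
                entries.append(Landmark(e.name, e.position.copy()))
        warped, tps = register_reference(reference, LandmarkSet(entries))
        assert np.abs(warped.midline.points
                      - reference.midline.points).max() < 1e-9

    def test_rigid_equivariance(self, reference):
        # rigidly moving the patient rigidly moves the warped output
        R = Rotation.from_euler("xyz", [5, 10, -8], degrees=True).as_matrix()
        t = np.array([3.0, -2.0, 6.0])
        patient = generate_mandible(MandibleSpec(body_arc_radius=33, seed=9))
        warped_a, _ = register_reference(reference, patient.landmarks)
        moved = LandmarkSet([Landmark(e.name, R @ e.position + t)
                             for e in patient.landmarks])
        warped_b, _ = register_reference(reference, moved)
        oracle = (R @ warped_a.midline.points.T).T + t
        assert np.abs(warped_b.midline.points - oracle).max() < 1e-6


class TestQualityAndPersistence:
    def test_quality_identity_is_zero(self, reference):
        warped, _ = register_reference(reference, reference.landmarks)
        q = registration_quality(warped, reference.landmarks, reference.mesh)
        assert q["max_landmark_residual_mm"] < 1e-6
        assert q["surface_distance_mean_mm"] < 0.2

    def test_quality_on_warped_synthetic_case(self, reference):
        patient = generate_mandible(MandibleSpec(body_arc_radius=33,
                                                 body_height=27, seed=3))
        warped, _ = register_reference(reference, patient.landmarks)
        q = registration_quality(warped, patient.landmarks, patient.mesh)
        assert q["max_landmark_residual_mm"] < 1e-6
        assert q["surface_distance_mean_mm"] < 2.0

    def test_reference_save_load_round_trip(self, reference, tmp_path):
        save_reference(reference, tmp_path / "ref.json")
        back = load_reference(tmp_path / "ref.json")
        assert back.landmarks.names == reference.landmarks.names
        np.testing.assert_allclose(back.zone_boundaries,
                                   reference.zone_boundaries, atol=1e-9)
        np.testing.assert_allclose(back.midline.points,
                                   reference.midline.points, atol=1e-9)
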