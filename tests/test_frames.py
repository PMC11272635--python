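"""Coordinate-frame construction, equivariance, and pelvic tilt."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hipimpinge as hi
from hipimpinge.model import BoneMesh


def _toy_pelvis():
    import trimesh

    mesh = trimesh.creation.icosphere(2, 30.0)
    lm = {
        "ASIS_left": np.array([50.0, 120.0, 80.0]),
        "ASIS_right": np.array([50.0, -120.0, 80.0]),
        "acetabular_center": np.zeros(3),
    }
    return BoneMesh(mesh, lm)


class TestFPP:
    def test_canonical_pose_gives_identity_axes(self):
        f = hi.define_fpp(_toy_pelvis())
        assert np.allclose(f.axes, np.eye(3), atol=1e-12)
        assert np.allclose(f.origin, [50.0, 0.0, 80.0])

    def test_orthonormal_right_handed(self, mean_hip):
        A = mean_hip.fpp.axes
        assert np.linalg.norm(A.T @ A - np.eye(3)) < 1e-9
        assert np.linalg.det(A) > 0.999

    def test_equivariance_under_rotation(self):
        """Rotating the pelvis rotates the frame axes identically
        (cranial reference is re-projected, so rotate about Z)."""
        pelvis = _toy_pelvis()
        R = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        f0 = hi.define_fpp(pelvis)
        f1 = hi.define_fpp(pelvis.transformed(R, np.zeros(3)))
        assert np.allclose(f1.axes, R @ f0.axes, atol=1e-10)

    def test_anterior_axis_points_toward_aiis(self, mean_hip):
        d = (mean_hip.pelvis.landmarks["AIIS_apex"]
             - mean_hip.pelvis.landmarks["acetabular_center"])
        assert float(mean_hip.fpp.anterior @ d) > 0.0

    def test_anterior_pelvic_plane_variant(self):
        """The APP option (ASIS + pubic tubercles) yields a valid frame
        whose anterior axis is the ASIS/pubis plane normal."""
        p = _toy_pelvis()
        p.landmarks["pubic_tubercle_mid"] = np.array([45.0, 0.0, -20.0])
        f = hi.define_fpp(p, variant="app")
        assert np.linalg.norm(f.axes.T @ f.axes - np.eye(3)) < 1e-9
        assert f.anterior[0] > 0.9  # near +X for this nearly vertical plane

    def test_degenerate_landmarks_raise(self):
        p = _toy_pelvis()
        p.landmarks["ASIS_left"] = p.landmarks["ASIS_right"]
        with pytest.raises(ValueError, match="ASIS"):
            hi.define_fpp(p)

    def test_z_parallel_to_asis_line_raises(self):
        p = _toy_pelvis()
        p.landmarks["ASIS_left"] = np.array([0.0, 0.0, 120.0])
        p.landmarks["ASIS_right"] = np.array([0.0, 0.0, -120.0])
        with pytest.raises(ValueError, match="parallel"):
            hi.define_fpp(p)


class TestFemoralFrame:
    def test_canonical_straight_femur(self):
        import trimesh

        lm = {
            "head_center": np.zeros(3),
            "knee_center": np.array([0.0, 0.0, -400.0]),
            "medial_epicondyle": np.array([0.0, 45.0, -400.0]),
            "lateral_epicondyle": np.array([0.0, -45.0, -400.0]),
        }
        femur = BoneMesh(trimesh.creation.icosphere(1, 24.0), lm)
        f = hi.define_femoral_frame(femur, side="right")
        assert np.allclose(f.axes, np.eye(3), atol=1e-12)
        assert np.allclose(f.origin, lm["head_center"])

    def test_equivariance(self, mean_hip):
        R = Rotation.from_rotvec([0.2, -0.4, 0.31]).as_matrix()
        t = np.array([5.0, -2.0, 11.0])
        f0 = mean_hip.femoral_frame
        f1 = hi.define_femoral_frame(mean_hip.femur.transformed(R, t), side="right")
        assert np.allclose(f1.axes, R @ f0.axes, atol=1e-9)
        assert np.allclose(f1.origin, R @ f0.origin + t, atol=1e-9)

    def test_version_visible_between_frames(self, mean_hip):
        """The neck axis leads the pelvic lateral axis by the femoral
        version in the transverse plane."""
        head = mean_hip.femur.landmarks["head_center"]
        neck = head - mean_hip.femur.landmarks["neck_base"]
        ant = mean_hip.fpp.anterior
        med = mean_hip.fpp.lateral  # right hip: medial = leftward axis
        v = np.degrees(np.arctan2(neck @ ant, neck @ med))
        assert abs(v - mean_hip.params.femoral_version) < 0.5

    def test_coincident_centers_raise(self):
        import trimesh

        lm = {
            "head_center": np.zeros(3),
            "knee_center": np.zeros(3),
            "medial_epicondyle": np.array([0.0, 45.0, -400.0]),
            "lateral_epicondyle": np.array([0.0, -45.0, -400.0]),
        }
        femur = BoneMesh(trimesh.creation.icosphere(1, 24.0), lm)
        with pytest.raises(ValueError, match="knee"):
            hi.define_femoral_frame(femur)


class TestPelvicTilt:
    def test_zero_tilt_is_identity(self, mean_hip):
        out = hi.apply_pelvic_tilt(mean_hip, 0.0)
        assert np.array_equal(out.pelvis.vertices, mean_hip.pelvis.vertices)

    def test_inverse_composition(self, mean_hip):
        out = hi.apply_pelvic_tilt(hi.apply_pelvic_tilt(mean_hip, 10.0), -10.0)
        assert np.abs(out.pelvis.vertices - mean_hip.pelvis.vertices).max() < 1e-9

    def test_posterior_sign_convention(self, mean_hip):
        """+10 deg moves the ASIS posteriorly while the rotation center
        stays fixed."""
        tilted = hi.apply_pelvic_tilt(mean_hip, 10.0)
        a0 = mean_hip.pelvis.landmarks["ASIS_right"] @ mean_hip.fpp.anterior
        a1 = tilted.pelvis.landmarks["ASIS_right"] @ mean_hip.fpp.anterior
        assert a1 < a0
        assert np.allclose(
            np.linalg.norm(tilted.pelvis.vertices - mean_hip.rotation_center, axis=1),
            np.linalg.norm(mean_hip.pelvis.vertices - mean_hip.rotation_center, axis=1),
            atol=1e-9,
        )

    def test_rigid_distance_preservation(self, mean_hip):
        tilted = hi.apply_pelvic_tilt(mean_hip, -10.0)
        v0 = mean_hip.pelvis.vertices[:200]
        v1 = tilted.pelvis.vertices[:200]
        d0 = np.linalg.norm(v0[:, None] - v0[None, :], axis=2)
        d1 = np.linalg.norm(v1[:, None] - v1[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_original_untouched(self, mean_hip):
        before = mean_hip.pelvis.vertices.copy()
        hi.apply_pelvic_tilt(mean_hip, 10.0)
        assert np.array_equal(before, mean_hip.pelvis.vertices)

    def test_tilt_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hi.PelvicPose(45.0)
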