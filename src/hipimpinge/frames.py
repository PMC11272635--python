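"""Anatomical coordinate frames and pelvic tilt.

The functional pelvic plane (FPP) is spanned by the bilateral ASIS line
and the scanner's longitudinal (+Z) axis: lateral = unit(ASIS_left -
ASIS_right), cranial = +Z orthogonalized against it, anterior completes
the right-handed triad.  The classic anterior pelvic plane (ASIS + pubic
tubercles) is available as an option for user meshes that carry pubic
landmarks, but the FPP is the default reference throughout.

Pelvic tilt is a pure rotation about the FPP lateral axis through the hip
rotation center, so tilting changes only the pelvis-femur orientation,
never the joint center.  Sign convention: **+tilt = posterior** (ASIS
move posteriorly), negative = anterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import BoneMesh, Frame, HipModel


@dataclass(frozen=True)
class PelvicPose:
    """Sagittal pelvic tilt in degrees; + = posterior, - = anterior."""

    tilt_deg: float = 0.0

    def __post_init__(self):
        if not (-30.0 <= self.tilt_deg <= 30.0):
            raise ValueError(f"tilt_deg {self.tilt_deg} outside [-30, 30]")


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis)).as_matrix()


def define_fpp(pelvis: BoneMesh, variant: str = "fpp") -> Frame:
    """Functional pelvic plane frame from the bilateral ASIS landmarks.

    ``variant="app"`` instead builds the anterior pelvic plane (requires a
    ``pubic_tubercle_mid`` landmark): anterior is the normal of the
    ASIS/pubis plane.
    """
    pelvis.require(["ASIS_left", "ASIS_right"])
    l = pelvis.landmarks["ASIS_left"]
    r = pelvis.landmarks["ASIS_right"]
    lat = l - r
    n = np.linalg.norm(lat)
    if n < 1e-6:
        raise ValueError("ASIS landmarks coincide: cannot define the pelvic plane")
    lat = lat / n
    origin = 0.5 * (l + r)
    if variant == "fpp":
        z = np.array([0.0, 0.0, 1.0])
        cran = z - (z @ lat) * lat
        cn = np.linalg.norm(cran)
        if cn < 1e-6:
            raise ValueError("scanner Z axis is parallel to the ASIS line")
        cran /= cn
    elif variant == "app":
        pelvis.require(["pubic_tubercle_mid"])
        p = pelvis.landmarks["pubic_tubercle_mid"]
        ant = np.cross(lat, p - origin)
        ant /= np.linalg.norm(ant)
        if ant[0] < 0:
            ant = -ant
        cran = np.cross(ant, lat)
        return Frame(origin, np.column_stack([ant, lat, cran]))
    else:
        raise ValueError(f"unknown pelvic plane variant {variant!r}")
    ant = np.cross(lat, cran)
    return Frame(origin, np.column_stack([ant, lat, cran]))


def define_femoral_frame(femur: BoneMesh, side: str = "right") -> Frame:
    """Femoral frame: origin at the head center, long axis head -> knee,
    flexion-reference axis from the epicondylar line orthogonalized
    against the long axis (pointing toward the patient's left)."""
    femur.require(["head_center", "knee_center", "medial_epicondyle", "lateral_epicondyle"])
    head = femur.landmarks["head_center"]
    knee = femur.landmarks["knee_center"]
    up = head - knee
    n = np.linalg.norm(up)
    if n < 1e-6:
        raise ValueError("head center coincides with knee center")
    up = up / n
    epi = femur.landmarks["medial_epicondyle"] - femur.landmarks["lateral_epicondyle"]
    if side == "right":
        leftward = epi  # medial = patient-left for a right femur
    else:
        leftward = -epi
    leftward = leftward - (leftward @ up) * up
    ln = np.linalg.norm(leftward)
    if ln < 1e-6:
        raise ValueError("epicondylar line is parallel to the femoral long axis")
    leftward /= ln
    ant = np.cross(leftward, up)
    return Frame(head, np.column_stack([ant, leftward, up]))


def apply_pelvic_tilt(model: HipModel, pose: PelvicPose | float) -> HipModel:
    """Return a copy of ``model`` with the pelvis tilted about the FPP
    lateral axis through the hip rotation center (+ = posterior).

    The femur is untouched; pelvis landmarks, rim samples, the FPP frame
    and the stored acetabular pole rotate rigidly with the bone.
    """
    if not isinstance(pose, PelvicPose):
        pose = PelvicPose(float(pose))
    # + tilt (posterior) moves the ASIS posteriorly: rotate by -tilt about
    # the leftward lateral axis
    R = rotation_about(model.fpp.lateral, -pose.tilt_deg)
    c = model.rotation_center
    t = c - R @ c
    pelvis = model.pelvis.transformed(R, t)
    extras = dict(model.extras)
    if "pole" in extras:
        extras["pole"] = R @ extras["pole"]
    return model.replace(
        pelvis=pelvis,
        fpp=model.fpp.transformed(R, t),
        tilt_deg=model.tilt_deg + pose.tilt_deg,
        extras=extras,
    )
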