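"""Acetabular contact-region classification (A = AIIS/subspine,
B = anterior, C = posterolateral).

Contacts are classified by their angular position in the sagittal
projection about the acetabular center (the lateral-view construction):
region A is the wedge between the ray through the ASIS-AIIS inflection
and the ray through the AIIS-rim inflection; B is the arc anterior /
inferior to that wedge down to the most caudal rim point; C is the
remaining posterolateral arc.  Wedge boundaries belong to A; the B/C cut
at the caudal rim belongs to B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import BoneMesh, Frame

_BOUNDARY_TOL_DEG = math.degrees(1e-6)


@dataclass
class RegionSectors:
    center: np.ndarray
    anterior: np.ndarray
    cranial: np.ndarray
    lateral: np.ndarray  # sagittal-plane normal
    theta_rim_inflection: float  # anterior-inferior boundary of wedge A (deg)
    theta_asis_inflection: float  # cranial boundary of wedge A (deg)
    theta_caudal_cut: float  # B/C split at the caudal rim extreme (deg)

    def angle_of(self, point: np.ndarray) -> float:
        """Sagittal-projection angle (deg): 0 = anterior, +90 = cranial."""
        rel = np.asarray(point, dtype=float) - self.center
        u = rel @ self.anterior
        v = rel @ self.cranial
        if math.hypot(u, v) < 1e-9:
            raise ValueError("point projects onto the acetabular center")
        return math.degrees(math.atan2(v, u))


def build_sectors(pelvis: BoneMesh, frame: Frame, side: str = "right") -> RegionSectors:
    """Build the A/B/C sector construction from pelvis landmarks.

    ``frame`` supplies the sagittal direction (its lateral axis) and the
    in-plane anterior/cranial axes; pass the tilted frame for a tilted
    pelvis so the sectors ride with the bone.
    """
    pelvis.require(["acetabular_center", "AIIS_apex", "inflection_ASIS_AIIS",
                    "inflection_AIIS_rim"])
    c = pelvis.landmarks["acetabular_center"]
    sectors = RegionSectors(
        center=c,
        anterior=frame.anterior,
        cranial=frame.cranial,
        lateral=frame.lateral,
        theta_rim_inflection=0.0,
        theta_asis_inflection=0.0,
        theta_caudal_cut=-90.0,
    )
    t1 = sectors.angle_of(pelvis.landmarks["inflection_AIIS_rim"])
    t2 = sectors.angle_of(pelvis.landmarks["inflection_ASIS_AIIS"])
    if t2 < t1:
        t1, t2 = t2, t1
    sectors.theta_rim_inflection = t1
    sectors.theta_asis_inflection = t2
    apex = sectors.angle_of(pelvis.landmarks["AIIS_apex"])
    if not (t1 - _BOUNDARY_TOL_DEG <= apex <= t2 + _BOUNDARY_TOL_DEG):
        raise ValueError(
            f"landmark inconsistency: AIIS apex at {apex:.1f} deg lies outside "
            f"the inflection wedge [{t1:.1f}, {t2:.1f}] deg"
        )
    if pelvis.rim_samples is not None and len(pelvis.rim_samples):
        rel = pelvis.rim_samples - c
        caudal_idx = int(np.argmin(rel @ frame.cranial))
        sectors.theta_caudal_cut = sectors.angle_of(pelvis.rim_samples[caudal_idx])
    return sectors


def classify_contact(point: np.ndarray, sectors: RegionSectors) -> str:
    """Map a pelvic contact point to region "A", "B" or "C"."""
    theta = sectors.angle_of(point)
    t1, t2 = sectors.theta_rim_inflection, sectors.theta_asis_inflection
    if t1 - _BOUNDARY_TOL_DEG <= theta <= t2 + _BOUNDARY_TOL_DEG:
        return "A"
    if sectors.theta_caudal_cut <= theta < t1:
        return "B"
    return "C"
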