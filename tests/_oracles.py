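"""Independent test oracles: analytic voxel-overlap collision checks and
closed-form limiting-angle solutions.

These deliberately avoid the package's mesh/BVH code path: overlap is
decided on a 0.5 mm voxel grid using the *analytic* implicit solids the
synthetic bones were built from, and limiting angles come from closed
forms, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np

VOXEL_PITCH = 0.5
AMBIGUITY_BAND = 0.5  # |separation| below this is not compared


class VoxelOverlapOracle:
    """Voxel-overlap verdicts for a synthetic hip at arbitrary femur poses.

    The pelvis field is sampled once on a 0.5 mm grid; each pose then
    evaluates the femur's field only at near-pelvis voxels.  The designed
    articular gap (a ~1 mm clearance annulus inside the socket) is
    excluded from the domain: it sits permanently inside the ambiguity
    band and is joint congruence, not impingement.

    ``separation(R)`` returns min over voxels of max(f_pelvis, f_femur):
    negative = penetration depth, positive = clearance (capped at the
    band edge).
    """

    def __init__(self, model):
        self.pelvis_solid = model.extras["pelvis_solid"]
        self.femur_solid = model.extras["femur_solid"]
        if self.pelvis_solid is None or self.femur_solid is None:
            raise ValueError("analytic solids unavailable (mirrored model?)")
        self.center = model.rotation_center
        c_acet = model.pelvis.landmarks["acetabular_center"]
        r_acet = model.extras["r_acet"]

        lo, hi = model.pelvis.mesh.bounds
        lo = lo - 1.0
        hi = hi + 1.0
        axes = [np.arange(lo[k], hi[k] + VOXEL_PITCH, VOXEL_PITCH) for k in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        keep = np.linalg.norm(grid - c_acet, axis=1) > r_acet - 0.25
        grid = grid[keep]
        fp = np.empty(len(grid))
        for i in range(0, len(grid), 500_000):
            fp[i : i + 500_000] = self.pelvis_solid.sdf(grid[i : i + 500_000])
        near = fp < AMBIGUITY_BAND
        self.points = grid[near]
        self.fp = fp[near]

    def separation(self, rotation: np.ndarray) -> float:
        """Signed separation at femur pose p -> R (p - c) + c."""
        R = np.asarray(rotation, dtype=float)
        # pull grid points back into the femur's neutral frame
        local = (self.points - self.center) @ R + self.center
        ff = self.femur_solid.sdf(local)
        return float(np.minimum(np.maximum(self.fp, ff), AMBIGUITY_BAND).min())


def capsule_plane_limit_angle(length: float, radius: float, wall_x: float) -> float:
    """Closed-form first-contact angle (deg) for a capsule swinging
    toward the plane x = wall_x.

    The capsule runs from the fixed origin to ``length`` along direction
    (sin t, 0, -cos t); its farthest reach toward the wall is
    length*sin(t) + radius, so contact occurs at
    t* = asin((wall_x - radius) / length).
    """
    s = (wall_x - radius) / length
    if not (0.0 < s < 1.0):
        raise ValueError("wall not reachable within a quarter sweep")
    return math.degrees(math.asin(s))


def euler_sequence_matrix(lat, ant, long_axis, flex, add, ir, side_sign=1.0):
    """Independent closed-form of the clinical rotation sequence used by
    the ROM engine (axis-angle products via Rodrigues terms)."""

    def rodrigues(axis, deg):
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        a = math.radians(deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)

    R1 = rodrigues(lat, -flex)
    R2 = rodrigues(R1 @ np.asarray(ant, float), side_sign * add)
    R3 = rodrigues(R2 @ R1 @ np.asarray(long_axis, float), side_sign * ir)
    return R3 @ R2 @ R1
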