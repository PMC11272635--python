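"""Range-of-motion engine: femur posing, limiting-angle search, protocol.

Posture convention (clinical Euler sequence): flexion about the (tilted)
pelvic medio-lateral axis, then adduction about the floating
anteroposterior axis, then internal rotation about the femoral long
axis, all about the hip rotation center.  The swept variable is marched
in 1-degree steps from the start posture and the first collision is
refined by bisection to 0.1 degree.

The 12-condition daily-activity protocol: maximum flexion (threshold
130 deg) at 0/10/20 deg adduction, and maximum internal rotation
(threshold 30 deg) at 90/70/45 deg flexion x 0/10/20 deg adduction.
A condition "impinges" when bone contact occurs below its threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collision import CollisionResult, MeshCollider
from .frames import PelvicPose, apply_pelvic_tilt, rotation_about
from .model import BoneMesh, HipModel

#: radius (mm) around the head center keeping femur triangles that can
#: plausibly reach the pelvis within the protocol's posture range
PROXIMAL_RADIUS = 80.0


@dataclass(frozen=True)
class HipPosture:
    flexion: float = 0.0
    adduction: float = 0.0
    internal_rotation: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.flexion <= 150.0):
            raise ValueError(f"flexion {self.flexion} outside [0, 150]")
        if not (-30.0 <= self.adduction <= 30.0):
            raise ValueError(f"adduction {self.adduction} outside [-30, 30]")
        if not (-60.0 <= self.internal_rotation <= 60.0):
            raise ValueError(f"internal_rotation {self.internal_rotation} outside [-60, 60]")


@dataclass(frozen=True)
class ProtocolCondition:
    id: int
    mode: str  # "max_flexion" | "max_internal_rotation"
    fixed_flexion: float
    fixed_adduction: float
    threshold: float

    def start_posture(self) -> HipPosture:
        if self.mode == "max_flexion":
            return HipPosture(0.0, self.fixed_adduction, 0.0)
        return HipPosture(self.fixed_flexion, self.fixed_adduction, 0.0)

    def posture_at(self, angle: float) -> HipPosture:
        if self.mode == "max_flexion":
            return HipPosture(angle, self.fixed_adduction, 0.0)
        return HipPosture(self.fixed_flexion, self.fixed_adduction, angle)


def default_protocol() -> list[ProtocolCondition]:
    """The 12 activities-of-daily-living conditions, in fixed order."""
    conds = [
        ProtocolCondition(i + 1, "max_flexion", 0.0, add, 130.0)
        for i, add in enumerate((0.0, 10.0, 20.0))
    ]
    i = 4
    for flex in (90.0, 70.0, 45.0):
        for add in (0.0, 10.0, 20.0):
            conds.append(ProtocolCondition(i, "max_internal_rotation", flex, add, 30.0))
            i += 1
    return conds


@dataclass
class ContactResult:
    limiting_angle: float
    impinged_within_threshold: bool
    contact_point: np.ndarray | None = None
    baseline_collision: bool = False
    patches: int = 0


@dataclass
class ImpingementRecord:
    patient_id: str | None
    tilt_deg: float
    condition_id: int
    mode: str
    threshold: float
    limiting_angle: float
    impinged: bool
    region: str | None
    contact_point: np.ndarray | None = None
    baseline_collision: bool = False


def posture_rotation(model: HipModel, posture: HipPosture) -> np.ndarray:
    """Rotation matrix taking the neutral femur to ``posture``.

    Flexion: about the pelvic lateral (leftward) axis, negative-sense so
    positive flexion carries the knee anteriorly.  Adduction: about the
    flexed anterior axis, toward the midline.  Internal rotation: about
    the femoral long axis, anterior knee turning medially.
    """
    sign = 1.0 if model.side == "right" else -1.0
    lat = model.fpp.lateral
    ant = model.fpp.anterior
    long_axis = model.femoral_frame.cranial
    R1 = rotation_about(lat, -posture.flexion)
    R2 = rotation_about(R1 @ ant, sign * posture.adduction)
    R21 = R2 @ R1
    R3 = rotation_about(R21 @ long_axis, sign * posture.internal_rotation)
    return R3 @ R21


def pose_femur(model: HipModel, posture: HipPosture) -> BoneMesh:
    """Return the femur rigidly posed at ``posture`` (head center fixed)."""
    R = posture_rotation(model, posture)
    c = model.rotation_center
    return model.femur.transformed(R, c - R @ c)


def sweep_limiting_angle(collides, cap: float, coarse: float = 1.0, tol: float = 0.1):
    """March ``collides(angle)`` from 0 in ``coarse`` steps up to ``cap``,
    then bisect the first colliding bracket to ``tol``.

    Returns ``(limiting_angle, first_hit_result, baseline)``:
    the largest collision-free angle found (== cap when nothing collides),
    the CollisionResult at the first colliding bisection bound (None when
    free), and whether the start posture already collided.
    """
    if cap <= 0.0:
        return 0.0, None, False
    res0 = collides(0.0)
    if res0.hit:
        return 0.0, res0, True
    lo, hit_res, hi = 0.0, None, None
    a = coarse
    while a < cap + 1e-9:
        res = collides(min(a, cap))
        if res.hit:
            hi, hit_res = min(a, cap), res
            break
        lo = min(a, cap)
        a += coarse
    if hi is None:
        return cap, None, False
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        res = collides(mid)
        if res.hit:
            hi, hit_res = mid, res
        else:
            lo = mid
    return lo, hit_res, False


@dataclass
class ProtocolRunner:
    """Caches per-(model, tilt) collision structures for the 12 conditions."""

    model: HipModel  # already tilted
    collider: MeshCollider = field(init=False)
    _tris_rel: np.ndarray = field(init=False)

    _max_tri_radius: float = field(init=False)

    def __post_init__(self):
        c = self.model.rotation_center
        keep = None
        if self.model.cup_face_mask is not None:
            keep = ~self.model.cup_face_mask
        # pelvis triangles beyond the femur subset's rotational reach can
        # never collide
        pel_tris = self.model.pelvis.mesh.triangles
        pel_r = np.linalg.norm(pel_tris - c, axis=2)
        reachable = pel_r.min(axis=1) < PROXIMAL_RADIUS + 2.0
        keep = reachable if keep is None else (keep & reachable)
        self.collider = MeshCollider.from_mesh(self.model.pelvis.mesh, keep)

        # femur triangles rotate rigidly about the head center, so their
        # radial band is invariant: drop triangles whose whole band lies
        # below the closest pelvis material (e.g. most of the head sphere)
        tris = self.model.femur.mesh.triangles
        fem_r = np.linalg.norm(tris - c, axis=2)
        pelvis_min_r = float(np.linalg.norm(self.collider.triangles - c, axis=2).min())
        near = (fem_r.mean(axis=1) < PROXIMAL_RADIUS) & (fem_r.max(axis=1) > pelvis_min_r - 1.0)
        self._tris_rel = tris[near] - c
        cent = self._tris_rel.mean(axis=1)
        self._max_tri_radius = float(
            np.linalg.norm(self._tris_rel - cent[:, None, :], axis=2).max()
        )
        # bucket femur triangles into ~10 mm clusters: per query only the
        # clusters within reach of the pelvis go to the triangle broad phase
        cell = np.floor(cent / 10.0).astype(int)
        _, labels = np.unique(cell, axis=0, return_inverse=True)
        order = np.argsort(labels)
        self._cluster_slices = []
        self._cluster_members = order
        bounds = np.searchsorted(labels[order], np.arange(labels.max() + 2))
        centers, radii = [], []
        for kk in range(labels.max() + 1):
            idx = order[bounds[kk]:bounds[kk + 1]]
            pts = self._tris_rel[idx].reshape(-1, 3)
            ctr = pts.mean(axis=0)
            centers.append(ctr)
            radii.append(np.linalg.norm(pts - ctr, axis=1).max())
            self._cluster_slices.append(idx)
        self._cluster_centers = np.asarray(centers)
        self._cluster_radii = np.asarray(radii)

    def _collides(self, posture: HipPosture) -> CollisionResult:
        R = posture_rotation(self.model, posture)
        c = self.model.rotation_center
        moved_centers = self._cluster_centers @ R.T + c
        bound = self._cluster_radii.max() + self.collider.max_radius + 1e-6
        d, _ = self.collider.tree.query(moved_centers, k=1, distance_upper_bound=bound)
        active = d <= self._cluster_radii + self.collider.max_radius + 1e-6
        if not active.any():
            return CollisionResult(False, np.zeros((0, 2, 3)), np.zeros(0, dtype=int))
        idx = np.concatenate([self._cluster_slices[kk] for kk in np.where(active)[0]])
        moved = self._tris_rel[idx] @ R.T + c
        return self.collider.query(moved, self._max_tri_radius)

    def search(self, condition: ProtocolCondition) -> ContactResult:
        fn = lambda a: self._collides(condition.posture_at(a))
        limiting, res, baseline = sweep_limiting_angle(fn, condition.threshold)
        if res is None:
            return ContactResult(limiting, False)
        cr = ContactResult(
            limiting,
            limiting < condition.threshold,
            contact_point=res.contact_point,
            baseline_collision=baseline,
        )
        cr.patches = res.patches
        return cr


def max_angle_search(
    model: HipModel, condition: ProtocolCondition, pose: PelvicPose | float = 0.0
) -> ContactResult:
    """Limiting angle of one protocol condition at a given pelvic tilt."""
    tilted = apply_pelvic_tilt(model, pose)
    return ProtocolRunner(tilted).search(condition)


def run_protocol(
    model: HipModel,
    pose: PelvicPose | float = 0.0,
    protocol: list[ProtocolCondition] | None = None,
) -> list[ImpingementRecord]:
    """Run the 12-condition protocol at one pelvic tilt.

    Contact points of impinging conditions are classified into regions
    A (AIIS/subspine), B (anterior) or C (posterolateral).
    """
    from .regions import build_sectors, classify_contact

    pose = pose if isinstance(pose, PelvicPose) else PelvicPose(float(pose))
    tilted = apply_pelvic_tilt(model, pose)
    runner = ProtocolRunner(tilted)
    sectors = build_sectors(tilted.pelvis, tilted.fpp, side=tilted.side)
    records = []
    for cond in protocol if protocol is not None else default_protocol():
        cr = runner.search(cond)
        region = None
        if cr.impinged_within_threshold and cr.contact_point is not None:
            region = classify_contact(cr.contact_point, sectors)
        records.append(
            ImpingementRecord(
                patient_id=model.patient_id,
                tilt_deg=pose.tilt_deg,
                condition_id=cond.id,
                mode=cond.mode,
                threshold=cond.threshold,
                limiting_angle=cr.limiting_angle,
                impinged=cr.impinged_within_threshold,
                region=region,
                contact_point=cr.contact_point,
                baseline_collision=cr.baseline_collision,
            )
        )
    return records
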