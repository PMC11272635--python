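"""Parametric hip anatomy: constructive bone generator and measurements.

No patient geometry ships with this package; hips are built
constructively so that every clinically named shape parameter maps to one
geometric control:

* femur = head sphere + neck capsule + shaft/condyle capsules, with a cam
  deformity modeled as a spherical thickening centered on the neck axis
  whose crossing ring with the (tolerance-inflated) head sphere sits at
  the requested alpha angle;
* hemipelvis = acetabular cup shell (hemispherical socket of radius
  head_radius + 1 mm cartilage-free clearance, truncated at the coverage
  angle solved from the requested LCEA) + an AIIS prominence whose
  inferior extent relative to the rim plane encodes the Hetsroni type +
  iliac columns carrying the ASIS.

Meshes are extracted by marching cubes (default pitch 1.5 mm, matching a
typical CT slice thickness) and are watertight by construction.  The
measurement functions recompute alpha angle, LCEA and both versions from
the output mesh/landmarks, closing the generate -> measure loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .implicit import Capsule, CupShell, Sphere, Union, mesh_from_solid, solid_bounds
from .model import BoneMesh, FEMUR_LANDMARKS, HipModel, PELVIS_LANDMARKS

log = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# fixed constructive constants (mm / degrees); see docs/methods.md
JOINT_CLEARANCE = 1.0      # cartilage-free gap between head and socket
SHELL_THICKNESS = 5.0      # acetabular shell radial thickness
INCLINATION_DEG = 40.0     # radiographic cup inclination, not a cohort variable
ALPHA_SPHERICAL_MAX = 45.0  # below this the head stays spherical (no cam)
ALPHA_TOL = 1.02           # head-sphere exit tolerance used by alpha measurement
CAM_OFFSET_FRAC = 0.35     # cam sphere center offset along neck axis, x head radius
AIIS_RADIUS = 6.5          # AIIS prominence capsule radius
HALF_PELVIC_WIDTH = 120.0  # hip center to midsagittal plane

#: Hetsroni morphotype -> lowest extent of the AIIS prominence above (+)
#: or below (-) the acetabular rim plane, mm.
AIIS_TYPE_DROP = {"I": +5.0, "II": 0.0, "III": -6.0}

#: Cohort defaults: anatomy of a surgical FAIS population
#: (means/SDs in degrees; AIIS morphotype frequencies).
COHORT_DEFAULTS = {
    "alpha_angle": (67.13, 8.89),
    "lcea": (30.77, 6.55),
    "acetabular_version": (18.63, 6.34),
    "femoral_version": (14.19, 10.84),
}
AIIS_TYPE_PROBS = {"I": 28 / 78, "II": 50 / 78, "III": 0.0}

FEASIBLE = {
    "alpha_angle": (30.0, 100.0),
    "lcea": (0.0, 60.0),
    "acetabular_version": (-5.0, 42.0),
    "femoral_version": (-25.0, 55.0),
}


class GenerationError(ValueError):
    """Raised when a parameter combination yields infeasible geometry."""


@dataclass(frozen=True)
class AnatomyParams:
    """Shape parameters of one hip (angles in degrees, lengths in mm)."""

    alpha_angle: float = 67.13
    lcea: float = 30.77
    acetabular_version: float = 18.63
    femoral_version: float = 14.19
    aiis_type: str = "II"
    head_radius: float = 24.0
    neck_shaft_angle: float = 130.0
    side: str = "right"

    def __post_init__(self):
        if not (30.0 <= self.alpha_angle <= 100.0):
            raise ValueError(f"alpha_angle {self.alpha_angle} outside [30, 100]")
        if not (0.0 <= self.lcea <= 60.0):
            raise ValueError(f"lcea {self.lcea} outside [0, 60]")
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")
        if self.aiis_type not in ("I", "II", "III"):
            raise ValueError(f"aiis_type must be I/II/III, got {self.aiis_type!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")


@dataclass
class CohortSpec:
    """Sampling spec for a synthetic cohort (defaults emulate the study group)."""

    n_patients: int = 78
    distributions: dict = field(default_factory=lambda: dict(COHORT_DEFAULTS))
    aiis_type_probs: dict = field(default_factory=lambda: dict(AIIS_TYPE_PROBS))
    head_radius: float = 24.0
    side: str = "right"
    resolution: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.aiis_type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"aiis_type_probs sum to {total}, expected 1")


# --------------------------------------------------------------------------
# construction helpers (all build the RIGHT side; left hips are mirrored)

def _acetabular_pole(av_deg: float) -> np.ndarray:
    """Unit axis from the acetabular center into the bony dome (right side)."""
    inc = math.radians(INCLINATION_DEG)
    av = math.radians(av_deg)
    # medial = +Y for the right hip; version rotates the pole posteriorly
    return np.array(
        [-math.sin(inc) * math.sin(av), math.sin(inc) * math.cos(av), math.cos(inc)]
    )

def _rim_basis(pole: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.array([0.0, 0.0, 1.0]) - pole[2] * pole
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(pole, e1)

def _rim_directions(pole: np.ndarray, psi: float, phis: np.ndarray) -> np.ndarray:
    e1, e2 = _rim_basis(pole)
    return (
        math.cos(psi) * pole[None, :]
        + math.sin(psi)
        * (np.cos(phis)[:, None] * e1[None, :] + np.sin(phis)[:, None] * e2[None, :])
    )

def _projected_lcea(pole: np.ndarray, psi: float) -> float:
    """Coronal-projection lateral center-edge angle of the rim ring (deg).

    Mirrors the radiographic measurement: project the rim ring onto the
    coronal plane and take the largest angle, at the center, between the
    cranial vertical and a cranial-half rim point, opening laterally
    (lateral = -Y on the right side).
    """
    u = _rim_directions(pole, psi, np.linspace(0.0, 2 * np.pi, 721))
    cranial = u[:, 2] > 0.0
    if not cranial.any():
        return -90.0
    theta = np.degrees(np.arctan2(-u[cranial, 1], u[cranial, 2]))
    return float(theta.max())

def _solve_coverage(av_deg: float, lcea_deg: float) -> tuple[np.ndarray, float]:
    """Solve the cup coverage half-angle psi reproducing the requested LCEA."""
    from scipy.optimize import brentq

    pole = _acetabular_pole(av_deg)
    f = lambda psi: _projected_lcea(pole, psi) - lcea_deg
    # coverage below 15 deg leaves no rim to carry the AIIS construction;
    # beyond 85 deg the socket over-wraps past the equator (protrusio-like)
    # and the rim annulus cuts into the neck/AIIS construction
    lo, hi = math.radians(15.0), math.radians(85.0)
    if f(lo) > 0 or f(hi) < 0:
        raise GenerationError(
            f"lcea={lcea_deg:.1f} with acetabular_version={av_deg:.1f} is "
            "infeasible: the required cup coverage half-angle leaves the "
            "buildable range [15, 85] deg (rim vanishes or self-intersects)"
        )
    psi = brentq(f, lo, hi, xtol=1e-10)
    return pole, float(psi)


def _nearest_azimuth(pole: np.ndarray, psi: float, target: np.ndarray) -> float:
    phis = np.linspace(0.0, 2 * np.pi, 1441)
    u = _rim_directions(pole, psi, phis)
    t = target / np.linalg.norm(target)
    return float(phis[np.argmax(u @ t)])


def _build_pelvis_solids(params: AnatomyParams, r_acet: float):
    """Right-side pelvis primitives, landmarks, and rim samples."""
    c = np.zeros(3)
    pole, psi = _solve_coverage(params.acetabular_version, params.lcea)
    r_outer = r_acet + SHELL_THICKNESS
    r_rim = 0.5 * (r_acet + r_outer)
    cup = CupShell(c, pole, r_acet, r_outer, psi)

    phis = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    rim_samples = c + r_rim * _rim_directions(pole, psi, phis)

    # AIIS prominence anterosuperior to the rim (~1:30 on the right clockface)
    phi_a = _nearest_azimuth(pole, psi, np.array([0.75, 0.0, 0.66]))
    u_a = _rim_directions(pole, psi, np.array([phi_a]))[0]
    e_a = u_a - math.cos(psi) * pole
    e_a /= np.linalg.norm(e_a)
    drop = AIIS_TYPE_DROP[params.aiis_type]
    s_tip = drop + AIIS_RADIUS  # capsule-tip height giving the requested drop
    tip = c + (r_rim * math.cos(psi) + s_tip) * pole + (r_rim * math.sin(psi) + 6.0) * e_a
    base = tip + 16.0 * pole + 3.0 * e_a
    aiis = Capsule(base, tip, AIIS_RADIUS)
    apex_dir = 0.5 * e_a - pole
    apex = tip + AIIS_RADIUS * apex_dir / np.linalg.norm(apex_dir)

    # anterior iliac column up to the ASIS, posterior column for the rim wall
    asis_r = c + np.array([50.0, -8.0, 80.0])
    column = Capsule(base + 2.0 * pole, asis_r, 10.0)
    # start the posterior column far enough above the rim that its surface
    # cannot dip through the shell into the joint space
    phi_p = _nearest_azimuth(pole, psi, np.array([-0.35, 0.0, 0.93]))
    rim_p = c + r_rim * _rim_directions(pole, psi, np.array([phi_p]))[0]
    post_col = Capsule(rim_p + 12.0 * pole, c + np.array([-30.0, 10.0, 60.0]), 9.0)

    # anterior-inferior rim inflection: 35% of the way from the AIIS azimuth
    # toward the most anterior-inferior rim point
    phi_ant = _nearest_azimuth(pole, psi, np.array([0.9, 0.0, -0.44]))
    d = (phi_ant - phi_a + np.pi) % (2 * np.pi) - np.pi
    u_infl = _rim_directions(pole, psi, np.array([phi_a + 0.35 * d]))[0]

    landmarks = {
        "ASIS_right": asis_r,
        "ASIS_left": np.array([asis_r[0], 2 * HALF_PELVIC_WIDTH - asis_r[1], asis_r[2]]),
        "acetabular_center": c,
        "AIIS_apex": apex,
        "inflection_ASIS_AIIS": 0.5 * (base + asis_r),
        "inflection_AIIS_rim": c + (r_rim + 1.0) * u_infl,
    }
    solids = Union(cup, aiis, column, post_col)
    meta = {"pole": pole, "psi": psi, "r_acet": r_acet, "r_rim": r_rim}
    return solids, landmarks, rim_samples, meta


def _neck_geometry(params: AnatomyParams):
    r = params.head_radius
    theta_d = math.radians(params.neck_shaft_angle - 90.0)
    fv = math.radians(params.femoral_version)
    # from head center toward the trochanter: lateral (-Y), inferior,
    # posterior by the anteversion angle
    d_neck = np.array(
        [-math.cos(theta_d) * math.sin(fv), -math.cos(theta_d) * math.cos(fv), -math.sin(theta_d)]
    )
    alpha_sph = min(params.alpha_angle, ALPHA_SPHERICAL_MAX)
    r_neck = ALPHA_TOL * r * math.sin(math.radians(alpha_sph))
    return d_neck, r_neck


def _build_femur_solids(params: AnatomyParams):
    """Right-side femur primitives and landmarks."""
    r = params.head_radius
    head_c = np.zeros(3)
    d_neck, r_neck = _neck_geometry(params)
    neck_len = 2.0 * r
    p_tr = head_c + neck_len * d_neck

    solids = [Sphere(head_c, r), Capsule(head_c, p_tr, r_neck)]
    if params.alpha_angle > ALPHA_SPHERICAL_MAX:
        # cam collar: sphere on the neck axis through the point at polar
        # angle alpha (from the neck axis) and radius ALPHA_TOL * r, so the
        # surface exits the tolerance sphere exactly at the alpha ring
        a = math.radians(params.alpha_angle)
        d_cam = CAM_OFFSET_FRAC * r
        rr = ALPHA_TOL * r
        r_cam = math.sqrt(rr * rr + d_cam * d_cam - 2 * d_cam * rr * math.cos(a))
        solids.append(Sphere(head_c + d_cam * d_neck, r_cam))

    gt_center = p_tr + np.array([0.0, -5.0, 8.0])
    knee_c = np.array([0.0, 0.0, -388.0])
    shaft_top = p_tr + np.array([0.0, 0.0, -6.0])
    shaft_dir = knee_c - shaft_top
    lt_center = shaft_top + 0.12 * shaft_dir + np.array([-9.0, 7.0, 0.0])
    solids += [
        Sphere(gt_center, 15.0),
        Capsule(shaft_top, knee_c + np.array([0.0, 0.0, 6.0]), 13.0),
        Sphere(lt_center, 8.0),
        Capsule(knee_c + np.array([0.0, -30.0, 2.0]), knee_c + np.array([0.0, 30.0, 2.0]), 20.0),
    ]
    landmarks = {
        "head_center": head_c,
        "neck_base": p_tr,
        "knee_center": knee_c,
        "medial_epicondyle": knee_c + np.array([0.0, 50.0, 2.0]),
        "lateral_epicondyle": knee_c + np.array([0.0, -50.0, 2.0]),
        "greater_trochanter_tip": gt_center + np.array([0.0, 0.0, 15.0]),
        "lesser_trochanter": lt_center + 8.0 * np.array([-0.75, 0.6, 0.0]) / math.hypot(0.75, 0.6),
    }
    return Union(*solids), landmarks


def _mirror_bone(bone: BoneMesh) -> BoneMesh:
    """Reflect through the midsagittal plane y = HALF_PELVIC_WIDTH... no:

    Bones are built in hip-centered coordinates; mirroring the hip side is
    a reflection through the local sagittal plane y = 0 (faces reversed to
    keep outward normals).
    """
    m = bone.mesh.copy()
    v = m.vertices.copy()
    v[:, 1] *= -1.0
    m.vertices = v
    m.invert()
    lm = {}
    for k, p in bone.landmarks.items():
        q = p.copy()
        q[1] *= -1.0
        lm[k] = q
    # patient-side-labeled landmarks swap under reflection (bone-relative
    # labels like medial/lateral epicondyle map onto themselves)
    for a, b in (("ASIS_left", "ASIS_right"),):
        if a in lm and b in lm:
            lm[a], lm[b] = lm[b], lm[a]
    rim = None
    if bone.rim_samples is not None:
        rim = bone.rim_samples.copy()
        rim[:, 1] *= -1.0
    return BoneMesh(m, lm, rim)


def generate_hip(params: AnatomyParams, resolution: float = 1.5) -> HipModel:
    """Generate one landmarked hip model.

    The returned model's re-measured alpha angle, LCEA and versions agree
    with ``params`` to within ~2 degrees (see the measurement functions).

    Raises
    ------
    GenerationError
        If the parameter combination is geometrically infeasible; the
        message names the violated constraint.
    """
    from . import frames as _frames

    r_acet = params.head_radius + JOINT_CLEARANCE
    pel_solid, pel_lm, rim, meta = _build_pelvis_solids(params, r_acet)
    fem_solid, fem_lm = _build_femur_solids(params)

    pel_mesh = mesh_from_solid(pel_solid, solid_bounds([pel_solid]), resolution)
    fem_mesh = mesh_from_solid(fem_solid, solid_bounds([fem_solid]), resolution)
    for name, m in (("pelvis", pel_mesh), ("femur", fem_mesh)):
        if not m.is_watertight:
            raise GenerationError(f"{name} mesh is not watertight at pitch {resolution}")

    pelvis = BoneMesh(pel_mesh, pel_lm, rim)
    femur = BoneMesh(fem_mesh, fem_lm)
    pole = meta["pole"]
    if params.side == "left":
        pelvis = _mirror_bone(pelvis)
        femur = _mirror_bone(femur)
        pole = pole * np.array([1.0, -1.0, 1.0])

    # label articular-cup faces: contact there is joint congruence
    centroids = pelvis.mesh.triangles_center
    rel = centroids - pelvis.landmarks["acetabular_center"]
    d = np.linalg.norm(rel, axis=1)
    ang = np.arccos(np.clip((rel @ pole) / np.maximum(d, 1e-12), -1, 1))
    cup_mask = (np.abs(d - r_acet) < 0.9) & (ang < meta["psi"] - math.radians(2.5))

    fpp = _frames.define_fpp(pelvis)
    fem_frame = _frames.define_femoral_frame(femur, side=params.side)
    model = HipModel(
        pelvis=pelvis,
        femur=femur,
        side=params.side,
        fpp=fpp,
        femoral_frame=fem_frame,
        rotation_center=femur.landmarks["head_center"],
        params=params,
        cup_face_mask=cup_mask,
        extras={"psi_deg": math.degrees(meta["psi"]), "pole": pole,
                "r_acet": r_acet, "r_rim": meta["r_rim"], "resolution": resolution,
                # analytic source solids (right-side construction only);
                # kept for independent voxel-overlap oracles
                "pelvis_solid": pel_solid if params.side == "right" else None,
                "femur_solid": fem_solid if params.side == "right" else None},
    )
    pelvis.require(PELVIS_LANDMARKS)
    femur.require(FEMUR_LANDMARKS)
    return model


# --------------------------------------------------------------------------
# measurement suite: recompute anatomy from the mesh + landmarks

def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through >= 4 points."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = math.sqrt(sol[3] + center @ center)
    return center, radius

def _neck_axis(femur: BoneMesh) -> tuple[np.ndarray, np.ndarray]:
    head = femur.landmarks["head_center"]
    if "neck_base" in femur.landmarks:
        base = femur.landmarks["neck_base"]
    else:
        base = 0.5 * (
            femur.landmarks["greater_trochanter_tip"] + femur.landmarks["lesser_trochanter"]
        )
    axis = base - head
    n = np.linalg.norm(axis)
    if n < 1e-6:
        raise ValueError("degenerate neck axis: head center coincides with neck base")
    return head, axis / n


def measure_alpha_angle(model: HipModel) -> float:
    """Alpha angle (deg): polar angle from the neck axis, at the fitted
    head center, where the head-neck surface first exits the best-fit head
    sphere inflated by 2%.

    The surface is scanned in 1-degree polar bins from the medial pole
    toward the neck; the crossing is located by linear interpolation of
    the per-bin maximum radial excess.
    """
    femur = model.femur
    head_lm, axis = _neck_axis(femur)
    v = femur.vertices
    rel = v - head_lm
    d0 = np.linalg.norm(rel, axis=1)
    # fit the head sphere on the hemisphere facing away from the neck
    approx_r = np.median(d0[d0 < np.percentile(d0, 20)])
    polar = np.degrees(np.arccos(np.clip((rel @ axis) / np.maximum(d0, 1e-12), -1, 1)))
    cap = v[(polar > 100.0) & (d0 < 1.6 * approx_r)]
    if len(cap) < 10:
        raise ValueError("degenerate femoral head: cannot fit head sphere")
    center, radius = _fit_sphere(cap)

    rel = v - center
    d = np.linalg.norm(rel, axis=1)
    polar = np.degrees(np.arccos(np.clip((rel @ axis) / np.maximum(d, 1e-12), -1, 1)))
    sel = (polar > 15.0) & (polar < 130.0) & (d < 1.9 * radius)
    excess = d[sel] - ALPHA_TOL * radius
    bins = np.floor(polar[sel]).astype(int)
    order = np.argsort(bins)
    bmax = {}
    for b, e in zip(bins[order], excess[order]):
        if e > bmax.get(b, -np.inf):
            bmax[b] = e
    angles = np.array(sorted(bmax))
    vals = np.array([bmax[a] for a in angles])
    out = np.where(vals > 0.0)[0]
    if len(out) == 0:
        raise ValueError("no surface exits the head sphere: neck not found")
    i = out[-1]  # largest polar angle still proud of the tolerance sphere
    if i + 1 < len(vals) and vals[i + 1] < 0.0:
        # interpolate the zero crossing between bin centers
        a0, a1 = angles[i] + 0.5, angles[i + 1] + 0.5
        frac = vals[i] / (vals[i] - vals[i + 1])
        return float(a0 + frac * (a1 - a0))
    return float(angles[i] + 0.5)


def _side_lateral(side: str) -> np.ndarray:
    return np.array([0.0, -1.0, 0.0]) if side == "right" else np.array([0.0, 1.0, 0.0])


def measure_lcea(model: HipModel) -> float:
    """Lateral center-edge angle (deg) from the rim samples, coronal view."""
    pelvis = model.pelvis
    if pelvis.rim_samples is None or len(pelvis.rim_samples) < 12:
        raise ValueError("rim samples required to measure LCEA")
    rel = pelvis.rim_samples - pelvis.landmarks["acetabular_center"]
    lat = _side_lateral(model.side)
    cranial = rel[:, 2] > 0
    theta = np.degrees(np.arctan2(rel[cranial] @ lat, rel[cranial, 2]))
    return float(theta.max())


def measure_acetabular_version(model: HipModel) -> float:
    """Axial-plane version (deg) of the acetabular opening from rim samples."""
    pelvis = model.pelvis
    if pelvis.rim_samples is None or len(pelvis.rim_samples) < 12:
        raise ValueError("rim samples required to measure acetabular version")
    rel = pelvis.rim_samples - pelvis.rim_samples.mean(axis=0)
    # opening normal = smallest principal axis of the rim ring
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    n = vt[2]
    lat = _side_lateral(model.side)
    if n @ lat < 0:
        n = -n
    return float(math.degrees(math.atan2(n[0], n @ lat)))


def measure_femoral_version(model: HipModel) -> float:
    """Femoral neck anteversion (deg) relative to the epicondylar line."""
    femur = model.femur
    head, neck = _neck_axis(femur)
    h = -neck  # base -> head
    med = femur.landmarks["medial_epicondyle"] - femur.landmarks["lateral_epicondyle"]
    up = femur.landmarks["neck_base"] - femur.landmarks["knee_center"] \
        if "neck_base" in femur.landmarks else head - femur.landmarks["knee_center"]
    up = up / np.linalg.norm(up)
    med = med - (med @ up) * up
    med /= np.linalg.norm(med)
    sign = 1.0 if model.side == "right" else -1.0
    ant = sign * np.cross(med, up)
    return float(math.degrees(math.atan2(h @ ant, h @ med)))


def measure_all(model: HipModel) -> dict[str, float]:
    return {
        "alpha_angle": measure_alpha_angle(model),
        "lcea": measure_lcea(model),
        "acetabular_version": measure_acetabular_version(model),
        "femoral_version": measure_femoral_version(model),
    }


# --------------------------------------------------------------------------

def sample_cohort(spec: CohortSpec) -> list[tuple[HipModel, dict]]:
    """Draw a cohort of hips; deterministic given ``spec.seed``.

    Each element is ``(model, record)`` where the record carries the
    *measured* anatomy of the generated mesh alongside the requested draw.
    Draws falling outside the buildable parameter ranges are clipped (and
    logged); generation failures are re-sampled, at most 100 tries each.
    """
    rng = np.random.default_rng(spec.seed)
    type_names = sorted(spec.aiis_type_probs)
    type_p = np.array([spec.aiis_type_probs[t] for t in type_names])
    out = []
    for i in range(spec.n_patients):
        for attempt in range(100):
            draw = {}
            for key in ("alpha_angle", "lcea", "acetabular_version", "femoral_version"):
                mu, sd = spec.distributions[key]
                val = float(rng.normal(mu, sd))
                lo, hi = FEASIBLE[key]
                clipped = min(max(val, lo), hi)
                if clipped != val:
                    log.info("patient %d: clipped %s %.2f -> %.2f", i, key, val, clipped)
                draw[key] = clipped
            aiis = type_names[int(rng.choice(len(type_names), p=type_p))]
            params = AnatomyParams(
                aiis_type=aiis, head_radius=spec.head_radius, side=spec.side, **draw
            )
            try:
                model = generate_hip(params, resolution=spec.resolution)
            except GenerationError as err:
                log.info("patient %d attempt %d failed: %s", i, attempt, err)
                continue
            measured = measure_all(model)
            model = model.replace(measured=measured, patient_id=f"P{i:03d}")
            record = {
                "patient_id": f"P{i:03d}",
                "aiis_type": aiis,
                "side": spec.side,
                **{f"requested_{k}": v for k, v in draw.items()},
                **measured,
            }
            out.append((model, record))
            break
        else:
            raise GenerationError(f"patient {i}: no feasible draw in 100 attempts")
    return out
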