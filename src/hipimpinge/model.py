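"""Core data containers: landmarked bone meshes and the hip model.

Coordinate convention (documented in the README): right-handed, units mm,
+X anterior, +Y toward the patient's left, +Z cranial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

PELVIS_LANDMARKS = (
    "ASIS_left",
    "ASIS_right",
    "acetabular_center",
    "AIIS_apex",
    "inflection_ASIS_AIIS",
    "inflection_AIIS_rim",
)
FEMUR_LANDMARKS = (
    "head_center",
    "knee_center",
    "medial_epicondyle",
    "lateral_epicondyle",
    "greater_trochanter_tip",
    "lesser_trochanter",
)


@dataclass
class BoneMesh:
    """A watertight triangle surface with named anatomical landmarks.

    ``landmarks`` maps a name to a 3-vector (mm).  Rim samples are stored
    under ``rim_samples`` as an (m, 3) array (m >= 12 for a pelvis).
    """

    mesh: trimesh.Trimesh
    landmarks: dict[str, np.ndarray]
    rim_samples: np.ndarray | None = None

    def __post_init__(self):
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}
        if self.rim_samples is not None:
            self.rim_samples = np.asarray(self.rim_samples, dtype=float)

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BoneMesh":
        """Return a rigidly transformed copy (p -> R p + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        m = self.mesh.copy()
        m.vertices = m.vertices @ R.T + t
        lm = {k: R @ v + t for k, v in self.landmarks.items()}
        rim = None if self.rim_samples is None else self.rim_samples @ R.T + t
        return BoneMesh(m, lm, rim)

    # -- I/O: STL/PLY for the surface, JSON for the landmarks ------------
    def save(self, mesh_path: str | Path, landmark_path: str | Path | None = None) -> None:
        mesh_path = Path(mesh_path)
        self.mesh.export(mesh_path)
        if landmark_path is None:
            landmark_path = mesh_path.with_suffix(".landmarks.json")
        payload = {k: list(map(float, v)) for k, v in self.landmarks.items()}
        if self.rim_samples is not None:
            payload["acetabular_rim_samples"] = self.rim_samples.tolist()
        Path(landmark_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, mesh_path: str | Path, landmark_path: str | Path | None = None) -> "BoneMesh":
        mesh_path = Path(mesh_path)
        mesh = trimesh.load_mesh(mesh_path)
        if landmark_path is None:
            landmark_path = mesh_path.with_suffix(".landmarks.json")
        payload = json.loads(Path(landmark_path).read_text())
        rim = payload.pop("acetabular_rim_samples", None)
        lm = {k: np.asarray(v, dtype=float) for k, v in payload.items()}
        return cls(mesh, lm, None if rim is None else np.asarray(rim, dtype=float))


@dataclass
class Frame:
    """Orthonormal right-handed frame; axis columns = (anterior, lateral, cranial).

    "lateral" points toward the patient's left (the +Y sense of the global
    convention), for both hip sides.
    """

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns anterior/lateral/cranial

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        err = np.linalg.norm(self.axes.T @ self.axes - np.eye(3))
        if err > 1e-8:
            raise ValueError(f"frame axes not orthonormal (|A'A - I| = {err:.2e})")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame is left-handed")

    @property
    def anterior(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def lateral(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def cranial(self) -> np.ndarray:
        return self.axes[:, 2]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        R = np.asarray(rotation, dtype=float)
        return Frame(R @ self.origin + np.asarray(translation, dtype=float), R @ self.axes)


@dataclass
class HipModel:
    """One simulated hip: pelvis + femur with frames and metadata.

    ``cup_face_mask`` labels pelvis faces belonging to the articular cup
    (lunate) surface; contact there is joint congruence, not impingement,
    and is excluded from collision verdicts.  ``tilt_deg`` records the
    pelvic tilt already applied to the pelvis (+ = posterior).
    """

    pelvis: BoneMesh
    femur: BoneMesh
    side: str  # "left" | "right"
    fpp: "Frame"
    femoral_frame: "Frame"
    rotation_center: np.ndarray
    params: object | None = None  # AnatomyParams used for generation, if any
    measured: dict | None = None  # re-measured anatomy, if computed
    cup_face_mask: np.ndarray | None = None
    tilt_deg: float = 0.0
    patient_id: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rotation_center = np.asarray(self.rotation_center, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def replace(self, **kw) -> "HipModel":
        return replace(self, **kw)
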