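"""Implicit-solid primitives and marching-cubes surfacing.

The synthetic bones are built as unions/intersections of analytic solids
(spheres, capsules, cut spherical shells).  Each solid exposes a scalar
field ``f(points)`` that is negative inside, positive outside, and is an
accurate Euclidean distance close to the surface (hard min/max CSG keeps
the near-surface field metric).  Meshes are extracted with marching cubes
on a regular grid; the same fields later serve as an independent
voxel-overlap collision oracle, so exactness near the zero level set
matters more than smoothness.
"""

from __future__ import annotations

import numpy as np
import trimesh


class Solid:
    """Base class: signed field, negative inside."""

    def sdf(self, points: np.ndarray) -> np.ndarray:  # (n, 3) -> (n,)
        raise NotImplementedError

    def __or__(self, other: "Solid") -> "Union":
        return Union(self, other)


class Sphere(Solid):
    def __init__(self, center, radius: float):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def sdf(self, points):
        return np.linalg.norm(points - self.center, axis=1) - self.radius


class Capsule(Solid):
    """Segment from ``a`` to ``b`` inflated by ``radius``."""

    def __init__(self, a, b, radius: float):
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.radius = float(radius)

    def sdf(self, points):
        ab = self.b - self.a
        denom = float(ab @ ab)
        if denom == 0.0:
            return np.linalg.norm(points - self.a, axis=1) - self.radius
        t = np.clip(((points - self.a) @ ab) / denom, 0.0, 1.0)
        closest = self.a + t[:, None] * ab
        return np.linalg.norm(points - closest, axis=1) - self.radius


class CupShell(Solid):
    """Spherical shell truncated by a cone about ``pole``.

    Material occupies radii in [r_inner, r_outer] at polar angles (from
    ``pole``, measured at ``center``) below ``psi``.  This is the
    acetabular dome plus rim annulus.  The cone part of the field is
    ``d * sin(angle - psi)``, which is the exact distance to the cone
    surface for nearby points.
    """

    def __init__(self, center, pole, r_inner: float, r_outer: float, psi_rad: float):
        self.center = np.asarray(center, dtype=float)
        self.pole = np.asarray(pole, dtype=float) / np.linalg.norm(pole)
        self.r_inner = float(r_inner)
        self.r_outer = float(r_outer)
        self.psi = float(psi_rad)

    def sdf(self, points):
        rel = points - self.center
        d = np.linalg.norm(rel, axis=1)
        d_safe = np.where(d < 1e-12, 1e-12, d)
        cosang = np.clip((rel @ self.pole) / d_safe, -1.0, 1.0)
        ang = np.arccos(cosang)
        shell = np.maximum(self.r_inner - d, d - self.r_outer)
        cone = d * np.sin(np.clip(ang - self.psi, -np.pi / 2, np.pi / 2))
        return np.maximum(shell, cone)


class Union(Solid):
    def __init__(self, *solids: Solid):
        parts = []
        for s in solids:
            if isinstance(s, Union):
                parts.extend(s.solids)
            else:
                parts.append(s)
        self.solids = parts

    def sdf(self, points):
        out = self.solids[0].sdf(points)
        for s in self.solids[1:]:
            np.minimum(out, s.sdf(points), out=out)
        return out


def _eval_chunked(solid: Solid, points: np.ndarray, chunk: int = 500_000) -> np.ndarray:
    out = np.empty(len(points), dtype=float)
    for i in range(0, len(points), chunk):
        out[i : i + chunk] = solid.sdf(points[i : i + chunk])
    return out


def mesh_from_solid(
    solid: Solid,
    bounds: tuple[np.ndarray, np.ndarray],
    pitch: float,
) -> trimesh.Trimesh:
    """Extract the zero level set of ``solid`` on a regular grid.

    ``bounds`` must enclose the solid with margin so the surface is
    closed; the result is a watertight triangle mesh.
    """
    from skimage.measure import marching_cubes

    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    axes = [lo[k] + pitch * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    field = _eval_chunked(solid, grid).reshape(shape)
    if field.min() >= 0.0:
        raise ValueError("solid has no interior inside the given bounds")
    verts, faces, _, _ = marching_cubes(
        field, level=0.0, spacing=(pitch, pitch, pitch), gradient_direction="descent"
    )
    # marching cubes emits an indexed, consistently wound surface; vertex
    # merging/degenerate-face stripping (process=True) can open pinholes
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
    return mesh


def solid_bounds(solids: list[Solid], margin: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounds enclosing a list of primitive solids."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)

    def visit(s: Solid):
        if isinstance(s, Union):
            for p in s.solids:
                visit(p)
        elif isinstance(s, Sphere):
            lo[:] = np.minimum(lo, s.center - s.radius)
            hi[:] = np.maximum(hi, s.center + s.radius)
        elif isinstance(s, Capsule):
            lo[:] = np.minimum(lo, np.minimum(s.a, s.b) - s.radius)
            hi[:] = np.maximum(hi, np.maximum(s.a, s.b) + s.radius)
        elif isinstance(s, CupShell):
            lo[:] = np.minimum(lo, s.center - s.r_outer)
            hi[:] = np.maximum(hi, s.center + s.r_outer)
        else:  # pragma: no cover
            raise TypeError(type(s))

    for s in solids:
        visit(s)
    return lo - margin, hi + margin
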