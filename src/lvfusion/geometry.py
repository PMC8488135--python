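"""Core geometric types for left-ventricular surface analysis.

Defines rigid transforms, fiducial landmark sets, triangle-mesh surface
models and the subject-specific cardiac coordinate frame built from the
LV long axis (apical/basal centroids) and the right-ventricular (RV)
direction.  All lengths are millimetres; angles are degrees at every
public interface and radians internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GEOM_TOL",
    "DegenerateGeometryError",
    "RigidTransform",
    "LandmarkSet",
    "SurfaceModel",
    "CardiacFrame",
    "build_frame",
    "estimate_rv_direction_echo",
    "rotation_about_axis",
    "to_cardiac_coords",
    "from_cardiac_coords",
    "apply_transform",
]

#: Geometric tolerance (mm / dimensionless) used throughout.
GEOM_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised for degenerate landmark/axis configurations."""


def _as_point(p: Sequence[float]) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < GEOM_TOL:
        raise DegenerateGeometryError("cannot normalize a near-zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis by ``angle_deg`` (right-hand rule)."""
    axis = _unit(np.asarray(axis, dtype=float))
    th = np.deg2rad(angle_deg)
    k = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation``.

    The rotation must be orthonormal with determinant +1.  Matrices that
    are off by floating-point drift (up to 1e-6) are re-projected onto
    SO(3) via SVD; anything worse is rejected.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(r @ r.T - np.eye(3)).max()
        if err > GEOM_TOL or abs(np.linalg.det(r) - 1.0) > 1e-6:
            if err > 1e-6:
                raise ValueError("rotation is not orthonormal with det +1")
            u, _, vt = np.linalg.svd(r)
            d = np.sign(np.linalg.det(u @ vt))
            r = u @ np.diag([1.0, 1.0, d]) @ vt
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class LandmarkSet:
    """Fiducial landmarks anchoring the cardiac frame.

    ``rv_insertions`` is a list of ``(point, label)`` with labels in
    {"anterior", "inferior", None}.  The ``cmr`` convention supplies one
    or more insertions (typically both anterior and inferior); the
    ``echo`` convention supplies at least an inferior insertion, from
    which the RV direction is estimated by the 70-degree rule.
    """

    apical_centroid: np.ndarray
    basal_centroid: np.ndarray
    rv_insertions: tuple
    convention: str = "cmr"

    def __post_init__(self) -> None:
        apex = _as_point(self.apical_centroid)
        base = _as_point(self.basal_centroid)
        if np.linalg.norm(apex - base) < GEOM_TOL:
            raise DegenerateGeometryError("apical and basal centroids coincide")
        ins = []
        for item in self.rv_insertions:
            p, label = item
            if label not in ("anterior", "inferior", None):
                raise ValueError(f"unknown RV insertion label: {label!r}")
            ins.append((_as_point(p), label))
        if self.convention not in ("cmr", "echo"):
            raise ValueError("convention must be 'cmr' or 'echo'")
        if self.convention == "echo":
            if not any(lbl == "inferior" for _, lbl in ins):
                raise ValueError("echo convention requires an inferior RV insertion")
        elif not ins:
            raise ValueError("cmr convention requires at least one RV insertion")
        object.__setattr__(self, "apical_centroid", apex)
        object.__setattr__(self, "basal_centroid", base)
        object.__setattr__(self, "rv_insertions", tuple(ins))

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            t.apply(self.apical_centroid),
            t.apply(self.basal_centroid),
            tuple((t.apply(p), lbl) for p, lbl in self.rv_insertions),
            self.convention,
        )


@dataclass
class SurfaceModel:
    """Triangle mesh of one LV surface (endo or epi) at one phase."""

    vertices: np.ndarray
    triangles: np.ndarray
    surface_tag: str = "endo"
    phase: str = "ED"
    parameterized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        if self.surface_tag not in ("endo", "epi"):
            raise ValueError("surface_tag must be 'endo' or 'epi'")
        if self.phase not in ("ED", "ES"):
            raise ValueError("phase must be 'ED' or 'ES'")
        if f.size:
            a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
            areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
            if np.any(areas <= GEOM_TOL):
                raise ValueError("mesh contains degenerate (zero-area) triangles")
        self.vertices = v
        self.triangles = f

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class CardiacFrame:
    """Right-handed orthonormal cardiac frame.

    ``origin`` is the basal centroid, ``e_long`` points base→apex,
    ``e_rv`` toward the RV centroid (orthogonalized against ``e_long``)
    and ``e_norm = e_long × e_rv``.
    """

    origin: np.ndarray
    e_long: np.ndarray
    e_rv: np.ndarray
    e_norm: np.ndarray

    def __post_init__(self) -> None:
        o = _as_point(self.origin)
        axes = [np.asarray(a, dtype=float).reshape(3) for a in (self.e_long, self.e_rv, self.e_norm)]
        for a in axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-8:
                raise ValueError("frame axes must be unit vectors")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(axes[i] @ axes[j]) > 1e-8:
                    raise ValueError("frame axes must be pairwise orthogonal")
        if np.linalg.det(np.stack([axes[1], axes[2], axes[0]])) < 0:
            raise ValueError("frame must be right-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "e_long", axes[0])
        object.__setattr__(self, "e_rv", axes[1])
        object.__setattr__(self, "e_norm", axes[2])

    @property
    def basis(self) -> np.ndarray:
        """Columns ``(e_rv, e_norm, e_long)``: frame→world rotation."""
        return np.column_stack([self.e_rv, self.e_norm, self.e_long])

    def transformed(self, t: RigidTransform) -> "CardiacFrame":
        return CardiacFrame(
            t.apply(self.origin),
            t.rotation @ self.e_long,
            t.rotation @ self.e_rv,
            t.rotation @ self.e_norm,
        )


def estimate_rv_direction_echo(
    inferior_insertion: np.ndarray, origin: np.ndarray, e_long: np.ndarray
) -> np.ndarray:
    """Approximate the RV-centroid direction from the inferior insertion.

    The anterior RV insertion is generally not visible on 3D echo, so the
    RV centroid is taken 70 degrees clockwise from the inferior insertion
    when viewed from apex to base.  With ``e_long`` pointing base→apex,
    "clockwise" for a viewer at the apex looking toward the base is a
    rotation by −70° about ``e_long`` (right-hand rule).
    """
    origin = _as_point(origin)
    e_long = _unit(np.asarray(e_long, dtype=float))
    d = _as_point(inferior_insertion) - origin
    d_perp = d - (d @ e_long) * e_long
    if np.linalg.norm(d_perp) < GEOM_TOL or _angle_to_axis_deg(d, e_long) < 1.0:
        raise DegenerateGeometryError(
            "inferior RV insertion is collinear with the long axis"
        )
    return _unit(rotation_about_axis(e_long, -70.0) @ _unit(d_perp))


def _angle_to_axis_deg(v: np.ndarray, axis: np.ndarray) -> float:
    c = abs(_unit(v) @ axis)
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def build_frame(landmarks: LandmarkSet) -> CardiacFrame:
    """Cardiac frame from landmarks.

    The long axis connects the basal to the apical centroid; the RV
    centroid (mean of all insertion points for CMR, 70°-rule estimate
    for echo) orients the model about its long axis.
    """
    origin = landmarks.basal_centroid
    axis = landmarks.apical_centroid - landmarks.basal_centroid
    if np.linalg.norm(axis) < GEOM_TOL:
        raise DegenerateGeometryError("apical and basal centroids coincide")
    e_long = _unit(axis)

    if landmarks.convention == "echo":
        inferior = next(p for p, lbl in landmarks.rv_insertions if lbl == "inferior")
        rv_dir = estimate_rv_direction_echo(inferior, origin, e_long)
    else:
        rv_centroid = np.mean([p for p, _ in landmarks.rv_insertions], axis=0)
        rv_dir = rv_centroid - origin
        if np.linalg.norm(rv_dir) < GEOM_TOL or _angle_to_axis_deg(rv_dir, e_long) < 1.0:
            raise DegenerateGeometryError(
                "RV centroid is collinear with the long axis"
            )
    e_rv = _unit(rv_dir - (rv_dir @ e_long) * e_long)
    e_norm = np.cross(e_long, e_rv)
    return CardiacFrame(origin, e_long, e_rv, e_norm)


def to_cardiac_coords(
    points: np.ndarray, frame: CardiacFrame, apex_extent: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map world points to cardiac coordinates ``(u, phi, r)``.

    ``u`` is the normalized longitudinal position (0 at the basal plane,
    1 at the apex), ``phi`` the circumferential angle in degrees in
    [0, 360) with 0 at ``e_rv`` increasing toward ``e_norm``, and ``r``
    the radial distance from the long axis in mm.
    """
    if apex_extent <= 0:
        raise ValueError("apex_extent must be positive")
    p = np.atleast_2d(np.asarray(points, dtype=float)) - frame.origin
    z = p @ frame.e_long
    x = p @ frame.e_rv
    y = p @ frame.e_norm
    u = z / apex_extent
    phi = np.rad2deg(np.arctan2(y, x)) % 360.0
    r = np.hypot(x, y)
    if np.ndim(points) == 1:
        return u[0], phi[0], r[0]
    return u, phi, r


def from_cardiac_coords(
    u: np.ndarray, phi_deg: np.ndarray, r: np.ndarray, frame: CardiacFrame, apex_extent: float
) -> np.ndarray:
    """Inverse of :func:`to_cardiac_coords`."""
    if apex_extent <= 0:
        raise ValueError("apex_extent must be positive")
    u = np.asarray(u, dtype=float)
    ph = np.deg2rad(np.asarray(phi_deg, dtype=float))
    r = np.asarray(r, dtype=float)
    pts = (
        frame.origin
        + np.multiply.outer(u * apex_extent, frame.e_long)
        + np.multiply.outer(r * np.cos(ph), frame.e_rv)
        + np.multiply.outer(r * np.sin(ph), frame.e_norm)
    )
    return pts


def apply_transform(obj, t: RigidTransform):
    """Apply a rigid transform to a SurfaceModel, LandmarkSet, frame or point array."""
    if isinstance(obj, SurfaceModel):
        return dataclasses.replace(obj, vertices=t.apply(obj.vertices))
    if isinstance(obj, (LandmarkSet, CardiacFrame)):
        return obj.transformed(t)
    return t.apply(np.asarray(obj, dtype=float))
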