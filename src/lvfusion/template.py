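"""Common-template least-squares re-fitting of LV surfaces.

Both modalities' surface point sets are re-fitted, in the shared cardiac
frame, to one canonical template: a radial field r(u, phi) sampled on a
regular longitudinal × circumferential grid (periodic in phi), obtained
by linear least squares with a second-difference Tikhonov roughness
penalty.  Two surfaces fitted on equal grids are in node-wise
correspondence by index, which is what the regional mean-surface-distance
statistic requires.

The template assumes star-shaped surfaces (single-valued r(u, phi) about
the long axis), which holds for truncated-ellipsoidal LV geometries; a
pre-check rejects multi-valued inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    CardiacFrame,
    SurfaceModel,
    from_cardiac_coords,
    to_cardiac_coords,
)

__all__ = [
    "LVTemplate",
    "FittedSurface",
    "parameterize_points",
    "fit_surface",
    "resample_mesh",
    "node_positions",
]

#: two points in one grid cell further apart radially than this indicate
#: a non-star-shaped (multi-valued) surface
STAR_SHAPE_DR_MM = 15.0


@dataclass(frozen=True)
class LVTemplate:
    """Radial field r(u_i, v_j) on a regular (u, phi) grid.

    ``u_i = i/(n_u-1)`` spans [0, 1] base→apex; ``v_j = j·360/n_v``
    spans [0°, 360°) and wraps periodically.  Node ordering is u-major:
    node ``k`` ↔ ``(i, j) = (k // n_v, k % n_v)``.
    """

    n_u: int
    n_v: int
    radii: np.ndarray  # (n_u, n_v), mm

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float).reshape(self.n_u, self.n_v)
        if self.n_u < 2 or self.n_v < 3:
            raise ValueError("template grid requires n_u >= 2, n_v >= 3")
        if not np.all(r > 0):
            raise ValueError("template radii must be positive everywhere")
        object.__setattr__(self, "radii", r)

    @property
    def u_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_u)

    @property
    def v_grid_deg(self) -> np.ndarray:
        return np.arange(self.n_v) * (360.0 / self.n_v)

    def interp_radius(self, u: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
        """Bilinear, phi-periodic interpolation of the radial field."""
        iu, su, jv, tv = _cell_coords(np.asarray(u, float), np.asarray(phi_deg, float), self.n_u, self.n_v)
        jp = (jv + 1) % self.n_v
        r = self.radii
        return (
            r[iu, jv] * (1 - su) * (1 - tv)
            + r[iu, jp] * (1 - su) * tv
            + r[iu + 1, jv] * su * (1 - tv)
            + r[iu + 1, jp] * su * tv
        )


@dataclass(frozen=True)
class FittedSurface:
    """A surface re-fitted to the canonical template in a given frame."""

    template: LVTemplate
    frame: CardiacFrame
    apex_extent: float
    surface_tag: str
    phase: str
    fit_rms: float
    mesh: SurfaceModel

    def node_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, phi°) of each template node, in canonical node order."""
        t = self.template
        u = np.repeat(t.u_grid, t.n_v)
        phi = np.tile(t.v_grid_deg, t.n_u)
        return u, phi


def _cell_coords(u, phi_deg, n_u, n_v):
    """Grid cell index and fractional offset for each (u, phi)."""
    du = 1.0 / (n_u - 1)
    iu = np.clip((u / du).astype(int), 0, n_u - 2)
    su = np.clip(u / du - iu, 0.0, 1.0)
    dv = 360.0 / n_v
    ph = np.asarray(phi_deg) % 360.0
    jv = np.clip((ph / dv).astype(int), 0, n_v - 1)
    tv = ph / dv - jv
    return iu, su, jv, tv


def parameterize_points(
    points: np.ndarray,
    frame: CardiacFrame,
    apex_extent: float,
    u_slack: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cardiac coordinates of a point cloud, with clamped u.

    Points up to ``u_slack`` outside [0, 1] longitudinally are clamped;
    more than 5% outside raises a coverage error.
    """
    u, phi, r = to_cardiac_coords(np.atleast_2d(points), frame, apex_extent)
    outside = (u < -u_slack) | (u > 1.0 + u_slack)
    if outside.mean() > 0.05:
        raise ValueError(
            f"{outside.mean():.1%} of points fall outside the tolerated "
            f"longitudinal range [-{u_slack}, 1+{u_slack}]"
        )
    return np.clip(u, 0.0, 1.0), phi, r


def _second_difference_operator(n_u: int, n_v: int) -> sp.csr_matrix:
    """Second differences along u (open) and phi (periodic), stacked."""
    rows, cols, vals = [], [], []
    k = 0
    idx = lambda i, j: i * n_v + j
    for j in range(n_v):
        for i in range(1, n_u - 1):
            rows += [k, k, k]
            cols += [idx(i - 1, j), idx(i, j), idx(i + 1, j)]
            vals += [1.0, -2.0, 1.0]
            k += 1
    for i in range(n_u):
        for j in range(n_v):
            rows += [k, k, k]
            cols += [idx(i, (j - 1) % n_v), idx(i, j), idx(i, (j + 1) % n_v)]
            vals += [1.0, -2.0, 1.0]
            k += 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(k, n_u * n_v))


def fit_surface(
    points: np.ndarray,
    frame: CardiacFrame,
    n_u: int = 24,
    n_v: int = 24,
    lambda_smooth: float = 1.0,
    apex_extent: Optional[float] = None,
    surface_tag: str = "endo",
    phase: str = "ED",
) -> FittedSurface:
    """Least-squares re-fit of a surface point cloud to the template.

    Solves ``min_r Σ_j (B(u_j, phi_j)·r − r_j)² + lambda_smooth·‖D r‖²``
    where B is bilinear interpolation on the periodic (u, phi) grid and
    D the second-difference operator.  ``apex_extent`` defaults to the
    maximal longitudinal extent of the data.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if apex_extent is None:
        apex_extent = float(np.max((pts - frame.origin) @ frame.e_long))
    u, phi, r_data = parameterize_points(pts, frame, apex_extent)
    # points on the long axis (e.g. an apical pole vertex) have undefined
    # phi and carry no radial information; drop them
    on_axis = r_data < 1e-6
    if on_axis.any():
        u, phi, r_data = u[~on_axis], phi[~on_axis], r_data[~on_axis]
    if len(u) == 0:
        raise ValueError("no off-axis points to fit")

    n_nodes = n_u * n_v
    iu, su, jv, tv = _cell_coords(u, phi, n_u, n_v)
    jp = (jv + 1) % n_v
    npts = len(u)
    rows = np.repeat(np.arange(npts), 4)
    cols = np.concatenate([iu * n_v + jv, iu * n_v + jp, (iu + 1) * n_v + jv, (iu + 1) * n_v + jp])
    cols = cols.reshape(4, npts).T.ravel()
    w = np.stack([(1 - su) * (1 - tv), (1 - su) * tv, su * (1 - tv), su * tv], axis=1).ravel()
    b = sp.csr_matrix((w, (rows, cols)), shape=(npts, n_nodes))

    # star-shapedness pre-check: radial spread within one grid cell.  The
    # apical cell row is exempt — the radius legitimately collapses toward
    # zero there, and a multi-valued surface trips cells everywhere.
    cell = iu * n_v + jv
    rmin = np.full((n_u - 1) * n_v, np.inf)
    rmax = np.full((n_u - 1) * n_v, -np.inf)
    np.minimum.at(rmin, cell, r_data)
    np.maximum.at(rmax, cell, r_data)
    occupied = np.isfinite(rmin)
    check = occupied.copy()
    check[(n_u - 2) * n_v:] = False
    if np.any((rmax - rmin)[check] > STAR_SHAPE_DR_MM):
        raise ValueError(
            "surface is not star-shaped about the long axis "
            f"(radial spread > {STAR_SHAPE_DR_MM} mm within one grid cell)"
        )
    if not np.all(occupied):
        if lambda_smooth == 0:
            raise np.linalg.LinAlgError(
                "grid cells without supporting data and lambda_smooth=0: "
                "singular least-squares system"
            )
        warnings.warn(
            f"{(~occupied).sum()} template grid cells have no supporting data; "
            "relying on the smoothness prior there",
            RuntimeWarning,
        )

    d = _second_difference_operator(n_u, n_v)
    lhs = (b.T @ b + lambda_smooth * (d.T @ d)).tocsc()
    rhs = b.T @ r_data
    r_nodes = spla.spsolve(lhs, rhs)
    fit_rms = float(np.sqrt(np.mean((b @ r_nodes - r_data) ** 2)))

    template = LVTemplate(n_u=n_u, n_v=n_v, radii=r_nodes.reshape(n_u, n_v))
    mesh = _build_mesh(template, frame, apex_extent, surface_tag, phase)
    return FittedSurface(
        template=template,
        frame=frame,
        apex_extent=apex_extent,
        surface_tag=surface_tag,
        phase=phase,
        fit_rms=fit_rms,
        mesh=mesh,
    )


def node_positions(template: LVTemplate, frame: CardiacFrame, apex_extent: float) -> np.ndarray:
    """World positions of template nodes in canonical (u-major) order."""
    u = np.repeat(template.u_grid, template.n_v)
    phi = np.tile(template.v_grid_deg, template.n_u)
    return from_cardiac_coords(u, phi, template.radii.ravel(), frame, apex_extent)


def _build_mesh(
    template: LVTemplate,
    frame: CardiacFrame,
    apex_extent: float,
    surface_tag: str,
    phase: str,
) -> SurfaceModel:
    n_u, n_v = template.n_u, template.n_v
    verts = node_positions(template, frame, apex_extent)
    pole = frame.origin + apex_extent * frame.e_long  # apex on the long axis
    verts = np.vstack([verts, pole])
    pole_idx = n_u * n_v

    tris = []
    for i in range(n_u - 1):
        for j in range(n_v):
            a = i * n_v + j
            b2 = i * n_v + (j + 1) % n_v
            c = (i + 1) * n_v + j
            d2 = (i + 1) * n_v + (j + 1) % n_v
            tris.append((a, b2, d2))
            tris.append((a, d2, c))
    top = (n_u - 1) * n_v
    for j in range(n_v):
        tris.append((top + j, top + (j + 1) % n_v, pole_idx))
    return SurfaceModel(
        vertices=verts,
        triangles=np.array(tris, dtype=np.int64),
        surface_tag=surface_tag,
        phase=phase,
        parameterized=True,
    )


def resample_mesh(fitted: FittedSurface) -> SurfaceModel:
    """Triangulated mesh over the (u, phi) grid with apex fan closure.

    Vertex count is ``n_u·n_v + 1`` (grid nodes in canonical order plus
    the apical pole); grid vertices reproduce r(u_i, v_j) exactly.
    """
    return _build_mesh(
        fitted.template, fitted.frame, fitted.apex_extent, fitted.surface_tag, fitted.phase
    )
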