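"""Global LV volumetric indices: EDV, ESV, EF, mass and BSA indexing.

Volumes are computed on the fitted template surfaces so that every
method shares one mesh-volume operator: the basal opening is capped by
a triangle fan to the basal-ring centroid and the enclosed volume is
evaluated by the divergence theorem (signed tetrahedra to the origin).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .template import FittedSurface

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "SubjectInfo",
    "VolumetricReport",
    "mesh_volume_mm3",
    "cavity_volume",
    "lv_mass",
    "ejection_fraction",
    "index_by_bsa",
    "volumetric_report",
]

#: standard echocardiographic myocardial density convention
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class SubjectInfo:
    subject_id: str
    bsa: float  # body surface area, m^2

    def __post_init__(self) -> None:
        if not self.bsa > 0:
            raise ValueError("BSA must be positive")


@dataclass
class VolumetricReport:
    """Per subject/method global indices (ml, %, g; indexed by BSA)."""

    method: str
    edv: float
    esv: float
    ef: float
    lvm: Optional[float] = None
    edvi: Optional[float] = None
    esvi: Optional[float] = None
    lvmi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.esv <= self.edv and not (0.0 <= self.ef <= 100.0):
            raise ValueError("EF must lie in [0, 100] when ESV <= EDV")


def _capped_mesh(fitted: FittedSurface) -> tuple[np.ndarray, np.ndarray]:
    """Vertices and triangles of the fitted mesh with the basal cap added."""
    mesh = fitted.mesh
    n_v = fitted.template.n_v
    verts = mesh.vertices
    ring = verts[:n_v]  # basal ring, u = 0
    centroid = ring.mean(axis=0)
    cap_center = len(verts)
    cap = [(int((j + 1) % n_v), int(j), cap_center) for j in range(n_v)]
    return np.vstack([verts, centroid]), np.vstack([mesh.triangles, np.array(cap)])


def mesh_volume_mm3(vertices: np.ndarray, triangles: np.ndarray) -> float:
    """Enclosed volume of a closed, consistently oriented triangle mesh.

    Divergence theorem: V = |Σ det(a, b, c)| / 6 over all triangles.
    """
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def cavity_volume(endo: FittedSurface) -> float:
    """Cavity volume (ml) of a fitted endocardial surface.

    The basal opening is capped in the plane of the basal-ring nodes;
    the cap is included in the cavity.
    """
    verts, tris = _capped_mesh(endo)
    return mesh_volume_mm3(verts, tris) / 1000.0


def lv_mass(
    endo: FittedSurface,
    epi: FittedSurface,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
    tol_mm: float = 0.1,
) -> float:
    """LV mass (g) from the epi/endo shell volume times myocardial density."""
    if (endo.template.n_u, endo.template.n_v) != (epi.template.n_u, epi.template.n_v):
        raise ValueError("endo and epi templates must share one grid")
    # evaluate the epicardial radius at each endocardial node's physical
    # longitudinal position (the two surfaces may have different apex extents)
    u_endo = np.repeat(endo.template.u_grid, endo.template.n_v)
    phi = np.tile(endo.template.v_grid_deg, endo.template.n_u)
    u_epi = np.clip(u_endo * endo.apex_extent / epi.apex_extent, 0.0, 1.0)
    r_epi = epi.template.interp_radius(u_epi, phi).reshape(endo.template.radii.shape)
    crossing = endo.template.radii - r_epi
    if np.any(crossing > tol_mm):
        raise ValueError(
            f"epicardium crosses inside the endocardium by up to "
            f"{crossing.max():.2f} mm (> {tol_mm} mm tolerance)"
        )
    shell_ml = cavity_volume(epi) - cavity_volume(endo)
    return shell_ml * density


def ejection_fraction(edv: float, esv: float) -> float:
    """EF (%) = 100·(EDV − ESV)/EDV."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def index_by_bsa(report: VolumetricReport, subject: SubjectInfo) -> VolumetricReport:
    """BSA-indexed copy of a volumetric report (ml/m², g/m²)."""
    if subject.bsa <= 0:
        raise ValueError("BSA must be positive")
    return replace(
        report,
        edvi=report.edv / subject.bsa,
        esvi=report.esv / subject.bsa,
        lvmi=None if report.lvm is None else report.lvm / subject.bsa,
    )


def volumetric_report(
    endo_ed: FittedSurface,
    endo_es: FittedSurface,
    epi_ed: Optional[FittedSurface] = None,
    method: str = "",
    subject: Optional[SubjectInfo] = None,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> VolumetricReport:
    """EDV/ESV/EF (and LVM from the ED models, if epi given) in one call."""
    edv = cavity_volume(endo_ed)
    esv = cavity_volume(endo_es)
    rep = VolumetricReport(
        method=method,
        edv=edv,
        esv=esv,
        ef=ejection_fraction(edv, esv),
        lvm=None if epi_ed is None else lv_mass(endo_ed, epi_ed, density),
    )
    if subject is not None:
        rep = index_by_bsa(rep, subject)
    return rep
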