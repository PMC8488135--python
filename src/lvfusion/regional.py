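"""AHA 16/17-segment partition and regional mean surface distance.

The endocardium is divided into the 16 AHA segments (the apical cap is
excluded); the epicardium carries all 17.  Differences between the
re-fitted echo and the CMR surfaces are expressed per segment as the
mean Euclidean distance between corresponding template nodes:

    MSD_seg = (1/N_p) Σ_p ||M_p − E_p||

where M_p, E_p are corresponding nodes of the two fitted surfaces and
N_p the number of node pairs in the segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .template import FittedSurface, node_positions

__all__ = [
    "AHALabelMap",
    "RegionalMSDReport",
    "SEGMENT_NAMES",
    "segment_of",
    "assign_aha_segments",
    "mean_surface_distance",
]

SEGMENT_NAMES = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apical cap",
}

# 60° circumferential sectors for the basal (ids row 0) and mid (row 1)
# rings, walking from the mid-septum (phi=0 at e_rv) toward the anterior
# wall: anteroseptal, anterior, anterolateral, inferolateral, inferior,
# inferoseptal.
_RING_IDS = np.array([
    [2, 1, 6, 5, 4, 3],    # basal
    [8, 7, 12, 11, 10, 9], # mid
])
# 90° apical sectors: septal [315°,45°), anterior [45°,135°),
# lateral [135°,225°), inferior [225°,315°)
_APICAL_IDS = np.array([14, 13, 16, 15])


@dataclass(frozen=True)
class AHALabelMap:
    """Per-node AHA segment id plus a mask of excluded nodes.

    ``labels[k]`` is the segment id of node ``k`` (0 where masked).
    Masked nodes are those below the basal plane or, on the
    endocardium, within the apical cap.
    """

    labels: np.ndarray
    mask: np.ndarray  # True where the node is excluded
    surface_tag: str
    cap_u: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        m = np.asarray(self.mask, dtype=bool)
        if lab.shape != m.shape:
            raise ValueError("labels and mask must have equal shape")
        valid = lab[~m]
        hi = 16 if self.surface_tag == "endo" else 17
        if valid.size and (valid.min() < 1 or valid.max() > hi):
            raise ValueError(f"{self.surface_tag} labels must lie in 1..{hi}")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class RegionalMSDReport:
    """Per-segment mean surface distance (mm) with node counts."""

    msd: Dict[int, float]
    n_p: Dict[int, int]
    surface_tag: str
    phase: str

    def __post_init__(self) -> None:
        for seg, v in self.msd.items():
            if v < 0:
                raise ValueError("MSD must be non-negative")
            if self.n_p.get(seg, 0) < 1:
                raise ValueError("every reported segment needs N_p >= 1")


def segment_of(u: np.ndarray, phi_deg: np.ndarray, cap_u: float = 0.90,
               surface_tag: str = "epi") -> tuple[np.ndarray, np.ndarray]:
    """AHA segment ids for cardiac coordinates (u, phi).

    Longitudinal thirds by u (basal [0,1/3), mid [1/3,2/3), apical
    [2/3, cap_u)), apical cap [cap_u, 1] on the epicardium only; on the
    endocardium cap nodes are masked.  Boundary ties resolve to the
    lower sector (half-open intervals).  Returns (labels, mask).
    """
    if not (2.0 / 3.0 < cap_u < 1.0):
        raise ValueError("cap_u must lie in (2/3, 1)")
    u = np.asarray(u, dtype=float)
    phi = np.asarray(phi_deg, dtype=float) % 360.0
    labels = np.zeros(u.shape, dtype=int)
    mask = u < 0.0

    sector60 = np.clip((phi // 60.0).astype(int), 0, 5)
    basal = (~mask) & (u < 1.0 / 3.0)
    mid = (u >= 1.0 / 3.0) & (u < 2.0 / 3.0)
    labels[basal] = _RING_IDS[0][sector60[basal]]
    labels[mid] = _RING_IDS[1][sector60[mid]]

    apical = (u >= 2.0 / 3.0) & (u < cap_u)
    sector90 = (((phi + 45.0) % 360.0) // 90.0).astype(int)
    labels[apical] = _APICAL_IDS[np.clip(sector90[apical], 0, 3)]

    cap = u >= cap_u
    if surface_tag == "endo":
        mask = mask | cap
    else:
        labels[cap] = 17
    labels[mask] = 0
    return labels, mask


def assign_aha_segments(fitted: FittedSurface, cap_u: float = 0.90) -> AHALabelMap:
    """Label every template node of a fitted surface with its AHA segment.

    The apical pole vertex (mesh index n_u·n_v) belongs to the cap.
    """
    if not fitted.mesh.parameterized:
        raise ValueError("assign_aha_segments requires a parameterized surface")
    u, phi = fitted.node_uv()
    u = np.append(u, 1.0)      # pole
    phi = np.append(phi, 0.0)
    labels, mask = segment_of(u, phi, cap_u=cap_u, surface_tag=fitted.surface_tag)
    return AHALabelMap(labels=labels, mask=mask, surface_tag=fitted.surface_tag, cap_u=cap_u)


def mean_surface_distance(
    ref: FittedSurface, test: FittedSurface, labels: AHALabelMap
) -> RegionalMSDReport:
    """Per-AHA-segment mean distance between corresponding template nodes.

    Requires equal template grids (node-index correspondence).  Segments
    with no unmasked nodes are absent from the report, not zero.
    """
    tr, tt = ref.template, test.template
    if (tr.n_u, tr.n_v) != (tt.n_u, tt.n_v):
        raise ValueError("mean_surface_distance requires equal template grids")
    pr = np.vstack([node_positions(tr, ref.frame, ref.apex_extent),
                    ref.frame.origin + ref.apex_extent * ref.frame.e_long])
    pt = np.vstack([node_positions(tt, test.frame, test.apex_extent),
                    test.frame.origin + test.apex_extent * test.frame.e_long])
    if labels.labels.shape[0] != pr.shape[0]:
        raise ValueError("label map does not match the template node count")
    d = np.linalg.norm(pr - pt, axis=1)
    msd: Dict[int, float] = {}
    n_p: Dict[int, int] = {}
    keep = ~labels.mask
    for seg in np.unique(labels.labels[keep]):
        sel = keep & (labels.labels == seg)
        msd[int(seg)] = float(d[sel].mean())
        n_p[int(seg)] = int(sel.sum())
    return RegionalMSDReport(msd=msd, n_p=n_p, surface_tag=ref.surface_tag, phase=ref.phase)
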