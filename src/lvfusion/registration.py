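"""Rigid registration of the 3D-echo LV model onto the CMR model.

Coarse alignment maps the echo cardiac frame onto the CMR frame (long
axis + RV direction), after which an iterative-closest-point refinement
with a closed-form SVD rigid update stands in for interactive manual
adjustment.  ED and ES are always registered independently, since the
transducer can move relative to the heart between acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CardiacFrame, RigidTransform, SurfaceModel, LandmarkSet, build_frame

__all__ = [
    "RegistrationResult",
    "PhaseData",
    "coarse_align",
    "icp_refine",
    "register_subject",
]

PHASES = ("ED", "ES")


@dataclass(frozen=True)
class PhaseData:
    """Endo+epi surfaces and landmarks of one modality at one phase."""

    endo: SurfaceModel
    epi: SurfaceModel
    landmarks: LandmarkSet


@dataclass
class RegistrationResult:
    phase: str
    coarse: RigidTransform
    refinement: RigidTransform
    total: RigidTransform
    rms_residual: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        expect = self.refinement.compose(self.coarse)
        if np.abs(expect.matrix - self.total.matrix).max() > 1e-9:
            raise ValueError("total transform must equal refinement ∘ coarse")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


def coarse_align(frame_echo: CardiacFrame, frame_cmr: CardiacFrame) -> RigidTransform:
    """Rigid transform mapping the echo frame onto the CMR frame.

    The unique proper rigid map sending (origin, e_long, e_rv, e_norm) of
    the source frame to those of the target frame.
    """
    r = frame_cmr.basis @ frame_echo.basis.T
    t = frame_cmr.origin - r @ frame_echo.origin
    return RigidTransform(r, t)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform src→dst (Kabsch/Umeyama, no scaling)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cd - r @ cs)


def icp_refine(
    src_points: np.ndarray,
    ref_points: np.ndarray,
    t0: Optional[RigidTransform] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    phase: str = "ED",
) -> RegistrationResult:
    """Point-to-point ICP refinement starting from a coarse transform.

    One-way nearest-neighbour correspondence (src→ref, ties broken by
    lowest index), closed-form SVD rigid update each iteration;
    converged when the RMS residual changes by less than ``tol`` mm.
    Non-convergence produces a warning, not an exception.
    """
    src = np.asarray(src_points, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref_points, dtype=float).reshape(-1, 3)
    if len(src) == 0 or len(ref) == 0:
        raise ValueError("ICP requires non-empty point sets")
    t0 = RigidTransform.identity() if t0 is None else t0

    tree = cKDTree(ref)
    total = t0
    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = total.apply(src)
        dist, idx = tree.query(moved, k=1)
        total = _kabsch(src, ref[idx])
        resid = np.linalg.norm(total.apply(src) - ref[idx], axis=1)
        rms = float(np.sqrt(np.mean(resid**2)))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
    if not converged:
        warnings.warn(
            f"ICP did not converge within {max_iter} iterations (RMS {rms:.3g} mm)",
            RuntimeWarning,
        )
    refinement = total.compose(t0.inverse())
    return RegistrationResult(
        phase=phase,
        coarse=t0,
        refinement=refinement,
        total=refinement.compose(t0),
        rms_residual=rms,
        n_iterations=it,
        converged=converged,
    )


def register_subject(
    echo: Mapping[str, PhaseData],
    cmr: Mapping[str, PhaseData],
    refine: bool = True,
    manual_override: Optional[Mapping[str, RigidTransform]] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    rms_threshold: float = 5.0,
) -> list[RegistrationResult]:
    """Register one subject's echo model onto its CMR model, per phase.

    ED and ES are solved with no shared parameters.  ``manual_override``
    maps a phase to a refinement transform that replaces ICP for that
    phase.  Refinement uses the union of endocardial and epicardial
    vertices.  A result whose RMS residual exceeds ``rms_threshold``
    (default 5 mm) triggers a warning flagging a poor fusion.
    """
    for ph in PHASES:
        if ph not in echo or ph not in cmr:
            raise ValueError(f"missing phase {ph!r} in input models")
    results = []
    for ph in PHASES:
        e, c = echo[ph], cmr[ph]
        coarse = coarse_align(build_frame(e.landmarks), build_frame(c.landmarks))
        override = (manual_override or {}).get(ph)
        if override is not None:
            total = override.compose(coarse)
            src = np.vstack([e.endo.vertices, e.epi.vertices])
            ref = np.vstack([c.endo.vertices, c.epi.vertices])
            dist, _ = cKDTree(ref).query(total.apply(src), k=1)
            res = RegistrationResult(
                phase=ph,
                coarse=coarse,
                refinement=override,
                total=total,
                rms_residual=float(np.sqrt(np.mean(dist**2))),
                n_iterations=0,
                converged=True,
            )
        elif refine:
            src = np.vstack([e.endo.vertices, e.epi.vertices])
            ref = np.vstack([c.endo.vertices, c.epi.vertices])
            res = icp_refine(src, ref, coarse, max_iter=max_iter, tol=tol, phase=ph)
        else:
            res = RegistrationResult(
                phase=ph,
                coarse=coarse,
                refinement=RigidTransform.identity(),
                total=coarse,
                rms_residual=0.0,
                n_iterations=0,
                converged=True,
            )
        if res.rms_residual > rms_threshold:
            warnings.warn(
                f"phase {ph}: registration RMS residual {res.rms_residual:.2f} mm "
                f"exceeds threshold {rms_threshold:.2f} mm — verify fusion",
                RuntimeWarning,
            )
        results.append(res)
    return results
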