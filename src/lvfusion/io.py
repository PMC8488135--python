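"""Readers and writers for the interchange formats.

Surface meshes: PLY (ASCII and binary little-endian, double precision)
and legacy-VTK ASCII polydata.  Landmarks: a strict JSON schema.
Image volumes: NIfTI-1 (via nibabel) and MetaImage .mha (via SimpleITK),
with spacing/origin/direction honored.  Surface tag and phase travel in
the ``<subject>_<phase>_<endo|epi>`` file-naming convention or an
explicit sidecar.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import LandmarkSet, SurfaceModel
from .intensity import ImageVolume

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_volume",
    "write_volume",
]

_NAME_RE = re.compile(r"(?:^|_)(ED|ES)_(endo|epi)$")


class MeshParseError(ValueError):
    """Malformed mesh file, with a line/offset hint."""


def _infer_tags(path: Path) -> tuple[Optional[str], Optional[str]]:
    m = _NAME_RE.search(path.stem)
    return (m.group(1), m.group(2)) if m else (None, None)


# ---------------------------------------------------------------- PLY

def _write_ply(path: Path, model: SurfaceModel, binary: bool) -> None:
    n_v, n_f = len(model.vertices), len(model.triangles)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"comment surface={model.surface_tag} phase={model.phase}\n"
        f"element vertex {n_v}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {n_f}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(model.vertices, dtype="<f8").tobytes())
            face = np.empty(n_f, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            face["n"] = 3
            face["idx"] = model.triangles
            fh.write(face.tobytes())
        else:
            for v in model.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n".encode("ascii"))
            for t in model.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n".encode("ascii"))


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    import trimesh

    mesh = trimesh.load(str(path), file_type="ply", process=False)
    meta: dict = {}
    for comment in mesh.metadata.get("ply_raw", {}).get("comments", []) or []:
        for part in str(comment).split():
            if "=" in part:
                k, v = part.split("=", 1)
                meta[k] = v
    return (
        np.asarray(mesh.vertices, dtype=float),
        np.asarray(mesh.faces, dtype=np.int64),
        meta,
    )


# ------------------------------------------------------- legacy VTK

def _write_vtk(path: Path, model: SurfaceModel) -> None:
    n_v, n_f = len(model.vertices), len(model.triangles)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"surface={model.surface_tag} phase={model.phase}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n_v} double\n")
        for v in model.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {n_f} {4 * n_f}\n")
        for t in model.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_vtk(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    lines = Path(path).read_text().splitlines()
    meta: dict = {}
    i = 0
    try:
        if not lines[0].startswith("# vtk DataFile"):
            raise MeshParseError(f"{path}:1: not a legacy VTK file")
        for part in lines[1].split():
            if "=" in part:
                k, v = part.split("=", 1)
                meta[k] = v
        while not lines[i].startswith("POINTS"):
            i += 1
        n_v = int(lines[i].split()[1])
        coords: list[float] = []
        i += 1
        while len(coords) < 3 * n_v:
            coords.extend(float(x) for x in lines[i].split())
            i += 1
        verts = np.array(coords, dtype=float).reshape(n_v, 3)
        while not lines[i].startswith("POLYGONS"):
            i += 1
        n_f = int(lines[i].split()[1])
        tris = []
        for j in range(n_f):
            vals = [int(x) for x in lines[i + 1 + j].split()]
            if vals[0] != 3:
                raise MeshParseError(f"{path}:{i + 2 + j}: only triangles supported")
            tris.append(vals[1:4])
    except (IndexError, ValueError) as exc:
        if isinstance(exc, MeshParseError):
            raise
        raise MeshParseError(f"{path}:{i + 1}: malformed legacy VTK polydata") from exc
    return verts, np.array(tris, dtype=np.int64).reshape(-1, 3), meta


def write_mesh(path, model: SurfaceModel, binary: bool = False) -> None:
    """Write a surface mesh as PLY (.ply) or legacy-VTK polydata (.vtk)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply(path, model, binary)
    elif path.suffix.lower() == ".vtk":
        _write_vtk(path, model)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")


def read_mesh(path, surface_tag: Optional[str] = None, phase: Optional[str] = None) -> SurfaceModel:
    """Read a PLY or legacy-VTK mesh.

    Surface tag and phase are taken from the arguments, else from the
    file's own metadata comment, else from the
    ``*_<ED|ES>_<endo|epi>`` naming convention.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        verts, tris, meta = _read_ply(path)
    elif path.suffix.lower() == ".vtk":
        verts, tris, meta = _read_vtk(path)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    name_phase, name_tag = _infer_tags(path)
    return SurfaceModel(
        vertices=verts,
        triangles=tris,
        surface_tag=surface_tag or meta.get("surface") or name_tag or "endo",
        phase=phase or meta.get("phase") or name_phase or "ED",
    )


# ---------------------------------------------------------- landmarks

_LM_REQUIRED = ("apical_centroid", "basal_centroid", "rv_insertions", "convention")


def write_landmarks(path, landmarks: LandmarkSet, extras: Optional[dict] = None) -> None:
    """Write a landmark set to JSON (unknown keys in ``extras`` preserved)."""
    doc = dict(extras or {})
    doc.update(
        {
            "apical_centroid": [float(x) for x in landmarks.apical_centroid],
            "basal_centroid": [float(x) for x in landmarks.basal_centroid],
            "rv_insertions": [
                {"xyz": [float(x) for x in p], "label": lbl}
                for p, lbl in landmarks.rv_insertions
            ],
            "convention": landmarks.convention,
        }
    )
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_landmarks(path, with_extras: bool = False):
    """Read a landmark set from JSON with strict schema validation."""
    doc = json.loads(Path(path).read_text())
    for key in _LM_REQUIRED:
        if key not in doc:
            raise ValueError(f"landmark file {path}: missing required field {key!r}")
    ins = []
    for item in doc["rv_insertions"]:
        if "xyz" not in item:
            raise ValueError(f"landmark file {path}: rv_insertion missing 'xyz'")
        ins.append((np.asarray(item["xyz"], dtype=float), item.get("label")))
    lm = LandmarkSet(
        apical_centroid=np.asarray(doc["apical_centroid"], dtype=float),
        basal_centroid=np.asarray(doc["basal_centroid"], dtype=float),
        rv_insertions=tuple(ins),
        convention=doc["convention"],
    )
    if with_extras:
        extras = {k: v for k, v in doc.items() if k not in _LM_REQUIRED}
        return lm, extras
    return lm


# ------------------------------------------------------------ volumes

def write_volume(path, vol: ImageVolume) -> None:
    """Write an image volume as NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha)."""
    path = Path(path)
    if path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        img.SetDirection(tuple(float(d) for d in vol.direction.ravel()))
        sitk.WriteImage(img, str(path))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = vol.direction @ np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name!r}")


def read_volume(path) -> ImageVolume:
    """Read a NIfTI-1 or MetaImage volume, honoring spacing/origin/direction."""
    path = Path(path)
    if path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
        direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        m = img.affine[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        direction = m / spacing
        origin = img.affine[:3, 3]
    else:
        raise ValueError(f"unsupported volume format: {path.name!r}")
    if np.abs(direction @ direction.T - np.eye(3)).max() > 1e-6:
        raise ValueError(f"{path}: non-orthonormal direction matrix")
    return ImageVolume(data=data, spacing=spacing, origin=origin, direction=direction)
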