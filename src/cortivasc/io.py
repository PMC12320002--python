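"""Volume and surface I/O.

Volumes go through nibabel (NIfTI, any affine-carrying format nibabel
reads).  Surfaces are read/written as GIFTI (.gii, the standard surface
exchange format) or as a minimal plain-text format: a header line
``n_vertices n_faces`` followed by one ``x y z`` line per vertex and one
``i j k`` (0-based) line per face.
"""

from __future__ import annotations

import pathlib

import nibabel as nib
import numpy as np

from .surfaces import SurfaceMesh

__all__ = ["load_volume", "save_volume", "load_surface", "save_surface"]


def load_volume(path):
    """Load a volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), str(path))


def load_surface(path, surface_label: str = "pial") -> SurfaceMesh:
    path = pathlib.Path(path)
    if path.suffix == ".gii" or str(path).endswith(".surf.gii"):
        img = nib.load(str(path))
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return SurfaceMesh(np.asarray(verts, dtype=float), np.asarray(faces), surface_label)
    with open(path) as fh:
        n_v, n_f = (int(x) for x in fh.readline().split())
        verts = np.loadtxt(fh, max_rows=n_v, ndmin=2)
        faces = np.loadtxt(fh, max_rows=n_f, dtype=np.int64, ndmin=2)
    return SurfaceMesh(verts, faces, surface_label)


def save_surface(path, mesh: SurfaceMesh) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".gii" or str(path).endswith(".surf.gii"):
        coords = nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
        tris = nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
        nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))
        return
    with open(path, "w") as fh:
        fh.write(f"{len(mesh.vertices)} {len(mesh.faces)}\n")
        np.savetxt(fh, mesh.vertices, fmt="%.9g")
        np.savetxt(fh, mesh.faces, fmt="%d")
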