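"""Cortical surface normals and the orientation angle theta_B0.

theta_B0 is the angle between the cortical surface normal and the main
magnetic field direction, folded into [0, 90] degrees (the sign of the
normal carries no information).  Per-face angles computed on a triangulated
surface are mapped into voxel space by assigning each gray-matter ribbon
voxel the angle of the face whose centroid is nearest to the voxel centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "OrientationVolume",
    "face_normals",
    "face_centroids",
    "theta_b0",
    "midthickness",
    "voxelize_theta",
    "sample_uniform_sphere_thetas",
]

DEGENERATE_AREA_MM2 = 1e-12


@dataclass
class SurfaceMesh:
    """Triangulated cortical boundary in world millimetres.

    vertices: (n, 3) float array; faces: (m, 3) int array of 0-based vertex
    indices; surface_label one of {"pial", "white", "mid"}.
    """

    vertices: np.ndarray
    faces: np.ndarray
    surface_label: str = "pial"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class OrientationVolume:
    """Per-voxel theta_B0 in degrees; NaN outside the cortical ribbon."""

    data: np.ndarray
    affine: np.ndarray
    b0_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        vals = self.data[np.isfinite(self.data)]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 90 + 1e-9):
            raise ValueError("orientation values must lie in [0, 90] degrees")


def face_centroids(mesh: SurfaceMesh) -> np.ndarray:
    return mesh.vertices[mesh.faces].mean(axis=1)


def face_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face unit normals from the triangle edge cross product.

    The orientation follows the mesh winding (consistent and outward for
    the closed meshes produced by the phantom).  A degenerate triangle
    (area below ``DEGENERATE_AREA_MM2``) raises, naming the face.
    """
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norms
    bad = np.flatnonzero(areas <= DEGENERATE_AREA_MM2)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) triangle at face index {int(bad[0])}")
    return cross / norms[:, None]


def theta_b0(normals, b0_axis) -> np.ndarray:
    """Angle (degrees, [0, 90]) between surface normals and the B0 axis.

    The absolute dot product folds the angle: flipping the normal leaves
    theta_B0 unchanged.
    """
    n = np.atleast_2d(np.asarray(normals, dtype=float))
    b = np.asarray(b0_axis, dtype=float)
    nb = np.linalg.norm(b)
    nn = np.linalg.norm(n, axis=1)
    if nb == 0 or np.any(nn == 0):
        raise ValueError("zero vector has no direction")
    cosang = np.clip(np.abs(n @ b) / (nn * nb), 0.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    return out if np.asarray(normals).ndim > 1 else float(out[0])


def midthickness(pial: SurfaceMesh, white: SurfaceMesh) -> SurfaceMesh:
    """Vertex-wise average of matched pial/white meshes (same topology).

    The mid-thickness surface gives a single unambiguous theta_B0 per
    cortical column, which is what per-voxel analyses consume.
    """
    if pial.vertices.shape != white.vertices.shape or not np.array_equal(pial.faces, white.faces):
        raise ValueError("pial and white meshes must share topology for midthickness")
    return SurfaceMesh(0.5 * (pial.vertices + white.vertices), pial.faces.copy(), "mid")


def voxelize_theta(
    mesh: SurfaceMesh,
    per_face_theta: np.ndarray,
    affine: np.ndarray,
    shape: tuple[int, int, int],
    ribbon_gm_mask: np.ndarray,
    b0_axis=(0.0, 0.0, 1.0),
) -> OrientationVolume:
    """Map per-face theta_B0 onto ribbon voxels by nearest face centroid.

    Every gray-matter voxel receives the angle of the face whose centroid
    is nearest (world mm) to the voxel centre; all other voxels are NaN.
    """
    per_face_theta = np.asarray(per_face_theta, dtype=float)
    if per_face_theta.shape[0] != mesh.n_faces:
        raise ValueError("per_face_theta length must match the number of faces")
    gm = np.asarray(ribbon_gm_mask, dtype=bool)
    if gm.shape != tuple(shape):
        raise ValueError("ribbon mask shape does not match the reference grid")
    if not gm.any():
        raise ValueError("ribbon contains no gray-matter voxels")

    centroids = face_centroids(mesh)
    ijk = np.argwhere(gm)
    centers = apply_affine(np.asarray(affine, dtype=float), ijk)

    lo = centers.min(axis=0) - 1e-9
    hi = centers.max(axis=0) + 1e-9
    if np.any(centroids.max(axis=0) < lo) or np.any(centroids.min(axis=0) > hi):
        raise ValueError("mesh lies entirely outside the reference grid")

    tree = cKDTree(centroids)
    _, nearest = tree.query(centers, workers=-1)
    out = np.full(shape, np.nan, dtype=np.float32)
    out[tuple(ijk.T)] = per_face_theta[nearest]
    return OrientationVolume(out, np.asarray(affine, dtype=float), tuple(b0_axis))


def sample_uniform_sphere_thetas(n: int, seed: int, b0_axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """theta_B0 of ``n`` uniformly random surface normals (degrees).

    For isotropically distributed normals the folded angle follows the
    sine density, CDF(theta) = 1 - cos(theta) on [0, 90] degrees — the
    orientation histogram a spherical cortex produces, and the reason the
    analysis bins by equal voxel count rather than equal angular width.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return theta_b0(v, b0_axis)
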