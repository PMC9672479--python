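"""Mask-only 3D shape descriptors (14 features).

Surface quantities come from a marching-cubes mesh of the binary mask in
physical (mm) coordinates; axis lengths come from a principal-component
decomposition of the voxel coordinates; diameters are maximal pairwise
distances over convex-hull vertices of the surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

__all__ = ["shape_features"]


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing)  # undo the pad offset
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10 and points.shape[1] <= 3:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (flat) point set: brute force below
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _planar_diameter(coords: np.ndarray, group_axis: int) -> float:
    """Max in-plane diameter over slabs perpendicular to ``group_axis``."""
    other = [a for a in range(3) if a != group_axis]
    best = 0.0
    for v in np.unique(coords[:, group_axis]):
        pts = coords[coords[:, group_axis] == v][:, other]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> dict[str, float]:
    """14 shape descriptors of a (z, y, x) binary mask; intensity-free."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        raise ValueError("shape: mask must contain at least 2 voxels")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))

    verts, faces = _mesh(mask, spacing)
    area = float(mesh_surface_area(verts, faces))
    mesh_vol = _mesh_volume(verts, faces)
    voxel_vol = float(mask.sum() * voxel_volume)
    vol = mesh_vol if mesh_vol > 0 else voxel_vol

    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    cov = np.cov(coords.T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]  # lambda1 >= lambda2 >= lambda3
    eig = np.maximum(eig, 0.0)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    # boundary voxels suffice for diameter computations
    from scipy.ndimage import binary_erosion
    boundary = mask & ~binary_erosion(mask)
    bcoords = np.argwhere(boundary).astype(float) * np.asarray(spacing)

    return {
        "MeshVolume": mesh_vol,
        "VoxelVolume": voxel_vol,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / vol,
        "Sphericity": float((36 * np.pi * vol**2) ** (1 / 3) / area),
        "Maximum3DDiameter": _max_pairwise(bcoords),
        "Maximum2DDiameterSlice": _planar_diameter(bcoords, 0),   # (y, x) plane
        "Maximum2DDiameterColumn": _planar_diameter(bcoords, 1),  # (z, x) plane
        "Maximum2DDiameterRow": _planar_diameter(bcoords, 2),     # (z, y) plane
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
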