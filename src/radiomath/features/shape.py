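"""Shape features of a binary ROI mask (14 features).

Surface quantities come from a marching-cubes triangulation of the
binary mask at iso-level 0.5 (so the surface passes midway between ROI
and background voxels): surface area is the summed triangle area, mesh
volume the summed signed tetrahedron volume.  Sphericity compares the
ROI surface to that of the equal-volume sphere,
``(36 pi V^2)^(1/3) / A``, and is 1 for a perfect ball.

Axis lengths derive from the principal components of the physical voxel
centre coordinates.  Each voxel is treated as a small uniform block, so
``spacing^2 / 12`` is added per axis before eigendecomposition; this
keeps single-voxel and collinear ROIs well defined (a lone voxel is
isotropic: Elongation = Flatness = 1) and makes a 1x1x10 line of unit
voxels come out at Elongation exactly 0.1.

Maximum diameters are the largest pairwise Euclidean distances between
ROI voxel centres, overall (3D) and restricted to planes of constant
first / second / third array axis (Slice / Column / Row).
"""

from __future__ import annotations

import numpy as np
from skimage.measure import marching_cubes

from .base import RoiSample

SHAPE_DIAMETER_AXES = {"Slice": 0, "Column": 1, "Row": 2}


def _binary_mask(sample: RoiSample) -> np.ndarray:
    coords = sample.coords
    lo = coords.min(axis=0)
    shape = coords.max(axis=0) - lo + 3
    mask = np.zeros(shape, dtype=bool)
    c = coords - lo + 1
    mask[c[:, 0], c[:, 1], c[:, 2]] = True
    return mask


def mesh_volume_area(mask: np.ndarray, spacing: np.ndarray) -> tuple[float, float]:
    """Mesh volume and surface area of a padded binary mask."""
    verts, faces, _, _ = marching_cubes(
        mask.astype(np.float64), level=0.5, spacing=tuple(spacing)
    )
    verts = verts.astype(np.float64)
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    area = float(0.5 * np.sqrt((cross**2).sum(axis=1)).sum())
    volume = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)
    return volume, area


def _boundary_points(sample: RoiSample) -> np.ndarray:
    """Physical coordinates of ROI voxels with at least one 6-neighbour outside."""
    mask = _binary_mask(sample)
    interior = np.ones_like(mask)
    for axis in range(3):
        interior &= np.roll(mask, 1, axis) & np.roll(mask, -1, axis)
    boundary = mask & ~interior
    idx = np.argwhere(boundary) - 1 + sample.coords.min(axis=0)
    return idx, idx * sample.spacing


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def shape_features(sample: RoiSample) -> dict[str, float]:
    """Compute the 14 shape features of one ROI."""
    spacing = sample.spacing
    mask = _binary_mask(sample)
    volume, area = mesh_volume_area(mask, spacing)
    voxel_volume = sample.n_voxels * sample.voxel_volume

    out = {
        "shape_MeshVolume": volume,
        "shape_VoxelVolume": voxel_volume,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / volume,
        "shape_Sphericity": (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area,
    }

    idx, pts = _boundary_points(sample)
    out["shape_Maximum3DDiameter"] = _max_pairwise(pts)
    for name, axis in SHAPE_DIAMETER_AXES.items():
        best = 0.0
        plane = [a for a in range(3) if a != axis]
        for value in np.unique(idx[:, axis]):
            best = max(best, _max_pairwise(pts[idx[:, axis] == value][:, plane]))
        out[f"shape_Maximum2DDiameter{name}"] = best

    centers = sample.coords * spacing
    cov = np.cov(centers, rowvar=False, ddof=0).reshape(3, 3)
    cov += np.diag(spacing**2 / 12.0)
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)  # ascending
    least, minor, major = eigvals
    out["shape_MajorAxisLength"] = 4.0 * np.sqrt(major)
    out["shape_MinorAxisLength"] = 4.0 * np.sqrt(minor)
    out["shape_LeastAxisLength"] = 4.0 * np.sqrt(least)
    out["shape_Elongation"] = float(np.sqrt(minor / major))
    out["shape_Flatness"] = float(np.sqrt(least / major))
    return out
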