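"""Voxel-grid helpers shared across the pipeline.

Internally every map lives on a vector of in-mask voxels with an explicit
``voxel_index`` (N x 3 integer array of 0-based grid coordinates, C-order).
World coordinates enter only through the NIfTI affine at report boundaries;
hemispheres are split at the affine x = 0 plane.
"""

from __future__ import annotations

import numpy as np

VOXEL_MM = 3.0


def default_affine(grid_shape: tuple[int, int, int], voxel_mm: float = VOXEL_MM) -> np.ndarray:
    """RAS affine with isotropic voxels, centred so x = 0 splits the grid."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(grid_shape, float) - 1) / 2.0
    return aff


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Binary mask of the ellipsoid inscribed in the grid (a brain stand-in)."""
    centre = (np.asarray(grid_shape, float) - 1) / 2.0
    semi = np.maximum(np.asarray(grid_shape, float) / 2.0, 0.5)
    ii, jj, kk = np.indices(grid_shape)
    r2 = sum(((ax - c) / s) ** 2 for ax, c, s in zip((ii, jj, kk), centre, semi))
    return r2 <= 1.0


def mask_coordinates(mask: np.ndarray) -> np.ndarray:
    """In-mask voxel coordinates in C-order (the canonical voxel ordering)."""
    return np.argwhere(mask)


def coords_to_flat(coords: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords))
    return np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), grid_shape)


def flat_to_coords(flat: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    return np.column_stack(np.unravel_index(np.asarray(flat), grid_shape))


def scatter_to_grid(values: np.ndarray, voxel_index: np.ndarray,
                    grid_shape: tuple[int, int, int], fill: float = 0.0) -> np.ndarray:
    """Place a per-voxel vector back onto the 3-D grid."""
    out = np.full(grid_shape, fill, dtype=float)
    out[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return out


def gather_from_grid(volume: np.ndarray, voxel_index: np.ndarray) -> np.ndarray:
    return volume[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]]


def hemisphere_labels(voxel_index: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """'left'/'right' per voxel from the sign of world x (RAS: x<0 is left)."""
    world_x = (affine[:3, :3] @ voxel_index.T)[0] + affine[0, 3]
    return np.where(world_x < 0, "left", "right")
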