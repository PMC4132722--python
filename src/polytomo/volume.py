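"""Low-level 3D grid operations shared by the simulator, averaging and place-back.

Conventions
-----------
Arrays are indexed ``[ix, iy, iz]``; the physical coordinate of a voxel is
``origin_nm + index * voxel_size``.  Reference maps are centred
(``origin = -(n-1)/2 * voxel``); tomograms have their origin at voxel (0,0,0).
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["rotate_volume", "embed_volume", "centered_origin"]


def centered_origin(shape, voxel_size: float) -> np.ndarray:
    """Physical coordinate (nm) of voxel (0,0,0) for a centred grid."""
    return -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * voxel_size


def rotate_volume(vol: np.ndarray, rot_matrix: np.ndarray, order: int = 1) -> np.ndarray:
    """Rotate a centred volume by R: output(x) = input(R^-1 x), x about the grid centre."""
    r_inv = np.asarray(rot_matrix, dtype=float).T
    c = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0
    offset = c - r_inv @ c
    return ndimage.affine_transform(
        vol, r_inv, offset=offset, order=order, prefilter=False, mode="constant", cval=0.0
    )


def embed_volume(
    canvas: np.ndarray,
    vol: np.ndarray,
    voxel_size: float,
    rot_matrix: np.ndarray,
    position_nm: np.ndarray,
    order: int = 1,
) -> None:
    """Add a rotated, translated copy of a centred volume into ``canvas`` in place.

    canvas(x) += vol(R^-1 (x - t)) with x in nm; resampling is trilinear by
    default and restricted to a window around the insertion point.
    """
    r_inv = np.asarray(rot_matrix, dtype=float).T
    position_nm = np.asarray(position_nm, dtype=float)
    origin = centered_origin(vol.shape, voxel_size)

    centre_idx = position_nm / voxel_size
    halfw = int(np.ceil(np.linalg.norm(vol.shape) / 2.0)) + 2
    lo = np.maximum(np.floor(centre_idx).astype(int) - halfw, 0)
    hi = np.minimum(np.floor(centre_idx).astype(int) + halfw + 1, canvas.shape)
    if np.any(lo >= hi):
        return

    # vol index = R^-1 @ (canvas index) + b, with b absorbing translation and origins
    b = (-(r_inv @ position_nm) - origin) / voxel_size
    offset = r_inv @ lo + b
    shape = tuple(hi - lo)
    patch = ndimage.affine_transform(
        vol, r_inv, offset=offset, output_shape=shape, order=order,
        prefilter=False, mode="constant", cval=0.0,
    )
    canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += patch
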