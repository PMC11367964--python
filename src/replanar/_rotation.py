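"""Axial-plane rotation as an explicit sparse linear operator.

Rotating a volume about the z axis is needed both by the multi-angle
forward model and by iterative reconstruction.  Implementing the rotation
as a sparse matrix of bilinear-interpolation weights (gather form) makes
its exact adjoint available for free as the transpose — which is what lets
the projector/back-projector pair be a truly matched pair instead of the
approximately-adjoint pair one gets from a generic image-rotation routine.

The operator acts on flattened (ny, nx) planes; a volume is rotated by
applying it to all z slices at once.  Out-of-grid source samples are
treated as zero.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse

__all__ = ["plane_rotation_matrix", "rotate_volume_z"]


@lru_cache(maxsize=512)
def plane_rotation_matrix(ny: int, nx: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse (ny*nx, ny*nx) operator rotating image content by ``angle_deg``.

    Rotation is about the plane centre ((ny-1)/2, (nx-1)/2) with bilinear
    interpolation; a zero angle yields the exact identity.
    """
    theta = np.deg2rad(angle_deg % 360.0)
    c, s = np.cos(theta), np.sin(theta)
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0

    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    u = iy.ravel() - cy0
    v = ix.ravel() - cx0
    # source coordinates: inverse rotation applied to output coordinates
    ys = c * u + s * v + cy0
    xs = -s * u + c * v + cx0

    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    fy = ys - y0
    fx = xs - x0

    rows, cols, vals = [], [], []
    out_idx = np.arange(ny * nx)
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            yy = y0 + dy
            xx = x0 + dx
            w = wy * wx
            ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx) & (w > 0)
            rows.append(out_idx[ok])
            cols.append((yy * nx + xx)[ok])
            vals.append(w[ok])
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx))
    return mat


def rotate_volume_z(vol: np.ndarray, angle_deg: float,
                    adjoint: bool = False) -> np.ndarray:
    """Rotate a (nz, ny, nx) volume about z; ``adjoint`` applies the transpose."""
    nz, ny, nx = vol.shape
    mat = plane_rotation_matrix(ny, nx, float(angle_deg))
    if adjoint:
        mat = mat.T
    out = mat @ vol.reshape(nz, ny * nx).T
    return np.ascontiguousarray(out.T).reshape(nz, ny, nx)
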