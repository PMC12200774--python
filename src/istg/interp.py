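"""Vectorized trilinear sampling of multi-component voxel grids.

One gather-based routine serves tensor (6-component), displacement
(3-component) and scalar (1-component) volumes alike, with per-component
constant fill outside the grid or clamp-to-edge extension.  This is the
inner loop of both the registration cost function and resampling; a
numba-compiled kernel is used when available, with a pure-NumPy
implementation as fallback.
"""

from __future__ import annotations

import numpy as np

__all__ = ["trilinear_sample"]

_CORNERS = [(dx, dy, dz) for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)]

try:
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _trilinear_kernel(data, vox, cval, clamp):  # pragma: no cover - jitted
        n = vox.shape[0]
        nx, ny, nz, nc = data.shape
        out = np.empty((n, nc))
        for i in range(n):
            x, y, z = vox[i, 0], vox[i, 1], vox[i, 2]
            inside = (
                0.0 <= x <= nx - 1 and 0.0 <= y <= ny - 1 and 0.0 <= z <= nz - 1
            )
            if not inside and not clamp:
                for c in range(nc):
                    out[i, c] = cval[c]
                continue
            if x < 0.0:
                x = 0.0
            elif x > nx - 1:
                x = nx - 1.0
            if y < 0.0:
                y = 0.0
            elif y > ny - 1:
                y = ny - 1.0
            if z < 0.0:
                z = 0.0
            elif z > nz - 1:
                z = nz - 1.0
            fx, fy, fz = int(x), int(y), int(z)
            if fx > nx - 2:
                fx = nx - 2
            if fy > ny - 2:
                fy = ny - 2
            if fz > nz - 2:
                fz = nz - 2
            wx, wy, wz = x - fx, y - fy, z - fz
            for c in range(nc):
                c00 = data[fx, fy, fz, c] * (1 - wz) + data[fx, fy, fz + 1, c] * wz
                c01 = data[fx, fy + 1, fz, c] * (1 - wz) + data[fx, fy + 1, fz + 1, c] * wz
                c10 = data[fx + 1, fy, fz, c] * (1 - wz) + data[fx + 1, fy, fz + 1, c] * wz
                c11 = data[fx + 1, fy + 1, fz, c] * (1 - wz) + data[fx + 1, fy + 1, fz + 1, c] * wz
                out[i, c] = (
                    (c00 * (1 - wy) + c01 * wy) * (1 - wx)
                    + (c10 * (1 - wy) + c11 * wy) * wx
                )
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _trilinear_numpy(data, v, cval):
    shape = np.array(data.shape[:3])
    C = data.shape[3]
    if cval is None:
        v = np.clip(v, 0.0, (shape - 1).astype(float))
    f = np.floor(v).astype(np.int64)
    f = np.minimum(f, shape - 2)
    f = np.maximum(f, 0)
    w = v - f
    out = np.zeros((v.shape[0], C), dtype=float)
    if cval is not None:
        inside = np.all((v >= 0.0) & (v <= (shape - 1)), axis=1)
    for dx, dy, dz in _CORNERS:
        wx = w[:, 0] if dx else 1.0 - w[:, 0]
        wy = w[:, 1] if dy else 1.0 - w[:, 1]
        wz = w[:, 2] if dz else 1.0 - w[:, 2]
        out += (wx * wy * wz)[:, None] * data[f[:, 0] + dx, f[:, 1] + dy, f[:, 2] + dz, :]
    if cval is not None:
        out[~inside] = np.asarray(cval, dtype=float)
    return out


def trilinear_sample(
    data: np.ndarray,
    vox: np.ndarray,
    cval: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``data`` (X, Y, Z, C) at fractional voxel coordinates.

    Parameters
    ----------
    data : float array, shape (X, Y, Z, C)
    vox : float array, shape (..., 3), 0-based voxel coordinates
    cval : length-C fill values for samples outside the grid, or ``None``
        to clamp coordinates to the grid edge instead.

    Returns
    -------
    float array of shape (..., C)
    """
    data = np.ascontiguousarray(data, dtype=float)
    vox = np.asarray(vox, dtype=float)
    lead = vox.shape[:-1]
    v = np.ascontiguousarray(vox.reshape(-1, 3))
    if _HAVE_NUMBA:
        if cval is None:
            out = _trilinear_kernel(data, v, np.zeros(data.shape[3]), True)
        else:
            out = _trilinear_kernel(
                data, v, np.ascontiguousarray(cval, dtype=float), False
            )
    else:
        out = _trilinear_numpy(data, v, cval)
    return out.reshape(*lead, data.shape[3])
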