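"""Fast trilinear interpolation kernel for PSF lookups.

The MAP grid search evaluates the PSF at a few hundred thousand points per
pattern; a compiled gather loop keeps the reconstruction interactive.  Falls
back to scipy.ndimage if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _trilinear_py(grid, fx, fy, fz, out):  # grid indexed [z, y, x]
    nz, ny, nx = grid.shape
    for k in range(fx.shape[0]):
        x, y, z = fx[k], fy[k], fz[k]
        if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1 or y > ny - 1 or z > nz - 1:
            out[k] = 0.0
            continue
        ix = int(x)
        iy = int(y)
        iz = int(z)
        if ix == nx - 1:
            ix -= 1
        if iy == ny - 1:
            iy -= 1
        if iz == nz - 1:
            iz -= 1
        tx = x - ix
        ty = y - iy
        tz = z - iz
        c00 = grid[iz, iy, ix] * (1 - tx) + grid[iz, iy, ix + 1] * tx
        c10 = grid[iz, iy + 1, ix] * (1 - tx) + grid[iz, iy + 1, ix + 1] * tx
        c01 = grid[iz + 1, iy, ix] * (1 - tx) + grid[iz + 1, iy, ix + 1] * tx
        c11 = grid[iz + 1, iy + 1, ix] * (1 - tx) + grid[iz + 1, iy + 1, ix + 1] * tx
        c0 = c00 * (1 - ty) + c10 * ty
        c1 = c01 * (1 - ty) + c11 * ty
        out[k] = c0 * (1 - tz) + c1 * tz


def _pattern_nll_py(grid, origin, voxel, pts, shots, counts, bg, out_nll, out_sphi):
    """Fused cross-entropy evaluation: for each candidate point, interpolate
    the PSF at (point - shot) for every shot and accumulate sum(Phi) and
    -sum(n_i ln Phi_i).  A zero model intensity at a positive count makes the
    point impossible (inf)."""
    nz, ny, nx = grid.shape
    n_shots = shots.shape[0]
    total = 0.0
    for i in range(n_shots):
        total += counts[i]
    for m in range(pts.shape[0]):
        sphi = 0.0
        nlog = 0.0
        ok = True
        for i in range(n_shots):
            x = (pts[m, 0] - shots[i, 0] - origin[0]) / voxel[0]
            y = (pts[m, 1] - shots[i, 1] - origin[1]) / voxel[1]
            z = (pts[m, 2] - shots[i, 2] - origin[2]) / voxel[2]
            if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1 or y > ny - 1 or z > nz - 1:
                v = 0.0
            else:
                ix = int(x)
                iy = int(y)
                iz = int(z)
                if ix == nx - 1:
                    ix -= 1
                if iy == ny - 1:
                    iy -= 1
                if iz == nz - 1:
                    iz -= 1
                tx = x - ix
                ty = y - iy
                tz = z - iz
                c00 = grid[iz, iy, ix] * (1 - tx) + grid[iz, iy, ix + 1] * tx
                c10 = grid[iz, iy + 1, ix] * (1 - tx) + grid[iz, iy + 1, ix + 1] * tx
                c01 = grid[iz + 1, iy, ix] * (1 - tx) + grid[iz + 1, iy, ix + 1] * tx
                c11 = grid[iz + 1, iy + 1, ix] * (1 - tx) + grid[iz + 1, iy + 1, ix + 1] * tx
                v = (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (c01 * (1 - ty) + c11 * ty) * tz
                if v < 0.0:
                    v = 0.0
            v += bg
            sphi += v
            if counts[i] > 0.0:
                if v <= 0.0:
                    ok = False
                else:
                    nlog += counts[i] * np.log(v)
        out_sphi[m] = sphi
        if not ok or sphi <= 0.0:
            out_nll[m] = np.inf
        else:
            out_nll[m] = -nlog + total * np.log(sphi)


if _HAVE_NUMBA:
    _trilinear = njit(cache=True, fastmath=True)(_trilinear_py)
    _pattern_nll = njit(cache=True, fastmath=True)(_pattern_nll_py)
else:  # pragma: no cover
    _trilinear = None
    _pattern_nll = None


def pattern_nll(grid: np.ndarray, origin, voxel, pts: np.ndarray, shots: np.ndarray,
                counts: np.ndarray, background: float = 0.0):
    """Cross-entropy NLL and summed PSF intensity per candidate point.

    Returns (nll, sum_phi) arrays of length len(pts).  ``counts`` and
    ``shots`` cover the illuminated slots only.
    """
    pts = np.ascontiguousarray(pts, dtype=np.float64)
    shots = np.ascontiguousarray(shots, dtype=np.float64)
    counts = np.ascontiguousarray(counts, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    voxel = np.asarray(voxel, dtype=np.float64)
    out_nll = np.empty(len(pts))
    out_sphi = np.empty(len(pts))
    fn = _pattern_nll if _pattern_nll is not None else _pattern_nll_py
    fn(grid, origin, voxel, pts, shots, counts, background, out_nll, out_sphi)
    return out_nll, out_sphi


def trilinear(grid: np.ndarray, frac_idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``grid`` [z, y, x] at fractional indices.

    ``frac_idx`` is (M, 3) in (x, y, z) index units; out-of-grid points
    return 0.
    """
    fx = np.ascontiguousarray(frac_idx[:, 0], dtype=np.float64)
    fy = np.ascontiguousarray(frac_idx[:, 1], dtype=np.float64)
    fz = np.ascontiguousarray(frac_idx[:, 2], dtype=np.float64)
    out = np.empty(len(fx))
    if _trilinear is not None:
        _trilinear(grid, fx, fy, fz, out)
    else:  # pragma: no cover
        from scipy.ndimage import map_coordinates

        out[:] = map_coordinates(grid, np.stack([fz, fy, fx]), order=1, mode="constant", cval=0.0)
        oob = (
            (fx < 0) | (fy < 0) | (fz < 0)
            | (fx > grid.shape[2] - 1) | (fy > grid.shape[1] - 1) | (fz > grid.shape[0] - 1)
        )
        out[oob] = 0.0
    return out
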