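"""Low-level grid/vector-field numerics shared by the transport solver.

Conventions (used everywhere in the package):

* voxel centers sit at integer coordinates ``0 .. N-1`` along each axis;
* maps and displacement fields are arrays of shape ``(*grid, 3)`` whose last
  axis indexes the spatial component, in voxel units;
* spatial derivatives use central differences in the interior and one-sided
  differences at the boundary faces.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Coordinate field x -> x, shape ``(*shape, 3)``."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def grad_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Central-difference derivative along one axis (one-sided at the faces)."""
    n = a.shape[axis]
    out = np.empty_like(a)
    if n == 1:
        out[...] = 0.0
        return out
    sl = [slice(None)] * a.ndim

    def s(i):
        sl2 = list(sl)
        sl2[axis] = i
        return tuple(sl2)

    out[s(slice(1, -1))] = (a[s(slice(2, None))] - a[s(slice(None, -2))]) * 0.5
    out[s(0)] = a[s(1)] - a[s(0)]
    out[s(-1)] = a[s(-1)] - a[s(-2)]
    return out


def grad_axis_adjoint(w: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`grad_axis` (exact transpose of the stencil)."""
    n = w.shape[axis]
    out = np.zeros_like(w)
    if n == 1:
        return out
    sl = [slice(None)] * w.ndim

    def s(i):
        sl2 = list(sl)
        sl2[axis] = i
        return tuple(sl2)

    if n > 2:
        out[s(slice(2, None))] += w[s(slice(1, -1))] * 0.5
        out[s(slice(None, -2))] -= w[s(slice(1, -1))] * 0.5
    out[s(0)] -= w[s(0)]
    out[s(1)] += w[s(0)]
    out[s(-1)] += w[s(-1)]
    out[s(-2)] -= w[s(-1)]
    return out


def jacobian(f: np.ndarray) -> np.ndarray:
    """Jacobian field J[..., a, b] = d f_a / d x_b of a map ``(*grid, 3)``."""
    grid = f.shape[:-1]
    J = np.empty(grid + (3, 3), dtype=np.float64)
    for a in range(3):
        for b in range(3):
            J[..., a, b] = grad_axis(f[..., a], b)
    # a singleton axis carries the identity map by convention; its diagonal
    # entry must be 1 (not 0) or the determinant degenerates on 2D problems
    for b in range(3):
        if grid[b] == 1:
            J[..., b, b] = 1.0
    return J


def det3(J: np.ndarray) -> np.ndarray:
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    d, e, f = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    g, h, i = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)


def cof3(J: np.ndarray) -> np.ndarray:
    """Cofactor matrix field: cof(J) = det(J) * inv(J).T, division-free."""
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    d, e, f = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    g, h, i = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    C = np.empty_like(J)
    C[..., 0, 0] = e * i - f * h
    C[..., 0, 1] = -(d * i - f * g)
    C[..., 0, 2] = d * h - e * g
    C[..., 1, 0] = -(b * i - c * h)
    C[..., 1, 1] = a * i - c * g
    C[..., 1, 2] = -(a * h - b * g)
    C[..., 2, 0] = b * f - c * e
    C[..., 2, 1] = -(a * f - c * d)
    C[..., 2, 2] = a * e - b * d
    return C


def sample_trilinear(vol: np.ndarray, coords: np.ndarray, with_grad: bool = False):
    """Trilinear interpolation with the *exact* piecewise gradient.

    Coordinates are clamped to the grid, so samples never leave the domain
    (the clamped region contributes zero gradient, a valid subgradient for
    the solver's line search).
    """
    shape = vol.shape
    c = coords.reshape(-1, 3)
    idx = []
    frac = []
    clamped = []
    for ax in range(3):
        n = shape[ax]
        clamped.append((c[:, ax] < 0.0) | (c[:, ax] > n - 1.0))
        x = np.clip(c[:, ax], 0.0, n - 1.0)
        if n == 1:
            i0 = np.zeros(len(x), dtype=np.intp)
            fx = np.zeros_like(x)
        else:
            i0 = np.clip(np.floor(x).astype(np.intp), 0, n - 2)
            fx = x - i0
        idx.append(i0)
        frac.append(fx)
    i, j, k = idx
    fx, fy, fz = frac
    di = 1 if shape[0] > 1 else 0
    dj = 1 if shape[1] > 1 else 0
    dk = 1 if shape[2] > 1 else 0
    v000 = vol[i, j, k]
    v001 = vol[i, j, k + dk]
    v010 = vol[i, j + dj, k]
    v011 = vol[i, j + dj, k + dk]
    v100 = vol[i + di, j, k]
    v101 = vol[i + di, j, k + dk]
    v110 = vol[i + di, j + dj, k]
    v111 = vol[i + di, j + dj, k + dk]
    # collapse z, then y, then x
    c00 = v000 * (1 - fz) + v001 * fz
    c01 = v010 * (1 - fz) + v011 * fz
    c10 = v100 * (1 - fz) + v101 * fz
    c11 = v110 * (1 - fz) + v111 * fz
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    val = c0 * (1 - fx) + c1 * fx
    out_shape = coords.shape[:-1]
    if not with_grad:
        return val.reshape(out_shape)
    gx = c1 - c0
    gy = ((c01 - c00) * (1 - fx) + (c11 - c10) * fx)
    d00 = v001 - v000
    d01 = v011 - v010
    d10 = v101 - v100
    d11 = v111 - v110
    gz = (d00 * (1 - fy) + d01 * fy) * (1 - fx) + (d10 * (1 - fy) + d11 * fy) * fx
    grad = np.stack([gx, gy, gz], axis=-1)
    # the clamped interpolant is constant beyond the grid: its true derivative
    # along a clamped axis is zero, and reporting anything else stalls the
    # solver's line search
    for ax in range(3):
        grad[clamped[ax], ax] = 0.0
    return val.reshape(out_shape), grad.reshape(out_shape + (3,))


def sample_field(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample each component of a ``(*grid, 3)`` field at fractional coords."""
    out = np.empty(coords.shape, dtype=np.float64)
    for a in range(3):
        out[..., a] = sample_trilinear(field[..., a], coords)
    return out


def downsample_density(rho: np.ndarray) -> np.ndarray:
    """Block-average by 2 along every even axis; total mass is renormalized."""
    out = rho
    for ax in range(3):
        n = out.shape[ax]
        if n % 2 == 0 and n > 1:
            sh = list(out.shape)
            sh[ax] = n // 2
            sh.insert(ax + 1, 2)
            out = out.reshape(sh).mean(axis=ax + 1)
    return out * (rho.sum() / out.sum())


def upsample_field(u: np.ndarray, fine_shape: tuple[int, int, int]) -> np.ndarray:
    """Resample a displacement field to a finer grid, rescaling the voxel units."""
    coarse_shape = u.shape[:-1]
    coords = identity_grid(fine_shape)
    for ax in range(3):
        scale = coarse_shape[ax] / fine_shape[ax]
        coords[..., ax] = (coords[..., ax] + 0.5) * scale - 0.5
    out = sample_field(u, coords)
    for ax in range(3):
        out[..., ax] *= fine_shape[ax] / coarse_shape[ax]
    return out


def smooth_field(u: np.ndarray, sigma_voxels: float) -> np.ndarray:
    """Gaussian-smooth each component of a vector field (reflective boundary)."""
    out = np.empty_like(u)
    for a in range(3):
        out[..., a] = ndimage.gaussian_filter(u[..., a], sigma_voxels, mode="reflect")
    return out
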