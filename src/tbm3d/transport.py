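"""Mass-preserving optimal transport between tissue-density images.

Each subject image ``I_i`` is represented by the transport map ``f`` that
rearranges the population reference ``I_0`` into it at minimal quadratic
cost::

    f* = argmin_f  \\int ||f(x) - x||^2 I_0(x) dx
    s.t.           det(Df(x)) I_i(f(x)) = I_0(x)

The constraint says that ``f`` pushes the reference density forward onto the
subject density (mass preservation, "MP"); the cost picks the rearrangement
that moves the least mass.  The map, its displacement ``u = f - id`` and its
Jacobian determinant parameterize the subject in the *transport domain*,
where linear statistics become meaningful and any point can be inverted back
to an image (:func:`synthesize_image`).

Solver
------
Deterministic multiresolution scheme built from two classical ingredients:

1. *Iterated linearized transport* (a Moser / Dacorogna–Moser iteration).
   With the pullback ``sigma = det(Df) I_i(f)``, the MP constraint reads
   ``sigma = I_0``.  Linearizing a correction ``c = id + grad(phi)`` applied
   before ``f`` gives the elliptic equation

       div(sigma * grad(phi)) = I_0 - sigma,

   solved with a DCT-preconditioned conjugate-gradient method (Neumann
   boundary).  Composing ``f <- f o c`` and repeating drives the constraint
   residual down; every increment is a gradient field, so the accumulated
   map inherits the curl-free (Brenier) structure of the true optimal map.
   The inverse map is tracked through the same compositions, which makes
   later synthesis cheap and robust.

2. *Optional polish*: a short augmented-Lagrangian L-BFGS run on the
   displacement field minimizing transport cost plus the MP constraint
   (multiplier updates) plus a Jacobian-asymmetry penalty that vanishes on
   gradient maps.  Starting from the near-feasible, near-optimal Moser
   solution this trims the remaining cost without leaving the basin.

A triangular 1D-CDF-matching initialization (:func:`knothe_map`) is kept as
an optional warm start for very large displacements, but the default starts
from the identity, which proved as accurate and considerably more robust in
low-density background regions.

There is no stochastic component: identical inputs give identical maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage, optimize

from ._fields import (
    cof3,
    det3,
    downsample_density,
    grad_axis,
    grad_axis_adjoint,
    identity_grid,
    jacobian,
    sample_field,
    sample_trilinear,
    upsample_field,
)
from .prep import TissueImage

__all__ = [
    "SolverParams",
    "TransportMap",
    "TransportConvergenceError",
    "solve_transport",
    "mp_residual",
    "invert_map",
    "synthesize_image",
    "warp_density",
    "transport_cost",
    "knothe_map",
]


class TransportConvergenceError(RuntimeError):
    """Raised when the solver cannot meet its tolerance; carries the best map."""

    def __init__(self, message, best_map=None, residual=None):
        super().__init__(message)
        self.best_map = best_map
        self.residual = residual


@dataclass
class SolverParams:
    """Tunable solver settings (engineering choices, surfaced in metadata).

    Attributes
    ----------
    n_scales : maximum number of pyramid levels; coarser levels are built by
        block-averaging while every axis stays even and >= ``min_level_size``.
    max_iters : linearized-transport iterations per level.
    mp_tolerance : target relative L1 mass-preservation residual; iteration
        stops early once reached.
    sigma_floor : lower bound (on mean-1 normalized densities) for the
        elliptic coefficient, keeping the correction well-posed in the
        near-empty background.
    mobility_floor : density scale below which per-iteration corrections are
        damped; keeps the (unconstrained) empty background near the identity
        while leaving low-density blob tails mobile.
    extra_iters : iterations continued after the MP tolerance is first met;
        the global residual is insensitive to errors in low-mass tails, which
        keep improving during these.
    step_max : cap on the per-iteration correction, voxels.
    jac_floor : backtracking keeps ``det`` of every correction above this.
    cg_tol, cg_maxiter : conjugate-gradient controls for the elliptic solve.
    polish_iters : L-BFGS iterations of the final cost polish (0 disables).
    mp_weight, curl_weight : augmented-Lagrangian penalty weights used by
        the polish stage, on mean-1 normalized densities.
    init : "identity" (default) or "knothe" warm start at the coarsest level.
    """

    n_scales: int = 1
    max_iters: int = 60
    mp_tolerance: float = 1e-2
    sigma_floor: float = 0.02
    mobility_floor: float = 0.002
    extra_iters: int = 12
    step_max: float = 1.0
    jac_floor: float = 0.25
    cg_tol: float = 1e-5
    cg_maxiter: int = 30
    polish_iters: int = 0
    mp_weight: float = 5000.0
    curl_weight: float = 2.0
    init: str = "identity"
    min_level_size: int = 12

    def __post_init__(self):
        if min(self.n_scales, self.max_iters) < 1:
            raise ValueError("n_scales and max_iters must be >= 1")
        if min(self.mp_tolerance, self.sigma_floor, self.step_max, self.cg_tol) <= 0:
            raise ValueError("tolerances and bounds must be positive")
        if self.init not in ("identity", "knothe"):
            raise ValueError(f"unknown init mode {self.init!r}")


@dataclass
class TransportMap:
    """Optimal-transport map from reference coordinates to subject coordinates."""

    f: np.ndarray  # (*grid, 3), voxel units
    voxel_size_mm: tuple[float, float, float]
    cost: float  # sum_x I0 ||f - x||^2, voxel^2
    mp_res: float  # relative L1 MP constraint residual
    jac_det: np.ndarray  # det(Df), finite differences
    f_inv: np.ndarray | None = None  # tracked inverse map
    history: list = field(default_factory=list)  # residual record per level
    params: SolverParams | None = None

    @property
    def displacement(self) -> np.ndarray:
        return self.f - identity_grid(self.f.shape[:-1])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f.shape[:-1]


# ---------------------------------------------------------------------------
# triangular (Knothe-type) rearrangement: 1D CDF matching per axis
# ---------------------------------------------------------------------------

def _cum_mid(m: np.ndarray) -> np.ndarray:
    """Cumulative mass at voxel centers (midpoint rule), normalized to (0,1)."""
    c = np.cumsum(m, axis=-1) - 0.5 * m
    return c / np.sum(m, axis=-1, keepdims=True)


def _match_lines(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Per-line monotone rearrangement: positions in ``tgt`` attaining the same
    cumulative mass as each ``src`` voxel center.  Shapes ``(B, N)``."""
    n = src.shape[-1]
    centers = np.arange(n, dtype=np.float64)
    cs = _cum_mid(src)
    ct = _cum_mid(tgt)
    out = np.empty_like(cs)
    for b in range(cs.shape[0]):
        out[b] = np.interp(cs[b], ct[b], centers)
    return out


def knothe_map(rho0: np.ndarray, rho1: np.ndarray) -> np.ndarray:
    """Triangular rearrangement pushing rho0 onto rho1 (axis order 0, 1, 2).

    Matches the axis-0 marginals by 1D CDF inversion, then the axis-1
    conditionals at the mapped slice, then the axis-2 conditionals at the
    mapped line.  Exact for identical inputs, translations, and densities
    varying along a single axis.
    """
    n0, n1, n2 = rho0.shape
    f = np.empty(rho0.shape + (3,), dtype=np.float64)

    m0 = rho0.sum(axis=(1, 2))[None, :]
    m1 = rho1.sum(axis=(1, 2))[None, :]
    f1 = _match_lines(m0, m1)[0]
    f[..., 0] = f1[:, None, None]

    S = rho0.sum(axis=2)
    T = rho1.sum(axis=2)
    k0 = np.clip(np.floor(f1).astype(np.intp), 0, max(n0 - 2, 0))
    w = (f1 - k0)[:, None]
    k1 = np.minimum(k0 + 1, n0 - 1)
    T_at = (1 - w) * T[k0] + w * T[k1]
    f2 = _match_lines(S, T_at)
    f[..., 1] = f2[:, :, None]

    j0 = np.clip(np.floor(f2).astype(np.intp), 0, max(n1 - 2, 0))
    wj = (f2 - j0)[..., None]
    j1 = np.minimum(j0 + 1, n1 - 1)
    wi = w[..., None]
    k0b = np.broadcast_to(k0[:, None], (n0, n1))
    k1b = np.broadcast_to(k1[:, None], (n0, n1))
    L = (
        (1 - wi) * (1 - wj) * rho1[k0b, j0, :]
        + (1 - wi) * wj * rho1[k0b, j1, :]
        + wi * (1 - wj) * rho1[k1b, j0, :]
        + wi * wj * rho1[k1b, j1, :]
    )
    f[..., 2] = _match_lines(
        rho0.reshape(n0 * n1, n2), L.reshape(n0 * n1, n2)
    ).reshape(n0, n1, n2)
    return f


# ---------------------------------------------------------------------------
# elliptic machinery for the linearized-transport iteration
# ---------------------------------------------------------------------------

def _neumann_poisson_inv(r: np.ndarray) -> np.ndarray:
    """Solve lap(z) = r with Neumann BC via DCT-II, zero-mean gauge."""
    shape = r.shape
    rhat = scipy.fft.dctn(r, type=2, norm="ortho")
    eig = np.zeros(shape)
    for ax, n in enumerate(shape):
        e = 2.0 * (np.cos(np.pi * np.arange(n) / n) - 1.0)
        sh = [1, 1, 1]
        sh[ax] = n
        eig = eig + e.reshape(sh)
    eig[(0,) * 3] = 1.0
    zhat = rhat / eig
    zhat[(0,) * 3] = 0.0
    return scipy.fft.idctn(zhat, type=2, norm="ortho")


def _apply_varcoef(phi: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """-div(sig grad phi), face-centered coefficients, zero-flux boundary."""
    out = np.zeros_like(phi)
    for ax in range(3):
        n = phi.shape[ax]
        if n == 1:
            continue
        sl = [slice(None)] * 3

        def s(i):
            t = list(sl)
            t[ax] = i
            return tuple(t)

        dphi = phi[s(slice(1, None))] - phi[s(slice(None, -1))]
        sface = 0.5 * (sig[s(slice(1, None))] + sig[s(slice(None, -1))])
        flux = sface * dphi
        out[s(slice(None, -1))] -= flux
        out[s(slice(1, None))] += flux
    return out


def _solve_elliptic(rhs, sig, tol, maxiter):
    """Preconditioned CG for div(sig grad phi) = rhs (Neumann, zero-mean)."""
    b = -(rhs - rhs.mean())
    x = np.zeros_like(b)
    r = b.copy()
    z = _neumann_poisson_inv(-r)
    p = z.copy()
    rz = float((r * z).sum())
    b_norm = float(np.linalg.norm(b))
    if b_norm == 0.0:
        return x
    for _ in range(maxiter):
        Ap = _apply_varcoef(p, sig)
        pAp = float((p * Ap).sum())
        if pAp <= 0:
            break
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        if float(np.linalg.norm(r)) < tol * b_norm:
            break
        z = _neumann_poisson_inv(-r)
        rz_new = float((r * z).sum())
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x


def _pullback(f: np.ndarray, rho1: np.ndarray) -> np.ndarray:
    return det3(jacobian(f)) * sample_trilinear(rho1, f)


def _moser_level(f, rho0, rho1, params: SolverParams, history):
    """Linearized-transport iterations at one level."""
    shape = rho0.shape
    idg = identity_grid(shape)
    # mobility: the map is only determined where there is mass; damping the
    # correction in the near-empty background keeps it close to the identity
    # instead of accumulating an unconstrained drift over the iterations
    rho0_s = ndimage.gaussian_filter(rho0, 1.5, mode="reflect")
    mobility = (rho0_s / (rho0_s + params.mobility_floor))[..., None]
    best = (np.inf, f)
    stall = 0
    cooldown = None
    for _ in range(params.max_iters):
        sig = _pullback(f, rho1)
        resid = rho0 - sig
        mp = float(np.abs(resid).sum() / rho0.sum())
        history.append(mp)
        if mp < best[0]:
            best = (mp, f)
            stall = 0
        else:
            stall += 1
        if mp < params.mp_tolerance and cooldown is None:
            cooldown = params.extra_iters
        if cooldown is not None:
            cooldown -= 1
            if cooldown <= 0:
                # the tolerance was met; the most recent map carries the extra
                # tail refinement even if its global residual wiggled slightly
                best = (mp, f)
                break
        if stall >= 4:
            break
        sig_reg = np.maximum(
            ndimage.gaussian_filter(sig, 1.0, mode="reflect"), params.sigma_floor
        )
        phi = _solve_elliptic(resid, sig_reg, params.cg_tol, params.cg_maxiter)
        step = mobility * np.stack([grad_axis(phi, a) for a in range(3)], axis=-1)
        smax = float(np.sqrt(np.sum(step**2, axis=-1)).max())
        alpha = min(1.0, params.step_max / smax) if smax > 0 else 1.0
        for _ in range(12):
            c = idg + alpha * step
            if det3(jacobian(c)).min() > params.jac_floor:
                break
            alpha *= 0.5
        else:
            break
        f = sample_field(f, c)  # f <- f o c
    return best[1]


# ---------------------------------------------------------------------------
# augmented-Lagrangian polish (cost reduction on the feasible manifold)
# ---------------------------------------------------------------------------

def _objective(u_flat, rho0, rho1, lam, mu, beta, grid, idgrid, record):
    n = rho0.size
    u = u_flat.reshape(grid + (3,))
    f = idgrid + u
    J = jacobian(f)
    det = det3(J)
    W, G = sample_trilinear(rho1, f, with_grad=True)
    R = det * W - rho0
    cost = float(np.sum(rho0[..., None] * u * u) / n)
    E = cost + float(np.mean(mu * R)) + float(0.5 * lam * np.mean(R * R))

    g = (2.0 / n) * rho0[..., None] * u
    a = (mu + lam * R) / n
    g += (a * det)[..., None] * G
    C = cof3(J)
    M = (a * W)[..., None, None] * C
    # Brenier structure: the optimal map is the gradient of a potential, so
    # its Jacobian is symmetric; penalizing the asymmetric part selects the
    # curl-free solution without biasing the optimum (the term vanishes there)
    if beta > 0:
        A = J - np.swapaxes(J, -1, -2)
        E += float(0.5 * beta / n * np.sum(A * A))
        M = M + (2.0 * beta / n) * A
    for comp in range(3):
        for ax in range(3):
            g[..., comp] += grad_axis_adjoint(M[..., comp, ax], ax)
    record.append(E)
    return E, g.ravel()


def _polish(u, rho0, rho1, params: SolverParams, history):
    grid = rho0.shape
    idgrid = identity_grid(grid)
    mu = np.zeros(grid)
    evals: list[float] = []

    def cb(_xk):
        if evals:
            history.append(evals[-1])

    res = optimize.minimize(
        _objective,
        u.ravel(),
        args=(rho0, rho1, params.mp_weight, mu, params.curl_weight, grid, idgrid, evals),
        method="L-BFGS-B",
        jac=True,
        callback=cb,
        options={"maxiter": params.polish_iters, "ftol": 1e-14, "gtol": 1e-14},
    )
    return res.x.reshape(grid + (3,))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _pyramid(rho: np.ndarray, params: SolverParams) -> list[np.ndarray]:
    levels = [rho]
    while len(levels) < params.n_scales:
        cur = levels[-1]
        if any(n % 2 != 0 and n > 1 for n in cur.shape):
            break
        if min(n for n in cur.shape if n > 1) < 2 * params.min_level_size:
            break
        levels.append(downsample_density(cur))
    return levels  # fine -> coarse


def _check_inputs(I0: TissueImage, Ii: TissueImage):
    if I0.shape != Ii.shape:
        raise ValueError(f"grid mismatch: reference {I0.shape} vs subject {Ii.shape}")
    for name, img in (("reference", I0), ("subject", Ii)):
        if img.data.min() <= 0:
            raise ValueError(
                f"{name} image must be strictly positive; run normalize_mass "
                "with an epsilon floor first"
            )
        if abs(img.mass - 1.0) > 1e-6:
            raise ValueError(f"{name} image must have unit mass (got {img.mass:.6g})")


def solve_transport(
    I0: TissueImage, Ii: TissueImage, params: SolverParams | None = None
) -> TransportMap:
    """Estimate the mass-preserving optimal transport map from I0 to Ii."""
    params = params or SolverParams()
    _check_inputs(I0, Ii)
    n_vox = I0.data.size
    pyr0 = _pyramid(I0.data * (n_vox / I0.data.sum()), params)
    pyr1 = _pyramid(Ii.data * (n_vox / Ii.data.sum()), params)
    n_levels = min(len(pyr0), len(pyr1))

    history: list[list[float]] = []
    f = None
    for lev in range(n_levels - 1, -1, -1):  # coarse -> fine
        rho0, rho1 = pyr0[lev], pyr1[lev]
        rho0 = rho0 * (rho0.size / rho0.sum())
        rho1 = rho1 * (rho1.size / rho1.sum())
        idg = identity_grid(rho0.shape)
        if f is None:
            f = knothe_map(rho0, rho1) if params.init == "knothe" else idg.copy()
        else:
            f = idg + upsample_field(f - identity_grid(prev_shape), rho0.shape)
        hist: list[float] = []
        f = _moser_level(f, rho0, rho1, params, hist)
        if lev == 0 and params.polish_iters > 0:
            u = _polish(f - idg, rho0, rho1, params, hist)
            f = idg + u
        history.append(hist)
        prev_shape = rho0.shape

    u = f - identity_grid(I0.shape)
    det = det3(jacobian(f))
    tm = TransportMap(
        f=f,
        voxel_size_mm=I0.voxel_size_mm,
        cost=float(np.sum(I0.data[..., None] * u * u)),
        mp_res=mp_residual(f, I0, Ii),
        jac_det=det,
        history=history,
        params=params,
    )
    if tm.mp_res > params.mp_tolerance:
        raise TransportConvergenceError(
            f"solver did not reach mp_tolerance={params.mp_tolerance:g} "
            f"(residual {tm.mp_res:.3g}) for subject {Ii.subject_id!r}",
            best_map=tm,
            residual=tm.mp_res,
        )
    return tm


def transport_cost(f: np.ndarray, I0: TissueImage) -> float:
    """Quadratic transport cost of a map: sum_x I0(x) ||f(x)-x||^2 (voxel^2)."""
    u = f - identity_grid(I0.shape)
    return float(np.sum(I0.data[..., None] * u * u))


def mp_residual(f: np.ndarray | TransportMap, I0: TissueImage, Ii: TissueImage) -> float:
    """Relative L1 violation of det(Df) Ii(f(x)) = I0(x)."""
    if isinstance(f, TransportMap):
        f = f.f
    det = det3(jacobian(f))
    W = sample_trilinear(Ii.data, f)
    return float(np.abs(det * W - I0.data).sum() / np.abs(I0.data).sum())


def invert_map(
    f: np.ndarray | TransportMap,
    max_iters: int = 40,
    tol: float = 1e-4,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Invert a map by damped Newton iteration on f(g(x)) = x.

    Each step solves the local 3x3 system ``Df(g) delta = x - f(g)`` (via the
    cofactor formula) and is capped at one voxel.  Transport maps produced by
    :func:`solve_transport` carry a tracked inverse which is used as the
    starting point; otherwise the iteration starts from ``id - u``.
    """
    g0 = init
    if isinstance(f, TransportMap):
        g0 = f.f_inv if g0 is None else g0
        f = f.f
    grid = f.shape[:-1]
    idg = identity_grid(grid)
    g = g0.copy() if g0 is not None else 2.0 * idg - f
    J = jacobian(f)
    best_rms, best_g = np.inf, g
    nmax = np.array(grid, dtype=np.float64) - 1.0
    for it in range(max_iters):
        fg = sample_field(f, g)
        res = idg - fg
        # voxels whose preimage leaves the grid cannot be resolved (their
        # true inverse samples outside the domain); they carry no mass and
        # are excluded from the convergence criterion
        inside = np.all((g >= 0.0) & (g <= nmax), axis=-1)
        r2 = np.sum(res**2, axis=-1)
        rms = float(np.sqrt(r2[inside].mean())) if inside.any() else 0.0
        if rms < best_rms:
            best_rms, best_g = rms, g
        if rms < tol:
            break
        Jg = np.empty(grid + (3, 3))
        for a in range(3):
            for b in range(3):
                Jg[..., a, b] = sample_trilinear(J[..., a, b], g)
        det = det3(Jg)
        det = np.where(np.abs(det) < 1e-6, 1e-6, det)
        C = cof3(Jg)
        # inv(A) = cof(A)^T / det(A); damped, capped at one voxel per step
        delta = np.einsum("...ba,...b->...a", C, res) / det[..., None]
        nrm = np.sqrt(np.sum(delta**2, axis=-1, keepdims=True))
        delta = delta * np.minimum(1.0, 1.0 / np.maximum(nrm, 1e-12))
        damp = 1.0 if it < 10 else 0.7
        g = g + damp * delta
    if best_rms > 0.05:
        raise TransportConvergenceError(
            f"map inversion did not converge (residual {best_rms:.3g} voxels)",
            residual=best_rms,
        )
    return best_g


def synthesize_image(
    f: np.ndarray | TransportMap,
    I0: TissueImage,
    renormalize: bool = True,
) -> TissueImage:
    """Generate the image a transport map encodes (inverse transformation).

    Applies the change-of-variables formula
    ``I(x) = det(Df^{-1}(x)) I0(f^{-1}(x))``.  The result is clipped to be
    nonnegative and, by default, renormalized to exact unit mass; the
    pre-normalization mass error is recorded in ``meta['synthesis_mass_error']``
    as a quality metric.
    """
    if isinstance(f, TransportMap):
        if f.jac_det.min() <= 0:
            raise ValueError("map is not invertible (non-positive Jacobian)")
    elif det3(jacobian(f)).min() <= 0:
        raise ValueError("map is not invertible (non-positive Jacobian)")
    g = invert_map(f)
    det_g = det3(jacobian(g))
    # cubic sampling: trilinear interpolation carries a sign-even bias that
    # is linear in the displacement and would contaminate small-increment
    # difference images; the spline's bias is two orders smaller
    vals = ndimage.map_coordinates(
        I0.data, [g[..., a] for a in range(3)], order=3, mode="nearest"
    )
    vals = vals * det_g
    vals = np.clip(vals, 0.0, None)
    mass = float(vals.sum())
    mass_error = abs(mass - I0.mass)
    if renormalize:
        if mass <= 0:
            raise ValueError("synthesized image has no mass")
        vals = vals * (I0.mass / mass)
    return TissueImage(
        data=vals,
        voxel_size_mm=I0.voxel_size_mm,
        tissue_class=I0.tissue_class,
        subject_id="synthesized",
        meta={"synthesis_mass_error": mass_error},
    )


def warp_density(displacement: np.ndarray, I0: TissueImage) -> TissueImage:
    """Push the density I0 forward by the map id + displacement.

    Convenience wrapper used by the phantom generator: the warped image is
    exactly the subject whose transport map from ``I0`` is ``id + displacement``
    (up to discretization), because synthesis inverts that same map.
    """
    f = identity_grid(I0.shape) + displacement
    return synthesize_image(f, I0)
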