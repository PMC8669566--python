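"""Transport-domain statistics.

Once every subject is represented by a transport map, morphometry becomes
linear algebra: the maps' displacement fields are vectorized into columns of
a data matrix, reduced by PCA, and the direction in the reduced space whose
subject projections correlate most strongly with a covariate is found in
closed form.  Because the transport representation is generative, any point
along that direction — mean map plus ``t`` times the direction — can be
synthesized back into an image.

Pipeline vocabulary:

* ``D`` (p x n): vectorized, sqrt(I0)-weighted displacement fields;
* ``x_bar``: the mean transport map (column mean of D);
* ``X`` (d x n): centered PCA coordinates retaining 90% of variance;
* ``w_corr``: unit direction maximizing corr(X^T w, v), computed as the
  normalized ``X v``;
* ``t``: position along the direction, linked to covariate units by the
  least-squares slope of subject scores on the covariate;
* permutation p-values: fraction of covariate permutations achieving a
  stronger correlation (add-one rule; exhaustive for n <= 7).

The sqrt(I0) weighting makes Euclidean distance in the embedding
approximate the linearized quadratic transport metric between images.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np

from ._fields import identity_grid, jacobian, det3
from .prep import TissueImage
from .transport import TransportMap

__all__ = [
    "TransportDataset",
    "PCAModel",
    "EffectDirection",
    "embed_maps",
    "embed_displacements",
    "unembed",
    "pca_reduce",
    "correlated_direction",
    "permutation_pvalue",
    "fit_t_scale",
    "point_along_direction",
    "mean_displacement_mm",
    "interaction_variable",
    "overlap_correlation",
    "variance_explained",
]


@dataclass
class TransportDataset:
    """Vectorized transport embeddings: columns are subjects."""

    D: np.ndarray  # (p, n)
    xbar: np.ndarray  # (p,)
    weight: np.ndarray  # (*grid,) embedding weight, sqrt(I0)
    grid_shape: tuple[int, int, int]
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.D.shape[1]


@dataclass
class PCAModel:
    """Truncated PCA of the embedding matrix."""

    V: np.ndarray  # (p, n-1) orthonormal eigenvectors
    singular_values: np.ndarray  # (n-1,)
    X: np.ndarray  # (d, n) centered reduced coordinates
    d: int
    var_fraction: float
    dataset: TransportDataset


@dataclass
class EffectDirection:
    """Most-correlated direction in the reduced transport space."""

    w_reduced: np.ndarray  # (d,), unit norm
    w_full: np.ndarray  # (p,)
    scores: np.ndarray  # (n,)
    v: np.ndarray  # (n,) analyzed (possibly residualized) covariate
    r: float
    p_perm: float | None = None
    slope_t_per_unit: float | None = None
    model: PCAModel | None = None


def _flatten_field(u: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Vectorize a weighted displacement field.

    Flattening order: within each of the three components, the first grid
    axis varies fastest (Fortran order); components are concatenated.
    """
    w = weight[..., None]
    return np.concatenate([(u[..., a] * weight).ravel(order="F") for a in range(3)])


def _unflatten_field(vec: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    n = int(np.prod(grid_shape))
    comps = [vec[a * n : (a + 1) * n].reshape(grid_shape, order="F") for a in range(3)]
    return np.stack(comps, axis=-1)


def embed_maps(maps: list[TransportMap], I0: TissueImage) -> TransportDataset:
    """Vectorize transport maps into a data matrix (one column per subject)."""
    disps = []
    ids = []
    for i, m in enumerate(maps):
        if m.shape != I0.shape:
            raise ValueError(
                f"grid mismatch: map {i} is {m.shape}, reference {I0.shape}"
            )
        disps.append(m.displacement)
        ids.append(str(i))
    return embed_displacements(disps, I0, subject_ids=ids)


def embed_displacements(
    disps: list[np.ndarray], I0: TissueImage, subject_ids: list[str] | None = None
) -> TransportDataset:
    """Embed raw displacement fields (used for maps and for ground truth)."""
    if len(disps) < 4:
        raise ValueError("need at least 4 subjects to build a transport dataset")
    weight = np.sqrt(I0.data)
    cols = [_flatten_field(u, weight) for u in disps]
    D = np.stack(cols, axis=1)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite values in transport embeddings")
    return TransportDataset(
        D=D,
        xbar=D.mean(axis=1),
        weight=weight,
        grid_shape=I0.shape,
        subject_ids=subject_ids or [str(i) for i in range(len(disps))],
    )


def unembed(vec: np.ndarray, dataset: TransportDataset) -> np.ndarray:
    """Map an embedding-space vector back to a displacement field."""
    u_weighted = _unflatten_field(vec, dataset.grid_shape)
    return u_weighted / dataset.weight[..., None]


def pca_reduce(dataset: TransportDataset, var_fraction: float = 0.90) -> PCAModel:
    """SVD of the column-centered data matrix, truncated at ``var_fraction``.

    ``d`` is the smallest number of leading components whose cumulative
    variance reaches the target.  The centering uses the same mean map that
    :func:`embed_maps` reports, so sampling along directions stays
    consistent with the mean-plus-t-times-direction construction.
    """
    n = dataset.n_subjects
    if n < 3:
        raise ValueError("PCA needs at least 3 subjects")
    Dc = dataset.D - dataset.xbar[:, None]
    V, s, Ut = np.linalg.svd(Dc, full_matrices=False)
    # at most n-1 nontrivial components after centering
    V, s, Ut = V[:, : n - 1], s[: n - 1], Ut[: n - 1]
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("zero-variance data: all subjects identical")
    cum = np.cumsum(var) / total
    d = int(np.searchsorted(cum, var_fraction - 1e-12) + 1)
    X = s[:d, None] * Ut[:d]
    return PCAModel(
        V=V,
        singular_values=s,
        X=X,
        d=d,
        var_fraction=var_fraction,
        dataset=dataset,
    )


def correlated_direction(
    model: PCAModel, v: np.ndarray, sign_positive: bool = True
) -> EffectDirection:
    """Direction in reduced space most correlated with covariate ``v``.

    The maximizer of ``w^T X v / ||w||`` is ``w ∝ X v``, normalized to unit
    length.  Subject scores are the projections ``X^T w``; the sign is fixed
    so the correlation is positive unless ``sign_positive=False``.
    """
    X = model.X
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.size != X.shape[1]:
        raise ValueError(f"covariate length {v.size} != n subjects {X.shape[1]}")
    if np.ptp(v) == 0:
        raise ValueError("covariate is constant; no direction is defined")
    w = X @ (v - v.mean())
    nrm = np.linalg.norm(w)
    if nrm <= 1e-12 * np.linalg.norm(X) * np.linalg.norm(v):
        raise ValueError("no correlated direction: X v is numerically zero")
    w = w / nrm
    scores = X.T @ w
    r = float(np.corrcoef(scores, v)[0, 1])
    if sign_positive and r < 0:
        w, scores, r = -w, -scores, -r
    return EffectDirection(
        w_reduced=w,
        w_full=model.V[:, : model.d] @ w,
        scores=scores,
        v=v,
        r=r,
        model=model,
    )


def _corr_stat(G: np.ndarray, v: np.ndarray) -> float:
    """|corr| of X^T w with v for w ∝ X v, computed via the Gram matrix G=X^T X."""
    vc = v - v.mean()
    s = G @ vc
    sc = s - s.mean()
    denom = np.linalg.norm(sc) * np.linalg.norm(vc)
    if denom == 0:
        return 0.0
    return abs(float(sc @ vc) / denom)


def permutation_pvalue(
    model: PCAModel, v: np.ndarray, T: int = 10000, seed: int = 0
) -> float:
    """Permutation p-value for the most-correlated direction.

    Each permutation reassigns the covariate to the subjects and re-derives
    the optimal direction (equivalently: the statistic is recomputed through
    the Gram matrix, since the direction is data-dependent).  The add-one
    rule ``p = (1 + #{|r_perm| >= |r_obs|}) / (T + 1)`` avoids zero
    p-values; for n <= 7 all n! permutations are enumerated instead and the
    p-value is the exact tail fraction (the identity permutation supplies
    the add-one).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    v = np.asarray(v, dtype=np.float64).ravel()
    if np.ptp(v) == 0:
        raise ValueError("covariate is constant; permutation test undefined")
    X = model.X
    G = X.T @ X
    r_obs = _corr_stat(G, v)
    n = v.size
    if n <= 7:
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            total += 1
            if _corr_stat(G, v[list(perm)]) >= r_obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(T):
        vp = rng.permutation(v)
        if _corr_stat(G, vp) >= r_obs - 1e-12:
            count += 1
    return (1 + count) / (T + 1)


def fit_t_scale(scores: np.ndarray, v: np.ndarray) -> float:
    """Least-squares slope of projection scores on the covariate.

    Defines the link ``t(delta) = slope * delta`` between covariate
    increments and positions along the direction.
    """
    v = np.asarray(v, dtype=np.float64).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    vc = v - v.mean()
    denom = float(vc @ vc)
    if denom == 0:
        raise ValueError("zero-variance covariate; slope undefined")
    return float((scores - scores.mean()) @ vc / denom)


def point_along_direction(
    direction: EffectDirection, t: float, I0: TissueImage
) -> TransportMap:
    """Transport-domain point x_bar + t * w, as a synthesizable map.

    The embedding vector is un-weighted back to a displacement field and
    turned into the map ``id + u``.  Raises if the resulting map folds
    (non-positive Jacobian); smaller ``|t|`` stays in the valid range.
    """
    ds = direction.model.dataset
    vec = ds.xbar + t * direction.w_full
    u = unembed(vec, ds)
    f = identity_grid(ds.grid_shape) + u
    jd = det3(jacobian(f))
    if jd.min() <= 0:
        raise ValueError(
            f"map at t={t:g} folds (min Jacobian {jd.min():.3g}); "
            "use a smaller |t|"
        )
    return TransportMap(
        f=f,
        voxel_size_mm=I0.voxel_size_mm,
        cost=float(np.sum(I0.data[..., None] * u * u)),
        mp_res=float("nan"),
        jac_det=jd,
    )


def mean_displacement_mm(
    direction: EffectDirection,
    t_for_increment: float,
    I0: TissueImage,
) -> float:
    """Mass-weighted mean displacement (mm) for a covariate increment.

    The displacement increment is ``t * w`` un-weighted to a field; its
    voxelwise norm (scaled by the voxel size) is averaged over the
    reference density.
    """
    ds = direction.model.dataset
    du = unembed(t_for_increment * direction.w_full, ds)
    vox = np.asarray(I0.voxel_size_mm)
    norms_mm = np.sqrt(np.sum((du * vox) ** 2, axis=-1))
    return float(np.sum(I0.data * norms_mm) / I0.data.sum())


def interaction_variable(
    age: np.ndarray,
    vo2: np.ndarray,
    confounds: np.ndarray | None = None,
) -> np.ndarray:
    """Age x fitness interaction covariate.

    The partial effect of age is removed from VO2 peak, the mean-subtracted
    age and residualized VO2 are multiplied, and the product is residualized
    against the remaining confounds (gender, education) plus an intercept.
    """
    from .prep import residualize

    age = np.asarray(age, dtype=np.float64).ravel()
    vo2 = np.asarray(vo2, dtype=np.float64).ravel()
    if np.ptp(age) == 0 or np.ptp(vo2) == 0:
        raise ValueError("age and vo2 must be non-constant for an interaction")
    vo2_res = residualize(vo2, age[:, None])
    v_raw = (age - age.mean()) * (vo2_res - vo2_res.mean())
    if np.ptp(v_raw) == 0:
        raise ValueError("degenerate interaction: product term is constant")
    return residualize(v_raw, confounds)


def overlap_correlation(
    dir_a: EffectDirection,
    dir_b: EffectDirection,
    T: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between two effect directions in transport space.

    Pearson correlation of the full-space direction entries; the p-value
    permutes the second covariate, re-derives its direction and collects the
    |r| null (add-one rule).
    """
    a, b = dir_a.w_full, dir_b.w_full
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm direction")
    r = float(np.corrcoef(a, b)[0, 1])
    model_b = dir_b.model
    if model_b is None or T < 1:
        return r, float("nan")
    rng = np.random.default_rng(seed)
    ac = a - a.mean()
    ac_n = ac / np.linalg.norm(ac)
    count = 0
    for _ in range(T):
        vp = rng.permutation(dir_b.v)
        w = model_b.X @ (vp - vp.mean())
        nrm = np.linalg.norm(w)
        if nrm == 0:
            continue
        wf = model_b.V[:, : model_b.d] @ (w / nrm)
        wc = wf - wf.mean()
        r_perm = abs(float(ac_n @ wc) / np.linalg.norm(wc))
        if r_perm >= abs(r) - 1e-12:
            count += 1
    return r, (1 + count) / (T + 1)


def variance_explained(r: float) -> int:
    """Shared variance in percent: 100 r^2, rounded to the nearest integer."""
    if abs(r) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    return int(round(100.0 * r * r))
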