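import numpy as np
import pytest

from tbm3d import (
    TissueImage,
    embed_displacements,
    correlated_direction,
    fit_t_scale,
    interaction_variable,
    mean_displacement_mm,
    overlap_correlation,
    pca_reduce,
    permutation_pvalue,
    point_along_direction,
    variance_explained,
)
from tbm3d.stats import TransportDataset, unembed

from conftest import gaussian_image


class TestEmbedding:
    def test_identity_maps_embed_to_zero(self):
        I0 = gaussian_image((12,) * 3, (5.5,) * 3, 2.0)
        zeros = [np.zeros((12, 12, 12, 3)) for _ in range(5)]
        ds = embed_displacements(zeros, I0)
        assert np.abs(ds.D).max() == 0
        assert np.abs(ds.xbar).max() == 0

    def test_single_nonzero_column_mean(self):
        I0 = gaussian_image((12,) * 3, (5.5,) * 3, 2.0)
        u = np.zeros((12, 12, 12, 3))
        u[..., 0] = 1.0
        disps = [np.zeros_like(u)] * 3 + [u]
        ds = embed_displacements(disps, I0)
        assert np.allclose(ds.xbar, ds.D[:, 3] / 4)

    def test_distance_between_translations_closed_form(self):
        """Embedded distance between two uniform-translation fields equals
        ||d1 - d2|| * sqrt(total reference mass)."""
        I0 = gaussian_image((16,) * 3, (7.5,) * 3, 2.5)
        d1 = np.broadcast_to([1.0, 0.0, 0.0], (16, 16, 16, 3)).copy()
        d2 = np.broadcast_to([0.0, 2.0, 0.0], (16, 16, 16, 3)).copy()
        ds = embed_displacements([d1, d2, d1, d2], I0)
        dist = np.linalg.norm(ds.D[:, 0] - ds.D[:, 1])
        expected = np.sqrt(5.0) * np.sqrt(I0.mass)
        assert dist == pytest.approx(expected, rel=0.02)

    def test_unembed_inverts_embedding(self):
        I0 = gaussian_image((10,) * 3, (4.5,) * 3, 2.0)
        rng = np.random.default_rng(0)
        u = rng.standard_normal((10, 10, 10, 3))
        ds = embed_displacements([u, -u, 2 * u, np.zeros_like(u)], I0)
        back = unembed(ds.D[:, 0], ds)
        assert np.abs(back - u).max() < 1e-9

    def test_too_few_subjects_rejected(self):
        I0 = gaussian_image((8,) * 3, (3.5,) * 3, 1.5)
        with pytest.raises(ValueError, match="4"):
            embed_displacements([np.zeros((8, 8, 8, 3))] * 3, I0)


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        coeffs = rng.standard_normal(8)
        D = np.outer(base, coeffs)
        ds = TransportDataset(D, D.mean(1), np.ones((10, 1, 1)), (10, 1, 1), list("abcdefgh"))
        model = pca_reduce(ds, 0.90)
        assert model.d == 1
        v1 = model.V[:, 0]
        cos = abs(v1 @ base) / np.linalg.norm(base)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_retained_variance_matches_covariance_eigen_oracle(self):
        rng = np.random.default_rng(2)
        D = rng.standard_normal((51, 20))
        ds = TransportDataset(D, D.mean(1), np.ones((17, 1, 1)), (17, 1, 1), [str(i) for i in range(20)])
        model = pca_reduce(ds, 0.90)
        Dc = D - D.mean(1, keepdims=True)
        evals = np.linalg.eigvalsh(Dc @ Dc.T)[::-1]
        ours = model.singular_values**2
        assert np.allclose(ours, evals[: len(ours)], atol=1e-8 * evals[0])
        cum = np.cumsum(evals) / evals.sum()
        assert model.d == np.searchsorted(cum, 0.90 - 1e-12) + 1

    def test_full_variance_keeps_all_and_reconstructs(self):
        rng = np.random.default_rng(3)
        D = rng.standard_normal((30, 9))
        ds = TransportDataset(D, D.mean(1), np.ones((10, 1, 1)), (10, 1, 1), [str(i) for i in range(9)])
        model = pca_reduce(ds, 1.0)
        assert model.d == 8  # n - 1
        recon = ds.xbar[:, None] + model.V[:, : model.d] @ model.X
        assert np.abs(recon - D).max() < 1e-8

    def test_centered_coordinates(self):
        rng = np.random.default_rng(4)
        D = rng.standard_normal((30, 10))
        ds = TransportDataset(D, D.mean(1), np.ones((10, 1, 1)), (10, 1, 1), [str(i) for i in range(10)])
        model = pca_reduce(ds)
        assert np.abs(model.X.mean(axis=1)).max() < 1e-10

    def test_zero_variance_rejected(self):
        D = np.ones((12, 5))
        ds = TransportDataset(D, D.mean(1), np.ones((4, 1, 1)), (4, 1, 1), list("abcde"))
        with pytest.raises(ValueError, match="variance"):
            pca_reduce(ds)


def toy_model(rng, p=36, n=10, d_keep=0.9):
    D = rng.standard_normal((p, n))
    ds = TransportDataset(D, D.mean(1), np.ones((p // 3, 1, 1)), (p // 3, 1, 1), [str(i) for i in range(n)])
    return pca_reduce(ds, d_keep)


class TestCorrelatedDirection:
    def test_perfect_alignment_gives_r_one(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(8)
        base = rng.standard_normal(30)
        D = np.outer(base, v - v.mean())
        ds = TransportDataset(D, D.mean(1), np.ones((10, 1, 1)), (10, 1, 1), [str(i) for i in range(8)])
        model = pca_reduce(ds, 0.99)
        direction = correlated_direction(model, v)
        assert direction.r == pytest.approx(1.0, abs=1e-10)

    def test_constant_covariate_rejected(self):
        model = toy_model(np.random.default_rng(6))
        with pytest.raises(ValueError, match="constant"):
            correlated_direction(model, np.ones(10))

    def test_orthogonal_covariate_rejected(self):
        """If v is orthogonal to every reduced row, no direction exists."""
        rng = np.random.default_rng(7)
        v = np.arange(6.0)
        vc = v - v.mean()
        pattern = rng.standard_normal(6)
        pattern -= pattern.mean()
        pattern -= (pattern @ vc) / (vc @ vc) * vc  # orthogonal to centered v
        base = rng.standard_normal(30)
        D = np.outer(base, pattern)
        ds = TransportDataset(D, D.mean(1), np.ones((10, 1, 1)), (10, 1, 1), list("abcdef"))
        model = pca_reduce(ds, 0.99)
        with pytest.raises(ValueError, match="no correlated direction"):
            correlated_direction(model, v)

    def test_no_random_unit_vector_beats_maximizer(self):
        """Stochastic maximality: w proportional to Xv attains the maximum of
        w^T X v over the unit sphere."""
        rng = np.random.default_rng(8)
        model = toy_model(rng, p=36, n=12, d_keep=1.0)
        v = rng.standard_normal(12)
        direction = correlated_direction(model, v)
        target = model.X @ (v - v.mean())
        best = abs(direction.w_reduced @ target)
        trials = rng.standard_normal((10000, model.d))
        trials /= np.linalg.norm(trials, axis=1, keepdims=True)
        assert np.abs(trials @ target).max() <= best + 1e-10

    def test_direction_invariant_to_confound_shift(self):
        """Adding any linear function of the confounds to the residualized
        covariate leaves the direction and correlation unchanged."""
        from tbm3d import residualize

        rng = np.random.default_rng(9)
        model = toy_model(rng, p=45, n=15, d_keep=1.0)
        Z = rng.standard_normal((15, 2))
        y = rng.standard_normal(15)
        v = residualize(y, Z)
        d1 = correlated_direction(model, v)
        shifted = v + Z @ np.array([2.0, -1.0]) + 3.0
        v2 = residualize(shifted, Z)
        d2 = correlated_direction(model, v2)
        assert np.abs(d1.w_reduced - d2.w_reduced).max() < 1e-8
        assert d1.r == pytest.approx(d2.r, abs=1e-8)


class TestPermutation:
    def test_exhaustive_small_n_monotone_case(self):
        """n=5 with scores strictly monotone in v: only the identity
        permutation attains the maximum, so p = 1/120."""
        rng = np.random.default_rng(10)
        v = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        base = rng.standard_normal(30)
        D = np.outer(base, v - v.mean()) + 0.01 * rng.standard_normal((30, 5))
        ds = TransportDataset(D, D.mean(1), np.ones((10, 1, 1)), (10, 1, 1), list("abcde"))
        model = pca_reduce(ds, 0.999)
        p = permutation_pvalue(model, v)
        assert p == pytest.approx(1.0 / 120.0)

    def test_constant_covariate_rejected_before_sampling(self):
        model = toy_model(np.random.default_rng(11))
        with pytest.raises(ValueError, match="constant"):
            permutation_pvalue(model, np.full(10, 2.0))

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(12)
        model = toy_model(rng, n=20)
        v = rng.standard_normal(20)
        p1 = permutation_pvalue(model, v, T=200, seed=5)
        p2 = permutation_pvalue(model, v, T=200, seed=5)
        assert p1 == p2


class TestTScale:
    def test_exact_slopes(self):
        v = np.array([1.0, 2.0, 4.0, 8.0])
        assert fit_t_scale(2 * v, v) == pytest.approx(2.0)
        orth = np.array([1.0, -1.0, -1.0, 1.0])
        vc = np.array([-1.0, 1.0, -1.0, 1.0])
        assert fit_t_scale(orth, vc) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_t_scale(np.arange(4.0), np.ones(4))


class TestSampling:
    def _fitted(self):
        rng = np.random.default_rng(13)
        I0 = gaussian_image((12,) * 3, (5.5,) * 3, 2.0)
        from tbm3d._fields import identity_grid
        g0 = identity_grid((12, 12, 12))[..., 0]
        base = np.zeros((12, 12, 12, 3))
        base[..., 0] = 0.1 * np.sin(2 * np.pi * g0 / 12)  # sign-mixed divergence
        disps = [s * base for s in (-2, -1, 1, 2)]
        ds = embed_displacements(disps, I0)
        model = pca_reduce(ds, 0.99)
        v = np.array([-2.0, -1.0, 1.0, 2.0])
        d = correlated_direction(model, v)
        d.slope_t_per_unit = fit_t_scale(d.scores, v)
        return I0, ds, d

    def test_t_zero_is_mean_map(self):
        I0, ds, d = self._fitted()
        tm = point_along_direction(d, 0.0, I0)
        assert np.allclose(tm.displacement, unembed(ds.xbar, ds), atol=1e-10)

    def test_symmetric_offsets(self):
        I0, ds, d = self._fitted()
        mean_u = unembed(ds.xbar, ds)
        up = point_along_direction(d, 0.5, I0).displacement - mean_u
        dn = point_along_direction(d, -0.5, I0).displacement - mean_u
        assert np.allclose(up, -dn, atol=1e-10)

    def test_folding_t_rejected(self):
        I0, ds, d = self._fitted()
        with pytest.raises(ValueError, match="smaller"):
            point_along_direction(d, 1e6, I0)


class TestDisplacementSummary:
    def test_uniform_unit_displacement_with_2mm_voxels(self):
        I0 = gaussian_image((12,) * 3, (5.5,) * 3, 2.0)
        I0 = TissueImage(I0.data, voxel_size_mm=(2.0, 2.0, 2.0))
        u = np.zeros((12, 12, 12, 3))
        u[..., 0] = 1.0
        disps = [u, -u, 2 * u, -2 * u]
        ds = embed_displacements(disps, I0)
        model = pca_reduce(ds, 0.99)
        v = np.array([1.0, -1.0, 2.0, -2.0])
        d = correlated_direction(model, v)
        # scale t so the displacement field is exactly one voxel
        t_unit = 1.0 / np.abs(unembed(d.w_full, ds)[..., 0]).max()
        mm = mean_displacement_mm(d, t_unit, I0)
        assert mm == pytest.approx(2.0, rel=1e-6)

    def test_linear_in_t(self):
        I0 = gaussian_image((12,) * 3, (5.5,) * 3, 2.0)
        rng = np.random.default_rng(14)
        disps = [rng.standard_normal((12, 12, 12, 3)) for _ in range(5)]
        ds = embed_displacements(disps, I0)
        model = pca_reduce(ds, 0.95)
        v = rng.standard_normal(5)
        d = correlated_direction(model, v)
        assert mean_displacement_mm(d, 2.0, I0) == pytest.approx(
            2 * mean_displacement_mm(d, 1.0, I0), abs=1e-10
        )
        zero = mean_displacement_mm(d, 0.0, I0)
        assert zero == 0.0


class TestInteraction:
    def test_matches_manual_arithmetic(self):
        """Six-subject example checked against explicit normal-equation
        projections (independent of the library's residualizer)."""
        age = np.array([60.0, 62.0, 65.0, 70.0, 74.0, 80.0])
        vo2 = np.array([30.0, 25.0, 28.0, 20.0, 18.0, 15.0])
        gender = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        edu = np.array([4.0, 5.0, 6.0, 5.0, 7.0, 8.0])
        Z = np.column_stack([gender, edu])

        def project_out(y, M):
            Mi = np.column_stack([M, np.ones(len(y))])
            beta = np.linalg.inv(Mi.T @ Mi) @ (Mi.T @ y)
            return y - Mi @ beta

        vo2_res = project_out(vo2, age[:, None])
        raw = (age - age.mean()) * (vo2_res - vo2_res.mean())
        expected = project_out(raw, Z)
        got = interaction_variable(age, vo2, Z)
        assert np.allclose(got, expected, atol=1e-10)
        assert np.abs(np.column_stack([Z, np.ones(6)]).T @ got).max() < 1e-8

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            interaction_variable(np.full(5, 70.0), np.arange(5.0), None)


class TestOverlap:
    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(15)
        model = toy_model(rng, n=10, d_keep=1.0)
        v = rng.standard_normal(10)
        d = correlated_direction(model, v)
        r, p = overlap_correlation(d, d, T=50, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_directions_near_zero(self):
        from dataclasses import replace
        rng = np.random.default_rng(16)
        model = toy_model(rng, n=10, d_keep=1.0)
        v = rng.standard_normal(10)
        d1 = correlated_direction(model, v)
        a = d1.w_full - d1.w_full.mean()
        w = rng.standard_normal(a.size)
        w -= w.mean()
        w -= (w @ a) / (a @ a) * a  # centered and orthogonal to the direction
        d2 = replace(d1, w_full=w)
        r, _ = overlap_correlation(d1, d2, T=0)
        assert abs(r) < 1e-10


@pytest.mark.parametrize(
    "r, pct",
    [(0.74, 55), (0.62, 38), (0.23, 5), (0.0, 0), (-0.74, 55)],
)
def test_variance_explained(r, pct):
    assert variance_explained(r) == pct


def test_variance_explained_rejects_out_of_range():
    with pytest.raises(ValueError):
        variance_explained(1.2)
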