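"""Linear subspaces: PCA against a full-SVD oracle, multiclass DA against
a dense generalized eigensolver, and the Foley–Sammon recursion against
closed forms, the dominant-eigenvector oracle, and Monte-Carlo maximality
of the Fisher criterion."""

import numpy as np
import pytest
import scipy.linalg
import scipy.spatial.distance
from hypothesis import given, settings
from hypothesis import strategies as st

import subspace_fewshot as sf
from subspace_fewshot.data import ValidationError

from conftest import random_binary_dataset, random_multiclass_dataset


class TestPCA:
    def test_rank_one_data_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=5)
        direction /= np.linalg.norm(direction)
        feats = np.outer(rng.normal(size=20), direction) + 3.0
        ds = sf.FeatureDataset(feats, np.repeat([0, 1], 10))
        sub = sf.fit_pca(ds, p=1)
        proj = sf.project(sub, feats)
        recon = proj @ sub.basis.T + sub.centering
        assert np.abs(recon - feats).max() < 1e-10

    def test_full_rank_projection_is_isometric_on_centered_rows(self):
        ds = random_multiclass_dataset(1, c=2, n_per_class=15, m=6)
        centered = ds.features - ds.features.mean(axis=0)
        rank = np.linalg.matrix_rank(centered)
        sub = sf.fit_pca(ds, p=rank)
        proj = sf.project(sub, ds.features)
        d_orig = scipy.spatial.distance.pdist(centered)
        d_proj = scipy.spatial.distance.pdist(proj)
        np.testing.assert_allclose(d_proj, d_orig, rtol=1e-8, atol=1e-8)

    @pytest.mark.parametrize("p", [1, 3, 8])
    def test_captured_variance_matches_full_svd_oracle(self, p):
        rng = np.random.default_rng(42)
        feats = rng.normal(size=(30, 8))
        ds = sf.FeatureDataset(feats, np.repeat([0, 1], 15))
        sub = sf.fit_pca(ds, p=p)
        s_full = scipy.linalg.svd(feats - feats.mean(axis=0), compute_uv=False)
        np.testing.assert_allclose(
            np.sum(sub.spectrum**2), np.sum(s_full[:p] ** 2), rtol=1e-10
        )

    def test_projected_variances_non_increasing(self):
        ds = random_multiclass_dataset(2, c=3, n_per_class=20, m=7)
        sub = sf.fit_pca(ds, p=5)
        variances = sf.project(sub, ds.features).var(axis=0)
        assert np.all(np.diff(variances) <= 1e-10)

    def test_spectrum_non_increasing_and_basis_orthonormal(self):
        ds = random_multiclass_dataset(3, c=2, n_per_class=20, m=8)
        sub = sf.fit_pca(ds, p=6)
        assert np.all(np.diff(sub.spectrum) <= 0)
        gram = sub.basis.T @ sub.basis
        assert np.abs(gram - np.eye(6)).max() < 1e-8

    def test_sign_convention_is_deterministic(self):
        ds = random_multiclass_dataset(4, c=2, n_per_class=20, m=8)
        a = sf.fit_pca(ds, p=4)
        b = sf.fit_pca(ds, p=4)
        np.testing.assert_array_equal(a.basis, b.basis)
        assert all(
            a.basis[np.argmax(np.abs(a.basis[:, k])), k] > 0 for k in range(4)
        )

    def test_p_out_of_range_rejected(self):
        ds = random_multiclass_dataset(0, c=2, n_per_class=5, m=4)
        with pytest.raises(ValidationError, match="out of range"):
            sf.fit_pca(ds, p=0)
        with pytest.raises(ValidationError, match="out of range"):
            sf.fit_pca(ds, p=5)

    def test_uncentered_mode(self):
        ds = random_multiclass_dataset(5, c=2, n_per_class=10, m=5)
        sub = sf.fit_pca(ds, p=2, center=False)
        assert sub.centering is None
        s_full = scipy.linalg.svd(ds.features, compute_uv=False)
        np.testing.assert_allclose(sub.spectrum, s_full[:2], rtol=1e-10)


class TestProject:
    def test_identity_basis_is_identity_map(self):
        sub = sf.LinearSubspace(
            basis=np.eye(3),
            spectrum=np.ones(3),
            centering=np.zeros(3),
            method_tag="pca",
        )
        x = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(sf.project(sub, x), x)

    def test_output_width_is_subspace_dim(self):
        ds = random_multiclass_dataset(0, c=2, n_per_class=10, m=6)
        sub = sf.fit_pca(ds, p=3)
        assert sf.project(sub, ds.features).shape == (20, 3)

    def test_in_span_norm_preservation(self):
        ds = random_multiclass_dataset(1, c=2, n_per_class=10, m=6)
        sub = sf.fit_pca(ds, p=4, center=False)
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=(5, 4))
        in_span = coeffs @ sub.basis.T
        proj = sf.project(sub, in_span)
        np.testing.assert_allclose(
            np.linalg.norm(proj, axis=1),
            np.linalg.norm(in_span, axis=1),
            rtol=1e-10,
        )

    def test_width_mismatch_rejected(self):
        ds = random_multiclass_dataset(0, c=2, n_per_class=10, m=6)
        sub = sf.fit_pca(ds, p=2)
        with pytest.raises(ValidationError, match="width"):
            sf.project(sub, np.ones((3, 5)))


class TestMulticlassDA:
    def test_default_dimension_is_c_minus_1(self):
        ds = random_multiclass_dataset(0, c=4, n_per_class=10, m=7)
        sub = sf.fit_multiclass_da(ds)
        assert sub.dim == 3
        assert sub.delta_used == pytest.approx(5e-3)

    def test_eigenpair_residuals(self):
        ds = random_multiclass_dataset(1, c=5, n_per_class=10, m=8)
        sub = sf.fit_multiclass_da(ds, delta=5e-3)
        stats = sf.compute_scatter(ds)
        shat = stats.S_W + 5e-3 * np.eye(ds.n_features)
        for k in range(sub.dim):
            v = sub.eigenvectors[:, k]
            lhs = stats.S_B @ v
            rhs = sub.spectrum[k] * (shat @ v)
            assert np.linalg.norm(lhs - rhs) < 1e-8 * max(
                np.linalg.norm(lhs), np.linalg.norm(rhs), 1e-12
            )

    def test_matches_dense_generalized_eigensolver(self):
        ds = random_multiclass_dataset(2, c=4, n_per_class=12, m=6)
        sub = sf.fit_multiclass_da(ds, delta=5e-3)
        stats = sf.compute_scatter(ds)
        shat = stats.S_W + 5e-3 * np.eye(6)
        w = np.sort(scipy.linalg.eigvals(np.linalg.inv(shat) @ stats.S_B).real)[::-1]
        np.testing.assert_allclose(sub.spectrum, w[: sub.dim], rtol=1e-8, atol=1e-10)

    def test_binary_limit_collinear_with_foley_sammon(self):
        """With equal class counts, S_B ∝ s_b s_bᵀ and S̃_W = S_W/2, so the
        single DA direction coincides with the first discriminant vector."""
        ds = random_binary_dataset(0, n_per_class=40, m=6)
        da = sf.fit_multiclass_da(ds, delta=1e-8)
        fs = sf.fit_foley_sammon(ds, L=1, delta=0.0)
        cos = abs(da.basis[:, 0] @ fs.directions[:, 0])
        assert cos > 1 - 1e-6

    def test_recovers_planted_discriminant_plane(self):
        """Class means displaced only in coordinates 0-1 with small
        *exactly* isotropic within-class scatter: the fitted 2-D basis must
        span those coordinates.  (The noise is whitened per class because
        any empirical anisotropy legitimately tilts the discriminant plane
        through the S_W⁻¹ metric.)"""
        rng = np.random.default_rng(3)
        means = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        rows = []
        for m in means:
            z = rng.normal(size=(30, 3))
            z -= z.mean(axis=0)
            dev = 1e-3 * z @ np.linalg.inv(scipy.linalg.sqrtm(z.T @ z).real)
            rows.append(m + dev)
        ds = sf.FeatureDataset(np.vstack(rows), np.repeat([0, 1, 2], 30))
        sub = sf.fit_multiclass_da(ds, delta=1e-9)
        angles = scipy.linalg.subspace_angles(sub.basis, np.eye(3)[:, :2])
        assert angles.max() < 1e-3

    def test_basis_orthonormal(self):
        ds = random_multiclass_dataset(4, c=6, n_per_class=10, m=9)
        sub = sf.fit_multiclass_da(ds)
        gram = sub.basis.T @ sub.basis
        assert np.abs(gram - np.eye(sub.dim)).max() < 1e-8

    def test_invalid_delta_rejected(self):
        ds = random_multiclass_dataset(0, c=3)
        with pytest.raises(ValidationError, match="delta"):
            sf.fit_multiclass_da(ds, delta=0.0)
        with pytest.raises(ValidationError, match="delta"):
            sf.fit_multiclass_da(ds, delta=-1.0)


class TestFoleySammon:
    def test_identity_within_scatter_normalizes_mean_difference(self):
        s_b = np.array([3.0, 4.0])
        stats = sf.BinaryScatterStats(
            s_b=s_b,
            S_tilde_B=np.outer(s_b, s_b),
            S_tilde_W=np.eye(2),
            beta=0.5,
            n_features=2,
        )
        basis = sf.foley_sammon_from_stats(stats, L=1)
        np.testing.assert_allclose(basis.directions[:, 0], [0.6, 0.8], atol=1e-12)

    def test_analytic_two_direction_solution(self, analytic_binary_stats):
        basis = sf.foley_sammon_from_stats(analytic_binary_stats, L=2)
        np.testing.assert_allclose(
            basis.directions[:, 0], np.array([2.0, 1.0]) / np.sqrt(5), atol=1e-12
        )
        d2 = basis.directions[:, 1]
        expected = np.array([-1.0, 2.0]) / np.sqrt(5)
        assert min(
            np.abs(d2 - expected).max(), np.abs(d2 + expected).max()
        ) < 1e-12
        np.testing.assert_allclose(
            basis.discrim_values, [1.5, 1.0 / 9.0], rtol=1e-12
        )

    def test_discrim_values_operation_matches_definition(
        self, analytic_binary_stats
    ):
        basis = sf.foley_sammon_from_stats(analytic_binary_stats, L=2)
        gammas = sf.discrim_values(basis, analytic_binary_stats)
        np.testing.assert_allclose(gammas, [1.5, 1.0 / 9.0], rtol=1e-12)

    def test_zero_mean_difference_has_no_direction(self):
        stats = sf.BinaryScatterStats(
            s_b=np.zeros(3),
            S_tilde_B=np.zeros((3, 3)),
            S_tilde_W=np.eye(3),
            beta=0.5,
            n_features=3,
        )
        with pytest.raises(ValidationError, match="coincide"):
            sf.foley_sammon_from_stats(stats, L=1)

    @pytest.mark.parametrize("seed", range(10))
    def test_first_direction_matches_dominant_generalized_eigenvector(self, seed):
        ds = random_binary_dataset(seed, n_per_class=30, m=5 + seed)
        stats = sf.compute_binary_scatter(ds)
        basis = sf.fit_foley_sammon(ds, L=1)
        w, v = scipy.linalg.eigh(stats.S_tilde_B, stats.S_tilde_W)
        dom = v[:, np.argmax(w)]
        dom /= np.linalg.norm(dom)
        assert abs(basis.directions[:, 0] @ dom) > 1 - 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_orthonormality_and_ordering(self, seed):
        m = 6 + (seed % 5)
        ds = random_binary_dataset(seed + 100, n_per_class=25, m=m)
        L = min(5, m)
        basis = sf.fit_foley_sammon(ds, L=L)
        gram = basis.directions.T @ basis.directions
        assert np.abs(gram - np.eye(L)).max() < 1e-8
        assert np.all(np.diff(basis.discrim_values) <= 1e-10)
        assert basis.discrim_values[-1] >= -1e-10

    def test_gram_matrix_matches_definition(self):
        ds = random_binary_dataset(7, n_per_class=25, m=6)
        stats = sf.compute_binary_scatter(ds)
        basis = sf.fit_foley_sammon(ds, L=4)
        w = stats.S_tilde_W + basis.delta_used * np.eye(6)
        expected = basis.directions.T @ np.linalg.solve(w, basis.directions)
        np.testing.assert_allclose(basis.gram, expected, rtol=1e-8, atol=1e-10)

    def test_ridge_applied_when_underdetermined(self):
        # N < M: the within-class scatter cannot be full rank
        ds = random_binary_dataset(1, n_per_class=4, m=12)
        basis = sf.fit_foley_sammon(ds, L=3)
        assert basis.delta_used == pytest.approx(5e-3)

    def test_l_out_of_range_rejected(self):
        ds = random_binary_dataset(0, n_per_class=10, m=4)
        with pytest.raises(ValidationError, match="out of range"):
            sf.fit_foley_sammon(ds, L=5)

    def test_multiclass_input_rejected(self):
        ds = random_multiclass_dataset(0, c=3)
        with pytest.raises(ValidationError, match="binary"):
            sf.fit_foley_sammon(ds, L=1)

    def test_rank_exhaustion_reports_step(self):
        """A rank-2 problem cannot support a 3rd informative direction if the
        recursion's Gram system collapses; the error names the step."""
        s_b = np.array([1.0, 0.0, 0.0])
        w = np.diag([1.0, 1.0, 1.0])
        stats = sf.BinaryScatterStats(
            s_b=s_b,
            S_tilde_B=np.outer(s_b, s_b),
            S_tilde_W=w,
            beta=0.5,
            n_features=3,
        )
        # identity W: d_1 = s_b; the next residual s_b − d_1/... vanishes
        with pytest.raises(ValidationError, match=r"(singular|collapsed)"):
            sf.foley_sammon_from_stats(stats, L=3)


class TestFisherRatio:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        scale=st.floats(
            min_value=1e-3, max_value=1e3, allow_nan=False, allow_infinity=False
        ),
    )
    def test_scale_invariance(self, seed, scale):
        ds = random_binary_dataset(seed, n_per_class=15, m=5)
        stats = sf.compute_binary_scatter(ds)
        d = np.random.default_rng(seed).normal(size=5)
        base = sf.fisher_ratio(d, stats)
        assert sf.fisher_ratio(scale * d, stats) == pytest.approx(base, rel=1e-10)
        assert sf.fisher_ratio(-d, stats) == pytest.approx(base, rel=1e-10)

    def test_direction_orthogonal_to_mean_difference_scores_zero(self):
        ds = random_binary_dataset(3, n_per_class=20, m=4)
        stats = sf.compute_binary_scatter(ds)
        rng = np.random.default_rng(0)
        d = rng.normal(size=4)
        d -= (d @ stats.s_b) / (stats.s_b @ stats.s_b) * stats.s_b
        assert sf.fisher_ratio(d, stats) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_first_direction_is_the_maximizer(self, seed):
        """d_1 attains the Fisher-criterion maximum: no random unit vector
        beats it (Monte-Carlo check, 1000 draws)."""
        ds = random_binary_dataset(seed + 50, n_per_class=30, m=6)
        stats = sf.compute_binary_scatter(ds)
        basis = sf.fit_foley_sammon(ds, L=1)
        best = sf.fisher_ratio(basis.directions[:, 0], stats)
        rng = np.random.default_rng(seed)
        for v in rng.normal(size=(1000, 6)):
            assert sf.fisher_ratio(v, stats) <= best * (1 + 1e-10)

    def test_zero_direction_rejected(self):
        ds = random_binary_dataset(0, n_per_class=10, m=4)
        stats = sf.compute_binary_scatter(ds)
        with pytest.raises(ValidationError, match="nonzero"):
            sf.fisher_ratio(np.zeros(4), stats)
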