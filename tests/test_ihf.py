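import numpy as np
import pytest

from ihf3d.ihf import (
    IHFConfig,
    IHFReference,
    compute_histogram,
    fit_reducer,
    fit_reference,
    load_reference,
    reduce_embedding,
    save_reference,
    score,
    score_mahalanobis,
    score_nn,
)
from ihf3d.phantoms import generate_id_phantom, generate_shifted_phantom
from ihf3d.preprocess import PreprocessConfig
from ihf3d.volume_io import Volume


def make_reference(train_reduced, mean=None, covariance=None):
    """Build an IHFReference directly from reduced embeddings (no image pipeline).

    By default uses the divisor-n sample covariance with the production ridge;
    explicit mean/covariance overrides bypass the estimation."""
    X = np.asarray(train_reduced, dtype=np.float64)
    if mean is None:
        mean = X.mean(axis=0)
    if covariance is None:
        D = X - mean
        covariance = (D.T @ D) / X.shape[0]
        scale = np.trace(covariance) / X.shape[1]
        covariance = covariance + 1e-6 * (scale if scale > 0 else 1.0) * np.eye(X.shape[1])
    return IHFReference(
        reducer=None, train_reduced=X, mean=np.asarray(mean, dtype=np.float64),
        covariance=np.asarray(covariance, dtype=np.float64), config=IHFConfig(use_pca=False),
    )


class TestHistogram:
    def test_single_value_mass(self):
        v = Volume(data=np.full((4, 4, 4), 0.5), spacing=(1, 1, 1))
        e = compute_histogram(v, m=4)
        np.testing.assert_allclose(e.values, [0, 0, 4, 0])

    def test_two_value_split(self):
        data = np.array([0.1] * 32 + [0.9] * 32).reshape(4, 4, 4)
        e = compute_histogram(Volume(data=data, spacing=(1, 1, 1)), m=2)
        np.testing.assert_allclose(e.values, [1.0, 1.0])

    def test_uniform_sampling_near_flat(self):
        rng = np.random.default_rng(42)
        data = rng.uniform(0, 1, size=(50, 50, 40))  # 1e5 voxels
        e = compute_histogram(Volume(data=data, spacing=(1, 1, 1)), m=10)
        np.testing.assert_allclose(e.values, 1.0, atol=0.05)

    def test_value_one_lands_in_last_bin(self):
        data = np.full((2, 2, 2), 1.0)
        e = compute_histogram(Volume(data=data, spacing=(1, 1, 1)), m=5)
        np.testing.assert_allclose(e.values, [0, 0, 0, 0, 5])

    def test_density_normalization_property(self):
        rng = np.random.default_rng(0)
        for m in (2, 17, 150):
            e = compute_histogram(Volume(data=rng.beta(2, 5, size=(10, 10, 10)), spacing=(1, 1, 1)), m=m)
            assert np.sum(e.values) / m == pytest.approx(1.0, abs=1e-9)
            assert np.all(e.values >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            compute_histogram(Volume(data=np.full((2, 2, 2), 1.5), spacing=(1, 1, 1)), m=4)


class TestReducer:
    def test_rank_one_data_gives_k1(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=8)
        E = np.outer(rng.normal(size=20), direction) + 3.0
        red = fit_reducer(E, v=0.9999)
        assert red.k == 1
        assert red.explained_variance_ratio == pytest.approx(1.0)
        # reconstruction recovers training rows
        for row in E[:5]:
            z = reduce_embedding(red, row)
            np.testing.assert_allclose(red.center + red.basis @ z, row, atol=1e-8)

    def test_isotropic_3d_cloud_keeps_all_components(self):
        rng = np.random.default_rng(3)
        E = rng.normal(size=(500, 3))
        # eigenvalue oracle: all three sample eigenvalues carry ~1/3 variance
        evals = np.linalg.eigvalsh(np.cov(E.T))
        assert evals.min() / evals.sum() > 0.25
        assert fit_reducer(E, v=0.9999).k == 3

    def test_v_equal_one_keeps_rank(self):
        rng = np.random.default_rng(4)
        low_rank = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 10))
        assert fit_reducer(low_rank, v=1.0).k == 2

    def test_basis_orthonormal_and_variance_target(self):
        rng = np.random.default_rng(5)
        E = rng.normal(size=(40, 12)) * np.linspace(3, 0.01, 12)
        red = fit_reducer(E, v=0.99)
        np.testing.assert_allclose(red.basis.T @ red.basis, np.eye(red.k), atol=1e-8)
        # independent eigendecomposition of the population covariance
        X = E - E.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(X.T @ X / X.shape[0]))[::-1]
        assert evals[: red.k].sum() / evals.sum() >= 0.99

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            fit_reducer(np.zeros((1, 5)), v=0.9)

    def test_reduce_center_maps_to_zero_and_identity_without_reducer(self):
        rng = np.random.default_rng(6)
        E = rng.normal(size=(10, 6))
        red = fit_reducer(E, v=0.9999)
        np.testing.assert_allclose(reduce_embedding(red, red.center), 0.0, atol=1e-12)
        e = rng.normal(size=6)
        np.testing.assert_array_equal(reduce_embedding(None, e), e)
        with pytest.raises(ValueError, match="length"):
            reduce_embedding(red, np.zeros(5))


class TestMahalanobis:
    def test_zero_at_mean(self):
        ref = make_reference(np.random.default_rng(0).normal(size=(20, 3)))
        assert score_mahalanobis(ref, ref.mean) == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_is_euclidean(self):
        ref = make_reference(np.zeros((2, 2)), mean=np.zeros(2), covariance=np.eye(2))
        assert score_mahalanobis(ref, np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_diagonal_closed_form(self):
        ref = make_reference(np.zeros((2, 2)), mean=np.zeros(2), covariance=np.diag([4.0, 1.0]))
        assert score_mahalanobis(ref, np.array([2.0, 1.0])) == pytest.approx(np.sqrt(2.0))

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            A = rng.normal(size=(5, 5))
            cov = A @ A.T + 0.5 * np.eye(5)
            mean = rng.normal(size=5)
            ref = make_reference(np.zeros((2, 5)), mean=mean, covariance=cov)
            x = rng.normal(size=5)
            expected = np.sqrt((x - mean) @ np.linalg.inv(cov) @ (x - mean))
            assert score_mahalanobis(ref, x) == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_linear_reparameterization(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 3))
        cov = np.cov(X.T, bias=True)
        mean = X.mean(axis=0)
        ref = make_reference(X, mean=mean, covariance=cov)
        x = rng.normal(size=3)
        base = score_mahalanobis(ref, x)
        for _ in range(5):
            T = rng.normal(size=(3, 3)) + 2 * np.eye(3)
            ref_t = make_reference(X @ T.T, mean=T @ mean, covariance=T @ cov @ T.T)
            assert score_mahalanobis(ref_t, T @ x) == pytest.approx(base, abs=1e-6)

    def test_mean_squared_train_score_equals_dimension(self):
        # with the divisor-n covariance, the average squared Mahalanobis
        # distance of the training points is exactly k (trace identity)
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 4)) @ np.diag([3, 1, 0.5, 0.1])
        ref = make_reference(X)
        sq = [score_mahalanobis(ref, x) ** 2 for x in X]
        assert np.mean(sq) == pytest.approx(4.0, rel=1e-3)

    def test_length_mismatch(self):
        ref = make_reference(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            score_mahalanobis(ref, np.zeros(4))


class TestNearestNeighbor:
    def test_zero_on_training_row(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        ref = make_reference(X)
        assert score_nn(ref, X[4]) == 0.0

    def test_small_example(self):
        ref = make_reference(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert score_nn(ref, np.array([0.2, 0.0])) == pytest.approx(0.2)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(200, 4))
        ref = make_reference(X)
        for q in rng.normal(size=(50, 4)):
            expected = min(float(np.sqrt(np.sum((row - q) ** 2))) for row in X)
            assert score_nn(ref, q) == expected


class TestFitReference:
    def test_identical_volumes_give_ridge_only_covariance(self, mri_pre):
        rng = np.random.default_rng(15)
        data = np.clip(rng.normal(50, 10, size=(8, 8, 6)), 0, None)
        vols = [Volume(data=data.copy(), spacing=(1, 1, 1.5)) for _ in range(2)]
        ref = fit_reference(vols, IHFConfig(m=20), mri_pre)
        k = ref.mean.size
        np.testing.assert_allclose(ref.covariance, 1e-6 * np.eye(k), atol=1e-12)
        np.testing.assert_allclose(ref.train_reduced[0], ref.train_reduced[1])

    def test_mean_matches_independently_recomputed_embeddings(self, small_phantom_config, mri_pre):
        vols = [generate_id_phantom(small_phantom_config, s)[0] for s in range(10)]
        cfg = IHFConfig(m=50)
        ref = fit_reference(vols, cfg, mri_pre)
        # recompute embeddings outside the fit path
        from ihf3d.preprocess import preprocess

        E = np.stack([compute_histogram(preprocess(v, mri_pre), cfg.m).values for v in vols])
        reduced = np.stack([reduce_embedding(ref.reducer, e) for e in E])
        np.testing.assert_allclose(ref.mean, reduced.mean(axis=0), atol=1e-9)

    def test_no_pca_keeps_full_width(self, small_phantom_config, mri_pre):
        vols = [generate_id_phantom(small_phantom_config, s)[0] for s in range(3)]
        ref = fit_reference(vols, IHFConfig(m=30, use_pca=False), mri_pre)
        assert ref.train_reduced.shape == (3, 30)

    def test_requires_two_volumes(self, small_phantom_config, mri_pre):
        v = generate_id_phantom(small_phantom_config, 0)[0]
        with pytest.raises(ValueError):
            fit_reference([v], IHFConfig(), mri_pre)

    def test_deterministic_fit_and_score(self, small_phantom_config, mri_pre):
        vols = [generate_id_phantom(small_phantom_config, s)[0] for s in range(5)]
        cfg = IHFConfig(m=40, scorer="mahalanobis")
        r1 = fit_reference(vols, cfg, mri_pre)
        r2 = fit_reference(vols, cfg, mri_pre)
        np.testing.assert_array_equal(r1.covariance, r2.covariance)
        q = generate_id_phantom(small_phantom_config, 99)[0]
        assert score(r1, q, cfg, mri_pre) == score(r2, q, cfg, mri_pre)


class TestEndToEndScoring:
    def test_training_volume_scores_zero_with_nn(self, small_phantom_config, mri_pre):
        vols = [generate_id_phantom(small_phantom_config, s)[0] for s in range(5)]
        cfg = IHFConfig(m=40, scorer="nn")
        ref = fit_reference(vols, cfg, mri_pre)
        assert score(ref, vols[2], cfg, mri_pre) == pytest.approx(0.0, abs=1e-9)

    def test_shifted_phantom_scores_above_id_median(self, mri_pre):
        # default study conditions: full-size phantoms, shift = 3 x noise sd
        from ihf3d.phantoms import PhantomConfig

        pcfg = PhantomConfig()
        cfg = IHFConfig(m=60, scorer="mahalanobis")
        train = [generate_id_phantom(pcfg, s)[0] for s in range(15)]
        ref = fit_reference(train, cfg, mri_pre)
        shift = 3.0 * pcfg.noise_sd  # pre-scaling tissue intensity shift
        wins = 0
        for rep in range(20):
            id_scores = [score(ref, generate_id_phantom(pcfg, 1000 + rep * 7 + i)[0], cfg, mri_pre) for i in range(3)]
            s_ood = score(ref, generate_shifted_phantom(pcfg, "intensity_shift", shift, 5000 + rep), cfg, mri_pre)
            wins += s_ood > np.median(id_scores)
        assert wins == 20

    def test_reference_roundtrip_serialization(self, tmp_path, small_phantom_config, mri_pre):
        vols = [generate_id_phantom(small_phantom_config, s)[0] for s in range(4)]
        cfg = IHFConfig(m=30, scorer="nn")
        ref = fit_reference(vols, cfg, mri_pre)
        path = tmp_path / "ref.npz"
        save_reference(ref, path)
        back = load_reference(path)
        q = generate_id_phantom(small_phantom_config, 77)[0]
        assert score(back, q, cfg, mri_pre) == pytest.approx(score(ref, q, cfg, mri_pre))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            IHFConfig(m=1)
        with pytest.raises(ValueError):
            IHFConfig(v=0.0)
        with pytest.raises(ValueError):
            IHFConfig(scorer="knn")
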