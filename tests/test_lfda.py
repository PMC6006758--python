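import logging

import numpy as np
import pytest
import scipy.linalg

from apoloc.lfda import (
    LfdaModel,
    affinity_matrix,
    lfda_fit,
    lfda_transform,
    local_scaling,
    local_scatter_matrices,
)

import oracles


class TestLocalScaling:
    def test_points_on_a_line(self):
        X = np.arange(9.0)[:, None]
        sigma = local_scaling(X, K=7)
        assert sigma[0] == pytest.approx(7.0)
        assert sigma[-1] == pytest.approx(7.0)

    def test_identical_points_floored_with_warning(self, caplog):
        X = np.zeros((10, 3))
        with caplog.at_level(logging.WARNING):
            sigma = local_scaling(X, K=7)
        np.testing.assert_allclose(sigma, 1e-12)
        assert any("floored" in r.message for r in caplog.records)

    def test_matches_brute_force_distance_matrix(self, rng):
        X = rng.normal(size=(30, 5))
        sigma = local_scaling(X, K=7)
        for i in range(30):
            dists = sorted(np.linalg.norm(X[i] - X[j]) for j in range(30)
                           if j != i)
            assert sigma[i] == pytest.approx(dists[6])

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="lower K"):
            local_scaling(rng.normal(size=(7, 2)), K=7)


class TestAffinityMatrix:
    def test_unit_diagonal(self, rng):
        X = rng.normal(size=(12, 4))
        aff = affinity_matrix(X, local_scaling(X, K=7))
        np.testing.assert_allclose(np.diag(aff.A), 1.0)

    def test_unit_exponent(self):
        d = 3.0
        X = np.array([[0.0], [d]])
        aff = affinity_matrix(X, np.array([1.5, 2.0]))  # sigma1*sigma2 = 3
        assert aff.A[0, 1] == pytest.approx(np.exp(-1.0))

    def test_symmetry(self, rng):
        X = rng.normal(size=(25, 6))
        aff = affinity_matrix(X, local_scaling(X, K=7))
        assert np.max(np.abs(aff.A - aff.A.T)) < 1e-12

    def test_entries_positive_and_at_most_one(self, rng):
        X = rng.normal(size=(20, 3))
        aff = affinity_matrix(X, local_scaling(X, K=7))
        assert np.all(aff.A > 0) and np.all(aff.A <= 1.0)

    def test_squared_variant(self, rng):
        X = rng.normal(size=(10, 2))
        sigma = local_scaling(X, K=7)
        plain = affinity_matrix(X, sigma, variant="plain").A
        squared = affinity_matrix(X, sigma, variant="squared").A
        assert not np.allclose(plain, squared)
        with pytest.raises(ValueError, match="variant"):
            affinity_matrix(X, sigma, variant="cubic")


class TestScatterMatrices:
    def test_all_ones_affinity_recovers_classical_within(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        A = np.ones((10, 10))
        Sw, _ = local_scatter_matrices(X, y, A)
        np.testing.assert_allclose(
            Sw, oracles.classical_within_scatter(X, y), atol=1e-10
        )

    def test_two_singletons_give_zero_within(self, rng):
        X = rng.normal(size=(2, 3))
        y = np.array([0, 1])
        A = np.ones((2, 2))
        Sw, _ = local_scatter_matrices(X, y, A)
        np.testing.assert_allclose(Sw, 0.0, atol=1e-15)

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(18, 5))
        y = rng.integers(0, 3, size=18)
        from apoloc.lfda import local_scaling as ls, affinity_matrix as am

        A = am(X, ls(X, K=7)).A
        Sw, Sb = local_scatter_matrices(X, y, A)
        Sw_ref, Sb_ref = oracles.naive_scatter_matrices(X, y, A)
        np.testing.assert_allclose(Sw, Sw_ref, atol=1e-10)
        np.testing.assert_allclose(Sb, Sb_ref, atol=1e-10)

    def test_symmetric_and_within_psd(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.integers(0, 2, size=20)
        A = affinity_matrix(X, local_scaling(X, K=7)).A
        Sw, Sb = local_scatter_matrices(X, y, A)
        assert np.max(np.abs(Sw - Sw.T)) < 1e-10
        assert np.max(np.abs(Sb - Sb.T)) < 1e-10
        assert np.linalg.eigvalsh(Sw).min() > -1e-10

    def test_missing_class_errors(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        A = np.ones((6, 6))
        with pytest.raises(ValueError, match="0 members"):
            local_scatter_matrices(X, y, A, classes=np.array([0, 1, 2]))


class TestLfdaFit:
    def test_recovers_known_discriminative_axis(self):
        # large n so the sample within-scatter is near-isotropic and the
        # whitened discriminant direction aligns with the planted axis
        rng = np.random.default_rng(7)
        n = 400
        X0 = rng.normal(size=(n, 5))
        X1 = rng.normal(size=(n, 5))
        X0[:, 0] -= 5.0
        X1[:, 0] += 5.0
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n)
        model = lfda_fit(X, y, r=1)
        e1 = np.zeros(5)
        e1[0] = 1.0
        assert abs(model.T[:, 0] @ e1) > 0.99

    def test_duplicated_class_no_separation_signal(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(40, 4)), rng.normal(size=(40, 4))])
        y = np.repeat([0, 1], 40)
        model = lfda_fit(X, y, r=2)
        # permuted-label null: same distribution, so the top eigenvalue
        # should be on the same scale as with shuffled labels
        null_vals = []
        for s in range(5):
            perm = np.random.default_rng(s).permutation(80)
            null_vals.append(lfda_fit(X, perm % 2, r=2).eigenvalues[0])
        assert model.eigenvalues[0] < 3.0 * max(null_vals)

    def test_toy_eigenpairs_match_dense_solver(self):
        X = np.array([[0.0, 0.1], [0.2, 0.0], [0.1, 0.3],
                      [2.0, 2.1], [2.2, 1.9], [1.9, 2.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = lfda_fit(X, y, r=2, K=3)
        Swr = model.Sw + model.epsilon * np.eye(2)
        # independent dense route: standard eig of inv(Swr) @ Sb
        vals = np.sort(scipy.linalg.eigvals(
            np.linalg.inv(Swr) @ model.Sb).real)[::-1]
        np.testing.assert_allclose(model.eigenvalues, vals[:2], atol=1e-8)
        for j in range(2):
            t = model.T[:, j]
            resid = model.Sb @ t - model.eigenvalues[j] * (Swr @ t)
            assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(model.Sb)

    def test_generalized_eigen_residual(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 3, size=40)
        model = lfda_fit(X, y, r=4)
        Swr = model.Sw + model.epsilon * np.eye(6)
        for j in range(4):
            t = model.T[:, j]
            resid = model.Sb @ t - model.eigenvalues[j] * (Swr @ t)
            assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(model.Sb)

    def test_rotation_equivariance(self, rng):
        X = rng.normal(size=(30, 4))
        X[:15] += 3.0
        y = np.repeat([0, 1], 15)
        Q = scipy.linalg.qr(rng.normal(size=(4, 4)))[0]
        m1 = lfda_fit(X, y, r=2)
        m2 = lfda_fit(X @ Q, y, r=2)
        angles = scipy.linalg.subspace_angles(Q.T @ m1.T, m2.T)
        assert np.max(angles) < 1e-6

    def test_three_class_separation_in_reduced_space(self):
        rng = np.random.default_rng(11)
        blocks, ys = [], []
        for c, shift in enumerate([(0, 0), (30, 0), (0, 30)]):
            B = rng.normal(size=(25, 6))
            B[:, 0] += shift[0]
            B[:, 1] += shift[1]
            blocks.append(B)
            ys.append(np.full(25, c))
        X = np.vstack(blocks)
        y = np.concatenate(ys)
        model = lfda_fit(X, y, r=2)
        Z = lfda_transform(model, X)
        within = max(
            np.sqrt(((Z[y == c] - Z[y == c].mean(0)) ** 2).sum(1).mean())
            for c in range(3)
        )
        for a in range(3):
            for b in range(a + 1, 3):
                gap = np.linalg.norm(Z[y == a].mean(0) - Z[y == b].mean(0))
                assert gap > 5.0 * within

    def test_eigenvalues_descending_unit_columns(self, rng):
        X = rng.normal(size=(25, 5))
        y = rng.integers(0, 2, size=25)
        model = lfda_fit(X, y, r=3)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(np.linalg.norm(model.T, axis=0), 1.0)

    def test_r_too_large_errors(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        with pytest.raises(ValueError, match="r <= 3"):
            lfda_fit(X, y, r=4)

    def test_single_class_errors(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="two classes"):
            lfda_fit(X, np.zeros(20, dtype=int), r=1)


class TestLfdaTransform:
    def test_identity_subblock(self, rng):
        X = rng.normal(size=(8, 3))
        model = LfdaModel(T=np.eye(3), eigenvalues=np.ones(3),
                          Sw=np.eye(3), Sb=np.eye(3), r=3, K=7, epsilon=0.0)
        np.testing.assert_allclose(lfda_transform(model, X), X)

    def test_single_sample_shape(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.integers(0, 2, size=15)
        model = lfda_fit(X, y, r=2)
        assert lfda_transform(model, X[0]).shape == (1, 2)

    def test_direct_product(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.integers(0, 2, size=20)
        model = lfda_fit(X, y, r=3)
        np.testing.assert_allclose(lfda_transform(model, X), X @ model.T)

    def test_column_mismatch(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.integers(0, 2, size=15)
        model = lfda_fit(X, y, r=2)
        with pytest.raises(ValueError, match="feature columns"):
            lfda_transform(model, rng.normal(size=(3, 5)))


def test_model_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(20, 4))
    y = rng.integers(0, 2, size=20)
    model = lfda_fit(X, y, r=2)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = LfdaModel.from_json(path)
    np.testing.assert_allclose(loaded.T, model.T)
    np.testing.assert_allclose(loaded.eigenvalues, model.eigenvalues)
    assert loaded.r == 2 and loaded.K == 7
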