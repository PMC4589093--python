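"""Wavelet compression, PCA reduction and the accelerated solver."""

import numpy as np
import pytest

from fmtwave import (
    ConfigurationError,
    SolverConfig,
    algorithm1_solve,
    build_wavelet_operator,
    compress_system,
    pca_reduce,
    solve_reduced,
    tikhonov_solve,
)
from fmtwave.errors import SolverError
from fmtwave.waveletpca import PCAReduction, _cg_with_count


class TestWaveletOperator:
    def test_haar_hand_example(self):
        W = build_wavelet_operator(4, "haar", 1)
        out = W.forward(np.array([4.0, 2.0, 6.0, 0.0]))
        np.testing.assert_allclose(
            out, [6 / np.sqrt(2), 6 / np.sqrt(2), 2 / np.sqrt(2), 6 / np.sqrt(2)],
            atol=1e-12,
        )

    @pytest.mark.parametrize("family", ["haar", "db2", "db4"])
    @pytest.mark.parametrize("n,level", [(4, 1), (13, 1), (32, 2), (100, 3)])
    def test_orthonormality(self, family, n, level):
        W = build_wavelet_operator(n, family, level)
        I = W.W @ W.W.T
        assert np.abs(I - np.eye(W.n_pad)).max() < 1e-12

    def test_constant_vector_has_zero_detail(self):
        W = build_wavelet_operator(16, "haar", 1)
        out = W.forward(np.full(16, 3.0))
        np.testing.assert_allclose(out[W.n1 :], 0.0, atol=1e-12)

    def test_unsupported_family(self):
        with pytest.raises(ConfigurationError):
            build_wavelet_operator(8, "sym5", 1)

    def test_round_trip(self):
        W = build_wavelet_operator(10, "db2", 1)
        v = np.arange(10.0)
        np.testing.assert_allclose(W.inverse(W.forward(v)), v, atol=1e-12)


class TestCompressSystem:
    def test_identity_compresses_to_identity(self):
        W = build_wavelet_operator(8, "haar", 1)
        K1, b1 = compress_system(np.eye(8), np.zeros(8), W, W)
        np.testing.assert_allclose(K1, np.eye(4), atol=1e-12)

    def test_constant_rhs_haar(self):
        W = build_wavelet_operator(8, "haar", 1)
        _, b1 = compress_system(np.eye(8), np.full(8, 2.0), W, W)
        np.testing.assert_allclose(b1, np.full(4, 2.0 * np.sqrt(2)), atol=1e-12)

    def test_frobenius_energy_preserved(self):
        rng = np.random.default_rng(5)
        K = rng.normal(size=(8, 8))
        W = build_wavelet_operator(8, "haar", 1)
        K_hat = W.W @ K @ W.W.T
        assert np.linalg.norm(K_hat) == pytest.approx(np.linalg.norm(K), rel=1e-10)


class TestPCAReduce:
    def test_hand_eigendecomposition(self):
        red = pca_reduce(np.array([[2.0, 0.0], [0.0, 1.0]]), np.array([1.0, 1.0]), q=1)
        np.testing.assert_allclose(red.L, [[1.0, -0.5], [-0.5, 0.25]], atol=1e-14)
        np.testing.assert_allclose(red.eigenvalues, [1.25, 0.0], atol=1e-12)
        v = red.eigenvectors[:, 0]
        expected = np.array([2.0, -1.0]) / np.sqrt(5)
        assert min(np.abs(v - expected).max(), np.abs(v + expected).max()) < 1e-12

    def test_full_rank_projection_reproduces_solution(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(10, 8))
        K1 = A.T @ A + 0.01 * np.eye(8)
        b1 = rng.normal(size=8)
        red = pca_reduce(K1, b1, q=8)
        dx = solve_reduced(red)
        np.testing.assert_allclose(dx, np.linalg.solve(K1, b1), atol=1e-10)

    def test_energy_fraction_one_counts_nonzero_eigenvalues(self):
        K1 = np.diag([3.0, 2.0, 1.0, 1.0])  # rank-3 column covariance
        red = pca_reduce(K1, np.zeros(4), energy_fraction=1.0)
        nonzero = (red.eigenvalues > 1e-12 * red.eigenvalues.sum()).sum()
        assert red.q == nonzero

    def test_eigenvalues_sorted_and_energy_reached(self):
        rng = np.random.default_rng(7)
        K1 = rng.normal(size=(12, 12))
        red = pca_reduce(K1, np.zeros(12), energy_fraction=0.9)
        lam = red.eigenvalues
        assert (np.diff(lam) <= 1e-12).all()
        assert lam[: red.q].sum() / lam.sum() >= 0.9 - 1e-12

    def test_zero_variance_warns_to_q1(self, caplog):
        with caplog.at_level("WARNING"):
            red = pca_reduce(np.zeros((3, 3)), np.zeros(3), energy_fraction=0.5)
        assert red.q == 1


class TestSolveReduced:
    def test_minimum_norm_underdetermined(self):
        red = PCAReduction(
            L=None, eigenvalues=None, eigenvectors=None, q=1,
            K_red=np.array([[1.0, 1.0]]), b_red=np.array([2.0]),
        )
        np.testing.assert_allclose(solve_reduced(red), [1.0, 1.0], atol=1e-12)

    def test_zero_rhs(self):
        red = PCAReduction(None, None, None, 1, np.array([[1.0, 0.0]]), np.array([0.0]))
        assert not solve_reduced(red).any()

    def test_inconsistent_system(self):
        red = PCAReduction(None, None, None, 1, np.zeros((1, 2)), np.array([1.0]))
        with pytest.raises(SolverError):
            solve_reduced(red)


def random_ridge_system(rng, n=37, xi=1e-3):
    A = rng.normal(size=(n + 5, n))
    return A.T @ A + xi * np.eye(n), A.T @ rng.normal(size=n + 5)


class TestAlgorithm1:
    def test_identity_system(self):
        b = np.arange(1.0, 9.0)
        dx, info = algorithm1_solve(np.eye(8), b)
        np.testing.assert_allclose(dx, b, atol=1e-8)
        assert info.converged

    def test_matches_dense_factorization(self):
        rng = np.random.default_rng(8)
        K, b = random_ridge_system(rng)
        dx, info = algorithm1_solve(K, b)
        dx_ref = tikhonov_solve(K, b)
        assert np.linalg.norm(dx - dx_ref) / np.linalg.norm(dx_ref) < 1e-6
        assert info.converged

    def test_residual_contract(self):
        rng = np.random.default_rng(9)
        K, b = random_ridge_system(rng, n=50)
        dx, _ = algorithm1_solve(K, b)
        assert np.linalg.norm(K @ dx - b) / np.linalg.norm(b) <= 1e-7

    @pytest.mark.parametrize("config", [
        SolverConfig(family="db2", level=2, energy_fraction=0.8),
        SolverConfig(family="haar", level=1, q=5),
    ])
    def test_fixed_point_independent_of_compression(self, config):
        rng = np.random.default_rng(10)
        K, b = random_ridge_system(rng)
        dx, _ = algorithm1_solve(K, b, config)
        ref = tikhonov_solve(K, b)
        assert np.linalg.norm(dx - ref) / np.linalg.norm(ref) < 1e-6

    def test_ordering_permutation_round_trip(self):
        rng = np.random.default_rng(12)
        K, b = random_ridge_system(rng, n=20)
        perm = rng.permutation(20)
        dx, _ = algorithm1_solve(K, b, SolverConfig(ordering=perm))
        np.testing.assert_allclose(dx, tikhonov_solve(K, b), atol=1e-6)

    def test_warm_start_helps_on_smooth_systems(self):
        """The compressed-solve initial guess saves CG iterations.

        Random SPD systems whose solutions are smooth (wavelet-compressible):
        the warm start must not lose to the zero start on at least 90% of 50
        draws.
        """
        rng = np.random.default_rng(13)
        n = 64
        W = build_wavelet_operator(n, "haar", 1)
        Q = W.W.T  # orthonormal; first n1 columns are the smooth scaling basis
        wins = 0
        for _ in range(50):
            # spectrum dominated by the smooth (approximation) subspace
            lam = np.concatenate([
                rng.uniform(5, 10, W.n1), rng.uniform(0.1, 0.5, n - W.n1)
            ])
            K = (Q * lam) @ Q.T
            x_true = Q[:, : W.n1] @ rng.normal(size=W.n1) + 0.05 * rng.normal(size=n)
            b = K @ x_true
            _, info = algorithm1_solve(K, b, SolverConfig(tol=1e-8))
            _, _, it0 = _cg_with_count(K, b, np.zeros(n), 1e-8, 10 * n)
            if info.cg_iterations <= it0:
                wins += 1
        assert wins >= 45


from hypothesis import given, settings, strategies as st


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=64),
    family=st.sampled_from(["haar", "db2"]),
    data=st.data(),
)
def test_wavelet_round_trip_property(n, family, data):
    """inverse(forward(v)) == v for arbitrary lengths and vectors."""
    v = np.array(data.draw(st.lists(
        st.floats(-1e3, 1e3, allow_nan=False), min_size=n, max_size=n)))
    W = build_wavelet_operator(n, family, 1)
    np.testing.assert_allclose(W.inverse(W.forward(v)), v, atol=1e-9)
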