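"""Tests of kernel construction, combination, expansion and decomposition."""

import numpy as np
import pytest

from gpkern.exceptions import (
    AlignmentError,
    DegenerateInputError,
    InvalidKernelError,
)
from gpkern.kernels import (
    KernelMatrix,
    arc_cosine_kernel,
    composite_weather_kernel,
    design_matrix,
    eigendecompose,
    expand_kernel,
    gaussian_kernel,
    identity_kernel,
    linear_kernel,
    validate_kernel,
)


class TestLinearKernel:
    def test_trace_equals_n(self, rng):
        K = linear_kernel(rng.normal(size=(17, 5)))
        assert np.trace(K.values) == pytest.approx(17.0, abs=1e-10)

    def test_two_by_one_example(self):
        K = linear_kernel(np.array([[1.0], [2.0]]))
        np.testing.assert_allclose(K.values, [[0.4, 0.8], [0.8, 1.6]])

    def test_matches_double_loop_grm(self, rng):
        X = rng.normal(size=(12, 6))
        K = linear_kernel(X)
        G = np.empty((12, 12))
        for i in range(12):
            for j in range(12):
                G[i, j] = float(X[i] @ X[j])
        np.testing.assert_allclose(K.values, G / (np.trace(G) / 12), atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            linear_kernel(np.zeros((4, 3)))


class TestGaussianKernel:
    def test_identical_rows_similarity_one(self, rng):
        X = rng.normal(size=(6, 4))
        X[1] = X[0]
        K = gaussian_kernel(X, h=2.0)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_median_distance_pair_at_e_minus_one(self, rng):
        X = rng.normal(size=(9, 3))
        K = gaussian_kernel(X, h=1.0)
        from scipy.spatial.distance import pdist, squareform

        d2 = squareform(pdist(X, "sqeuclidean"))
        q = np.median(d2[np.triu_indices_from(d2, k=1)])
        i, j = np.unravel_index(np.argmin(np.abs(d2 - q) + np.eye(9) * 1e9), d2.shape)
        assert K.values[i, j] == pytest.approx(np.exp(-d2[i, j] / q), rel=1e-12)

    def test_monotone_decreasing_in_distance(self, rng):
        X = rng.normal(size=(10, 3))
        K = gaussian_kernel(X, h=1.5)
        from scipy.spatial.distance import pdist, squareform

        d2 = squareform(pdist(X, "sqeuclidean"))
        iu = np.triu_indices(10, k=1)
        order = np.argsort(d2[iu])
        assert np.all(np.diff(K.values[iu][order]) <= 1e-12)

    def test_small_bandwidth_approaches_all_ones(self, rng):
        K = gaussian_kernel(rng.normal(size=(8, 3)), h=1e-8)
        assert np.all(np.abs(K.values - 1.0) < 1e-6)

    def test_identical_records_rejected(self):
        with pytest.raises(DegenerateInputError):
            gaussian_kernel(np.ones((5, 2)), h=1.0)


class TestArcCosineKernel:
    def test_identical_vector_diagonal(self, rng):
        X = rng.normal(size=(5, 4))
        K = arc_cosine_kernel(X, layers=1)
        np.testing.assert_allclose(
            np.diag(K.values), np.linalg.norm(X, axis=1) ** 2, rtol=1e-12
        )

    def test_orthogonal_vectors(self):
        X = np.array([[2.0, 0.0], [0.0, 3.0]])
        K = arc_cosine_kernel(X, layers=1)
        assert K.values[0, 1] == pytest.approx(2 * 3 / np.pi, rel=1e-12)

    def test_relu_random_feature_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        K = arc_cosine_kernel(X, layers=1)
        n_mc = 200_000
        W = rng.standard_normal((n_mc, 4))
        R = np.maximum(W @ X.T, 0.0)
        prods = 2 * (R.T @ R) / n_mc
        se = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                se[i, j] = 2 * np.std(R[:, i] * R[:, j]) / np.sqrt(n_mc)
        assert np.all(np.abs(prods - K.values) <= 3 * se)

    def test_deeper_layers_stay_valid(self, rng):
        K = arc_cosine_kernel(rng.normal(size=(8, 3)), layers=5)
        validate_kernel(K)

    def test_zero_norm_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            arc_cosine_kernel(np.array([[0.0, 0.0], [1.0, 1.0]]), layers=1)


class TestComposite:
    def test_identical_constituents_fixed_point(self, rng):
        X = rng.normal(size=(7, 3))
        K = gaussian_kernel(X, 1.0)
        comp = composite_weather_kernel([K, K], kind="gaussian")
        np.testing.assert_allclose(comp.values, K.values, atol=1e-12)

    def test_gaussian_weights_are_inverse_h(self, rng):
        X = rng.normal(size=(7, 3))
        K1, K3 = gaussian_kernel(X, 1.0), gaussian_kernel(X, 3.0)
        comp = composite_weather_kernel([K1, K3], kind="gaussian")
        np.testing.assert_allclose(comp.hyperparams["weights"], [0.75, 0.25])
        np.testing.assert_allclose(
            comp.values, 0.75 * K1.values + 0.25 * K3.values, atol=1e-12
        )
        assert np.all(np.abs(np.diag(comp.values) - 1.0) < 1e-12)

    def test_linear_sum_trace_normalized(self, rng):
        ks = [linear_kernel(rng.normal(size=(6, 4))) for _ in range(3)]
        comp = composite_weather_kernel(ks, kind="linear")
        assert np.trace(comp.values) == pytest.approx(6.0, abs=1e-10)

    def test_label_mismatch_rejected(self, rng):
        a = linear_kernel(rng.normal(size=(4, 2)), labels=list("abcd"))
        b = linear_kernel(rng.normal(size=(4, 2)), labels=list("abce"))
        with pytest.raises(AlignmentError):
            composite_weather_kernel([a, b], kind="linear")


class TestExpansion:
    def test_single_level_partner_reduces_to_plain_expansion(self, rng):
        K = linear_kernel(rng.normal(size=(3, 2)))
        Z = design_matrix([0, 1, 2, 0], [0, 1, 2])
        ones = KernelMatrix(np.ones((1, 1)), ["only"], "identity")
        Z1 = np.ones((4, 1))
        out = expand_kernel(K, Z[:, :], ones, Z1)
        plain = expand_kernel(K, Z)
        np.testing.assert_allclose(out.values, plain.values, atol=1e-12)

    def test_hadamard_of_psd_is_psd(self, rng):
        Ka = linear_kernel(rng.normal(size=(4, 3)))
        Kb = gaussian_kernel(rng.normal(size=(3, 2)), 1.0)
        Za = design_matrix([0, 1, 2, 3, 0, 1], range(4))
        Zb = design_matrix(["x", "x", "y", "y", "z", "z"], ["x", "y", "z"])
        out = expand_kernel(Ka, Za, Kb, Zb)
        w = np.linalg.eigvalsh(out.values)
        assert w.min() >= -1e-8 * max(w.max(), 1e-30)

    def test_toy_case_elementwise_loop(self):
        Ka = KernelMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["h1", "h2"], "linear")
        Kb = KernelMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]), ["e1", "e2"], "gaussian")
        recs_h = ["h1", "h2", "h1", "h2"]
        recs_e = ["e1", "e1", "e2", "e2"]
        Za = design_matrix(recs_h, ["h1", "h2"])
        Zb = design_matrix(recs_e, ["e1", "e2"])
        out = expand_kernel(Ka, Za, Kb, Zb)
        hi = {"h1": 0, "h2": 1}
        ei = {"e1": 0, "e2": 1}
        for i in range(4):
            for j in range(4):
                expect = (
                    Ka.values[hi[recs_h[i]], hi[recs_h[j]]]
                    * Kb.values[ei[recs_e[i]], ei[recs_e[j]]]
                )
                assert out.values[i, j] == pytest.approx(expect)

    def test_identity_partner_via_none(self):
        Ka = KernelMatrix(np.ones((2, 2)), ["h1", "h2"], "linear")
        Za = design_matrix(["h1", "h2", "h1"], ["h1", "h2"])
        Zb = design_matrix(["e1", "e1", "e2"], ["e1", "e2"])
        out = expand_kernel(Ka, Za, None, Zb)
        # identity partner zeroes similarities across environments
        assert out.values[0, 2] == 0.0
        assert out.values[0, 1] == 1.0


class TestEigendecompose:
    def test_identity_keeps_all(self):
        basis = eigendecompose(identity_kernel(5))
        np.testing.assert_allclose(basis.values, np.ones(5))
        assert basis.rank == 5

    def test_rank_one_kernel(self, rng):
        v = rng.normal(size=6)
        K = KernelMatrix(np.outer(v, v), list(range(6)), "linear")
        basis = eigendecompose(K)
        assert basis.rank == 1
        assert basis.values[0] == pytest.approx(v @ v)

    def test_captured_fraction_against_full_oracle(self, rng):
        X = rng.normal(size=(50, 8))
        K = linear_kernel(X)
        basis = eigendecompose(K, tol=1e-10, max_rank=4)
        w = np.linalg.eigvalsh(K.values)[::-1]
        expect = w[:4].sum() / np.clip(w, 0, None).sum()
        assert basis.variance_captured == pytest.approx(expect, rel=1e-10)

    def test_vectors_orthonormal(self, rng):
        K = gaussian_kernel(rng.normal(size=(20, 4)), 1.0)
        basis = eigendecompose(K)
        G = basis.vectors.T @ basis.vectors
        np.testing.assert_allclose(G, np.eye(basis.rank), atol=1e-8)

    def test_asymmetric_rejected(self):
        K = KernelMatrix.__new__(KernelMatrix)
        K.values = np.array([[1.0, 0.5], [0.0, 1.0]])
        K.labels = [0, 1]
        K.kind = "linear"
        with pytest.raises(InvalidKernelError):
            eigendecompose(K)


class TestKernelValidationSuite:
    def test_random_instances_pass_contracts(self, rng):
        for i in range(10):
            X = rng.normal(size=(12, 4))
            for K in (
                linear_kernel(X),
                gaussian_kernel(X, 0.5 + i / 5),
                arc_cosine_kernel(X, layers=1 + i % 3),
            ):
                validate_kernel(K)
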