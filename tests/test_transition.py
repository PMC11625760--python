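"""Pseudo-inverse and transition-matrix fitting."""

import numpy as np
import pytest

from latmap.matrices import FeatureMatrix, PairingError
from latmap.transition import (TransitionMatrix, fit_transition, map_features,
                               pseudo_inverse, reconstruction_error)


def _random_mixed_rank(rng, m, k):
    """Random matrix with rank drawn between 1 and min(m, k)."""
    r = int(rng.integers(1, min(m, k) + 1))
    return rng.normal(size=(m, r)) @ rng.normal(size=(r, k)), r


class TestPseudoInverse:
    def test_identity(self):
        res = pseudo_inverse(np.eye(3))
        np.testing.assert_allclose(res.A_plus, np.eye(3), atol=1e-12)
        assert res.effective_rank == 3

    def test_zero_matrix_maps_to_zero(self):
        # all singular values are zero and are mapped to zero, not inverted
        res = pseudo_inverse(np.zeros((2, 3)))
        assert res.A_plus.shape == (3, 2)
        assert np.all(res.A_plus == 0)
        assert res.effective_rank == 0

    def test_matches_normal_equations_oracle(self):
        # full column rank: A+ = (A^T A)^-1 A^T
        rng = np.random.default_rng(7)
        A = rng.uniform(-1, 1, size=(4, 2))
        oracle = np.linalg.inv(A.T @ A) @ A.T
        res = pseudo_inverse(A)
        np.testing.assert_allclose(res.A_plus, oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_moore_penrose_identities(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 40))
        k = int(rng.integers(2, 40))
        A, _ = _random_mixed_rank(rng, m, k)
        P = pseudo_inverse(A).A_plus
        nA, nP = np.linalg.norm(A), np.linalg.norm(P)
        assert np.linalg.norm(A @ P @ A - A) <= 1e-8 * max(nA, 1e-300)
        assert np.linalg.norm(P @ A @ P - P) <= 1e-8 * max(nP, 1e-300)
        assert np.linalg.norm(A @ P - (A @ P).T) <= 1e-8 * max(nA * nP, 1)
        assert np.linalg.norm(P @ A - (P @ A).T) <= 1e-8 * max(nA * nP, 1)

    def test_singular_values_sorted_and_mask_consistent(self):
        rng = np.random.default_rng(3)
        A, r = _random_mixed_rank(rng, 15, 9)
        res = pseudo_inverse(A)
        s = res.singular_values
        assert np.all(np.diff(s) <= 0)
        np.testing.assert_array_equal(res.kept_mask, s > res.cutoff)
        assert res.effective_rank == r

    def test_rejects_nonfinite_naming_position(self):
        A = np.ones((3, 3))
        A[1, 2] = np.nan
        with pytest.raises(ValueError, match="row 1, column 2"):
            pseudo_inverse(A)


class TestFitTransition:
    def test_identity_map(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6)) + 6 * np.eye(6)
        fa = FeatureMatrix(A, source="latent")
        fb = FeatureMatrix(A.copy(), sample_ids=fa.sample_ids, source="expert")
        T = fit_transition(fa, fb)
        np.testing.assert_allclose(T.T, np.eye(6), atol=1e-10)

    def test_planted_map_recovered(self, planted_map):
        T = fit_transition(planted_map["A"], planted_map["B"])
        assert T.residual_frobenius <= 1e-8
        # A has full column rank, so the least-squares solution is W itself
        np.testing.assert_allclose(T.T, planted_map["W"], atol=1e-8)

    def test_shape_contract_wide_latent(self):
        # latent dimension exceeding the sample-supported rank still yields
        # a k x l transition matrix
        rng = np.random.default_rng(21)
        m, k, l = 600, 96, 4
        ids = [f"s{i}" for i in range(m)]
        A = FeatureMatrix(rng.normal(size=(m, k)), sample_ids=ids)
        B = FeatureMatrix(rng.normal(size=(m, l)), sample_ids=ids,
                          source="expert")
        T = fit_transition(A, B)
        assert T.T.shape == (k, l)
        assert T.k == k and T.l == l

    def test_rejects_unpaired(self, planted_map):
        B = planted_map["B"]
        reordered = B.subset(list(range(B.n_samples))[::-1])
        with pytest.raises(PairingError):
            fit_transition(planted_map["A"], reordered)

    def test_least_squares_optimality_under_perturbation(self, planted_map):
        A, B = planted_map["A"], planted_map["B"]
        Bn = FeatureMatrix(B.values + 0.3, sample_ids=B.sample_ids,
                           source="expert")  # make the residual nonzero
        T = fit_transition(A, Bn)
        base = np.linalg.norm(A.values @ T.T - Bn.values, ord="fro")
        rng = np.random.default_rng(99)
        for _ in range(100):
            delta = rng.normal(size=T.T.shape)
            delta *= 0.01 / np.linalg.norm(delta, ord="fro")
            perturbed = np.linalg.norm(A.values @ (T.T + delta) - Bn.values,
                                       ord="fro")
            assert perturbed >= base

    def test_scale_equivariance(self, planted_map):
        A, B = planted_map["A"], planted_map["B"]
        c = 3.7
        Bc = FeatureMatrix(c * B.values, sample_ids=B.sample_ids,
                           source="expert")
        T1 = fit_transition(A, B)
        T2 = fit_transition(A, Bc)
        np.testing.assert_allclose(T2.T, c * T1.T, atol=1e-10)

    def test_standardized_fit_maps_in_original_units(self, planted_map):
        A, B = planted_map["A"], planted_map["B"]
        T = fit_transition(A, B, standardize=True)
        mapped = map_features(A.values, T)
        np.testing.assert_allclose(mapped, B.values, atol=1e-8)

    def test_serialization_roundtrip(self, planted_map, tmp_path):
        T = fit_transition(planted_map["A"], planted_map["B"])
        T.save(tmp_path / "T.npy")
        loaded = TransitionMatrix.load(tmp_path / "T.npy")
        np.testing.assert_array_equal(loaded.T, T.T)
        assert loaded.k == T.k and loaded.l == T.l
        assert loaded.residual_frobenius == T.residual_frobenius
        assert loaded.expert_feature_names == T.expert_feature_names


class TestMapFeatures:
    def test_identity_transition(self):
        T = TransitionMatrix(T=np.eye(4), k=4, l=4, residual_frobenius=0.0,
                             effective_rank=4, rcond=0.0)
        a = np.array([1.0, -2.0, 0.5, 3.0])
        np.testing.assert_array_equal(map_features(a, T), a)

    def test_linearity_zero_maps_to_zero(self):
        rng = np.random.default_rng(5)
        T = TransitionMatrix(T=rng.normal(size=(4, 2)), k=4, l=2,
                             residual_frobenius=0.0, effective_rank=2,
                             rcond=0.0)
        np.testing.assert_array_equal(map_features(np.zeros(4), T),
                                      np.zeros(2))

    def test_planted_row_maps_to_expert_row(self, planted_map):
        T = fit_transition(planted_map["A"], planted_map["B"])
        b0 = map_features(planted_map["A"].values[0], T)
        np.testing.assert_allclose(b0, planted_map["B"].values[0], atol=1e-8)

    def test_dimension_mismatch_names_k(self, planted_map):
        T = fit_transition(planted_map["A"], planted_map["B"])
        with pytest.raises(ValueError, match="k = 5"):
            map_features(np.zeros(7), T)


class TestReconstructionError:
    def test_exact_fit_zero_error(self, planted_map):
        T = fit_transition(planted_map["A"], planted_map["B"])
        err = reconstruction_error(planted_map["A"], planted_map["B"], T)
        assert err["frobenius"] <= 1e-8

    def test_matches_direct_arithmetic_with_noise(self, planted_map):
        rng = np.random.default_rng(42)
        A, B = planted_map["A"], planted_map["B"]
        Bn = FeatureMatrix(B.values + rng.normal(0, 0.1, B.values.shape),
                           sample_ids=B.sample_ids, source="expert")
        T = fit_transition(A, Bn)
        err = reconstruction_error(A, Bn, T)
        direct = np.linalg.norm(A.values @ T.T - Bn.values, ord="fro")
        assert err["frobenius"] == pytest.approx(direct, abs=1e-12)
        np.testing.assert_allclose(
            err["per_sample_euclidean"],
            np.linalg.norm(A.values @ T.T - Bn.values, axis=1), atol=1e-12)

    def test_single_sample_frobenius_equals_euclidean(self):
        A = FeatureMatrix(np.array([[1.0, 2.0]]), sample_ids=["x"])
        B = FeatureMatrix(np.array([[3.0]]), sample_ids=["x"], source="expert")
        T = fit_transition(A, B)
        Bo = FeatureMatrix(np.array([[5.0]]), sample_ids=["x"],
                           source="expert")
        err = reconstruction_error(A, Bo, T)
        assert err["frobenius"] == pytest.approx(err["per_sample_euclidean"][0])
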