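"""Relevance vector machine: kernels, posterior, evidence iteration, prediction."""

import numpy as np
import pytest

from dtirvm import (KernelSpec, RVMModel, TrainingConfig, design_matrix,
                    kernel_value, log_marginal_likelihood, posterior,
                    rvm_classify, rvm_fit, rvm_predict)
from dtirvm.rvm import RVMConvergenceWarning, kernel_matrix


class TestKernels:
    def test_poly2_at_origin(self):
        k = KernelSpec("poly2", 1.0)
        assert kernel_value(k, np.zeros(3), np.zeros(3)) == pytest.approx(1.0)

    def test_poly2_analytic(self):
        k = KernelSpec("poly2", 1.0)
        x = np.array([1.0, 1.0])
        assert kernel_value(k, x, x) == pytest.approx(9.0)  # (1 + 2)^2

    def test_poly2_width_scales_inner_product(self):
        k = KernelSpec("poly2", 2.0)
        x = np.array([1.0, 1.0])
        assert kernel_value(k, x, x) == pytest.approx(4.0)  # (1 + 2/2)^2

    def test_rbf_zero_distance(self):
        k = KernelSpec("rbf", 1.5)
        x = np.array([0.3, -2.0])
        assert kernel_value(k, x, x) == pytest.approx(1.0)

    def test_linear_is_dot_product(self):
        k = KernelSpec("linear")
        assert kernel_value(k, np.array([1.0, 2.0]),
                            np.array([3.0, -1.0])) == pytest.approx(1.0)

    def test_toolbox_spelling_accepted(self):
        assert KernelSpec("ploy2").name == "poly2"

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel_value(KernelSpec(), np.zeros(2), np.zeros(3))

    def test_invalid_width(self):
        with pytest.raises(ValueError, match="width"):
            KernelSpec("poly2", 0.0)


class TestDesignMatrix:
    def test_square_training_shape(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 3))
        phi = design_matrix(KernelSpec(), X, X)
        assert phi.shape == (6, 7)
        np.testing.assert_array_equal(phi[:, 0], 1.0)

    def test_single_zero_point(self):
        phi = design_matrix(KernelSpec("poly2", 1.0),
                            np.zeros((1, 2)), np.zeros((1, 2)))
        np.testing.assert_allclose(phi, [[1.0, 1.0]])

    def test_matches_entrywise_oracle(self):
        rng = np.random.default_rng(1)
        X, B = rng.standard_normal((4, 2)), rng.standard_normal((3, 2))
        for k in (KernelSpec("poly2"), KernelSpec("rbf", 0.7), KernelSpec("linear")):
            phi = design_matrix(k, X, B)
            assert phi.shape == (4, 4)
            for i in range(4):
                for j in range(3):
                    assert phi[i, j + 1] == pytest.approx(
                        kernel_value(k, X[i], B[j]), abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            design_matrix(KernelSpec(), np.empty((0, 2)), np.empty((0, 2)))


class TestPosterior:
    def test_infinite_prior_precision_zeroes_weights(self):
        rng = np.random.default_rng(2)
        phi = rng.standard_normal((8, 4))
        t = rng.integers(0, 2, 8).astype(float)
        _, u = posterior(phi, t, np.full(4, 1e12), sigma2=0.1)
        np.testing.assert_allclose(u, 0.0, atol=1e-6)

    def test_matches_dense_inverse_oracle(self):
        # three points, fixed hyperparameters, textbook evaluation
        rng = np.random.default_rng(3)
        phi = rng.standard_normal((3, 3))
        t = np.array([0.0, 1.0, 1.0])
        alpha = np.array([0.5, 1.0, 2.0])
        sigma2 = 0.3
        Sigma, u = posterior(phi, t, alpha, sigma2)
        Sigma_oracle = np.linalg.inv(phi.T @ phi / sigma2 + np.diag(alpha))
        u_oracle = Sigma_oracle @ phi.T @ t / sigma2
        np.testing.assert_allclose(Sigma, Sigma_oracle, atol=1e-8)
        np.testing.assert_allclose(u, u_oracle, atol=1e-8)

    def test_flat_prior_interpolates(self):
        rng = np.random.default_rng(4)
        phi = rng.standard_normal((4, 4)) + 4 * np.eye(4)  # well-conditioned
        t = np.array([1.0, 0.0, 1.0, 0.0])
        _, u = posterior(phi, t, np.zeros(4), sigma2=0.5)
        np.testing.assert_allclose(phi @ u, t, atol=1e-6)

    def test_ridge_closed_form_equivalence(self):
        # equal fixed alpha: u is ridge regression with penalty alpha*sigma2
        rng = np.random.default_rng(5)
        phi = rng.standard_normal((10, 5))
        t = rng.standard_normal(10)
        alpha, sigma2 = 2.0, 0.4
        _, u = posterior(phi, t, np.full(5, alpha), sigma2)
        lam = alpha * sigma2
        ridge = np.linalg.solve(phi.T @ phi + lam * np.eye(5), phi.T @ t)
        np.testing.assert_allclose(u, ridge, atol=1e-8)

    def test_defining_equations_satisfied(self):
        rng = np.random.default_rng(6)
        phi = rng.standard_normal((12, 6))
        t = rng.integers(0, 2, 12).astype(float)
        alpha = rng.uniform(0.1, 5.0, 6)
        sigma2 = 0.2
        Sigma, u = posterior(phi, t, alpha, sigma2)
        H = phi.T @ phi / sigma2 + np.diag(alpha)
        np.testing.assert_allclose(H @ Sigma, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(H @ u, phi.T @ t / sigma2, atol=1e-8)

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError, match="sigma2"):
            posterior(np.eye(2), np.zeros(2), np.ones(2), sigma2=0.0)


class TestFit:
    def test_separable_blobs_sparse_and_accurate(self, blob_data):
        X, y = blob_data
        model = rvm_fit(X, y)
        assert (rvm_classify(model, X) == y).mean() == 1.0
        assert model.n_relevance_vectors < len(y)
        assert model.metadata["converged"]

    def test_single_class_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="single class"):
            rvm_fit(rng.standard_normal((6, 2)), np.zeros(6))

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="NaN"):
            rvm_fit(X, np.array([0, 1]))

    def test_one_step_reduces_to_posterior(self, blob_data):
        # with tol=inf the first evidence check trivially passes, so the
        # returned weights are exactly the posterior at the initial alpha
        X, y = blob_data
        n = len(y)
        model = rvm_fit(X, y, cfg=TrainingConfig(max_iter=1, tol=np.inf))
        phi = design_matrix(KernelSpec(), X, X)
        _, u = posterior(phi, y, np.full(n + 1, 1.0 / n),
                         max(0.1 * y.var(), 1e-3))
        # the poly2 Gram is ill-conditioned, so two BLAS evaluations of the
        # same solve agree to ~1e-7, not machine precision
        np.testing.assert_allclose(model.bias, u[0], atol=1e-6)
        np.testing.assert_allclose(model.weights, u[1:], atol=1e-6)
        assert model.n_relevance_vectors == n

    def test_duplicated_training_set_same_decisions(self, blob_data):
        X, y = blob_data
        base = rvm_fit(X, y)
        dup = rvm_fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_array_equal(rvm_classify(dup, X), rvm_classify(base, X))
        np.testing.assert_allclose(rvm_predict(dup, X), rvm_predict(base, X),
                                   atol=0.05)

    def test_deterministic(self, blob_data):
        X, y = blob_data
        a, b = rvm_fit(X, y), rvm_fit(X, y)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.bias == b.bias
        np.testing.assert_array_equal(a.relevance_vectors, b.relevance_vectors)

    def test_gamma_in_unit_interval_and_sigma2_positive(self, blob_data):
        X, y = blob_data
        for update in (False, True):
            model = rvm_fit(X, y, cfg=TrainingConfig(update_sigma2=update))
            gamma = np.array(model.metadata["gamma_final"])
            assert np.all((gamma >= 0) & (gamma <= 1))
            assert model.sigma2_final > 0

    def test_monotone_evidence(self, blob_data):
        X, y = blob_data
        model = rvm_fit(X, y)
        ev = model.metadata["log_evidence_path"]
        assert len(ev) > 1
        assert all(b >= a - 1e-6 for a, b in zip(ev, ev[1:]))

    def test_pruning_consistency(self, blob_data):
        # pinning the pruned precisions at alpha_prune in the full basis
        # reproduces the pruned model's predictions
        X, y = blob_data
        n = len(y)
        cfg = TrainingConfig()
        model = rvm_fit(X, y, cfg=cfg)
        active = model.metadata["active_indices"]
        alpha_full = np.full(n + 1, cfg.alpha_prune)
        alpha_full[active] = model.alpha_final
        phi = design_matrix(model.kernel, X, X)
        _, u_full = posterior(phi, y, alpha_full, model.sigma2_final)
        rng = np.random.default_rng(8)
        Q = rng.standard_normal((15, 2)) * 3
        phi_q = design_matrix(model.kernel, Q, X)
        np.testing.assert_allclose(phi_q @ u_full, rvm_predict(model, Q),
                                   atol=1e-4)

    def test_nonconvergence_warns_and_returns_state(self, blob_data):
        X, y = blob_data
        with pytest.warns(RVMConvergenceWarning):
            model = rvm_fit(X, y, cfg=TrainingConfig(max_iter=2, tol=1e-12))
        assert not model.metadata["converged"]
        assert np.all(np.isfinite(rvm_predict(model, X)))

    def test_evidence_against_direct_formula(self, blob_data):
        X, y = blob_data
        n = len(y)
        phi = design_matrix(KernelSpec(), X, X)
        alpha = np.full(n + 1, 1.0 / n)
        sigma2 = 0.025
        omega = sigma2 * np.eye(n) + phi @ np.diag(1.0 / alpha) @ phi.T
        expected = (-0.5 * (n * np.log(2 * np.pi)
                            + np.linalg.slogdet(omega)[1]
                            + y @ np.linalg.solve(omega, y)))
        # Omega is poorly conditioned (low-rank poly2 Gram + small sigma2),
        # so two algebraically identical evaluations agree only loosely
        assert log_marginal_likelihood(phi, y, alpha, sigma2) == pytest.approx(
            expected, rel=1e-4)


class TestPredict:
    def _toy_model(self, weights, bias=0.0):
        return RVMModel(kernel=KernelSpec(), relevance_vectors=np.eye(2),
                        weights=np.asarray(weights, dtype=float), bias=bias,
                        bias_active=True, alpha_final=np.ones(3),
                        sigma2_final=0.1)

    def test_zero_weights_zero_scores(self):
        m = self._toy_model([0.0, 0.0])
        np.testing.assert_array_equal(rvm_predict(m, np.random.rand(4, 2)), 0.0)

    def test_bias_only(self):
        m = RVMModel(kernel=KernelSpec(), relevance_vectors=np.empty((0, 2)),
                     weights=np.empty(0), bias=0.7, bias_active=True,
                     alpha_final=np.ones(1), sigma2_final=0.1)
        np.testing.assert_allclose(rvm_predict(m, np.random.rand(5, 2)), 0.7)

    def test_hand_computed_expansion(self):
        rv = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        w = np.array([0.2, -0.5, 1.1])
        m = RVMModel(kernel=KernelSpec("poly2", 1.0), relevance_vectors=rv,
                     weights=w, bias=0.3, bias_active=True,
                     alpha_final=np.ones(4), sigma2_final=0.1)
        q = np.array([[2.0, -1.0]])
        expected = 0.3 + sum(
            wj * kernel_value(KernelSpec("poly2", 1.0), q[0], rv[j])
            for j, wj in enumerate(w))
        assert rvm_predict(m, q)[0] == pytest.approx(expected, abs=1e-12)

    def test_classification_thresholds(self):
        m = self._toy_model([0.0, 0.0])
        scores = np.array([0.2, 0.5, 0.9])
        assert np.array_equal((scores >= m.threshold).astype(int), [0, 1, 1])
        m.threshold = 0.0
        assert np.array_equal((scores >= m.threshold).astype(int), [1, 1, 1])

    def test_classify_is_thresholded_predict(self, blob_data):
        X, y = blob_data
        model = rvm_fit(X, y)
        np.testing.assert_array_equal(
            rvm_classify(model, X),
            (rvm_predict(model, X) >= model.threshold).astype(int))

    def test_dimension_mismatch(self, blob_data):
        X, y = blob_data
        model = rvm_fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            rvm_predict(model, np.zeros((2, 5)))

    def test_json_round_trip(self, tmp_path, blob_data):
        X, y = blob_data
        model = rvm_fit(X, y)
        model.to_json(tmp_path / "m.json")
        back = RVMModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(rvm_predict(back, X), rvm_predict(model, X),
                                   atol=1e-12)


def test_kernel_matrix_consistent_with_kernel_value():
    rng = np.random.default_rng(9)
    X, B = rng.standard_normal((3, 4)), rng.standard_normal((2, 4))
    k = KernelSpec("rbf", 1.3)
    K = kernel_matrix(k, X, B)
    for i in range(3):
        for j in range(2):
            assert K[i, j] == pytest.approx(kernel_value(k, X[i], B[j]), abs=1e-12)
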