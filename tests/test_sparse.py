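import warnings
from types import SimpleNamespace

import numpy as np
import pytest

import gcpca
from gcpca import (
    ConditionPair,
    GcPCA,
    SparseConfig,
    SparseGcPCA,
    build_theta,
    elastic_net_step,
    procrustes_step,
    rank_features,
    tikhonov_repair,
    variant_spec,
)
from gcpca.core import build_normalized_problem, build_shared_basis
from gcpca.preprocessing import center_features, compute_covariance

from conftest import diagonal_pair, random_pair


def _problem(pair, variant="v4", center=True):
    a = center_features(pair.data_a) if center else pair.data_a
    b = center_features(pair.data_b) if center else pair.data_b
    ca = compute_covariance(a).values
    cb = compute_covariance(b).values
    spec = variant_spec(variant)
    basis, _ = build_shared_basis(ConditionPair(a, b))
    return spec, build_normalized_problem(ca, cb, spec, basis)


class TestBuildTheta:
    def test_identical_conditions_zero_target(self, rng):
        a = rng.normal(size=(20, 4))
        spec, problem = _problem(ConditionPair(a, a.copy()))
        theta = build_theta(spec, problem)
        assert np.abs(theta).max() < 1e-10

    def test_diagonal_closed_form(self):
        spec, problem = _problem(diagonal_pair(), center=False)
        theta = build_theta(spec, problem)
        evals = np.sort(np.linalg.eigvalsh(theta))[::-1]
        np.testing.assert_allclose(evals, [0.6, 0.0], atol=1e-10)

    def test_v4_target_eigenvalues_bounded(self):
        for seed in range(20):
            spec, problem = _problem(random_pair(seed))
            evals = np.linalg.eigvalsh(build_theta(spec, problem))
            assert evals.min() >= -1 - 1e-9 and evals.max() <= 1 + 1e-9

    def test_v1_requires_covariances(self):
        with pytest.raises(ValueError, match="cov"):
            build_theta(variant_spec("v1", alpha=1.0), None)


class TestTikhonovRepair:
    def test_pd_input_unchanged(self):
        np.testing.assert_array_equal(tikhonov_repair(np.eye(2), 0.01), np.eye(2))

    def test_shift_closed_form(self):
        repaired = tikhonov_repair(np.diag([0.5, -0.5]), 0.01)
        np.testing.assert_allclose(repaired, np.diag([1.01, 0.01]), atol=1e-14)

    def test_eigenvectors_and_ordering_preserved(self, rng):
        x = rng.normal(size=(4, 4))
        theta = (x + x.T) / 2
        repaired = tikhonov_repair(theta, 1e-3)
        ev0, vec0 = np.linalg.eigh(theta)
        ev1, vec1 = np.linalg.eigh(repaired)
        assert ev1.min() > 0
        assert np.all(np.diff(ev1) >= -1e-12) == np.all(np.diff(ev0) >= -1e-12)
        for j in range(4):
            assert abs(abs(vec0[:, j] @ vec1[:, j]) - 1) < 1e-10


class TestProcrustesStep:
    def test_identity_target_returns_b(self, rng):
        b = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        np.testing.assert_allclose(procrustes_step(np.eye(4), b), b, atol=1e-12)

    def test_orthonormal_columns_contract(self, rng):
        theta_sqrt = gcpca.symmetric_sqrt(np.diag([2.0, 1.0, 0.5]))
        y = procrustes_step(theta_sqrt, rng.normal(size=(3, 2)))
        np.testing.assert_allclose(y.T @ y, np.eye(2), atol=1e-10)

    def test_matches_polar_decomposition_oracle(self, rng):
        x = rng.normal(size=(3, 3))
        theta_sqrt = gcpca.symmetric_sqrt(x @ x.T + np.eye(3))
        b = rng.normal(size=(3, 2))
        u, _, vt = np.linalg.svd(theta_sqrt @ theta_sqrt @ b, full_matrices=False)
        np.testing.assert_allclose(procrustes_step(theta_sqrt, b), u @ vt, atol=1e-10)

    def test_rank_deficient_b_errors(self):
        b = np.ones((3, 2))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            procrustes_step(np.eye(3), b)


class TestElasticNetStep:
    def test_unpenalized_recovers_targets(self):
        spec, problem = _problem(random_pair(0))
        theta = build_theta(spec, problem)
        theta_sqrt = gcpca.symmetric_sqrt(tikhonov_repair(theta, 1e-6))
        _, y = np.linalg.eigh(theta)
        y = y[:, ::-1][:, :2]
        config = SparseConfig(lasso_lambda=0.0, ridge_kappa=0.0)
        b = elastic_net_step(theta_sqrt, y, config, problem)
        np.testing.assert_allclose(b, y, atol=1e-8)

    def test_huge_lambda_zeroes_everything(self):
        spec, problem = _problem(random_pair(1))
        theta = build_theta(spec, problem)
        theta_sqrt = gcpca.symmetric_sqrt(tikhonov_repair(theta, 1e-6))
        _, y = np.linalg.eigh(theta)
        config = SparseConfig(lasso_lambda=1e6)
        b = elastic_net_step(theta_sqrt, y[:, :2], config, problem)
        assert np.abs(b).max() == 0.0

    def test_objective_not_worse_than_candidates(self):
        # the returned coefficients must beat both the dense target and zero
        spec, problem = _problem(random_pair(2, p=4))
        theta = build_theta(spec, problem)
        theta_sqrt = gcpca.symmetric_sqrt(tikhonov_repair(theta, 1e-6))
        _, y = np.linalg.eigh(theta)
        y = y[:, ::-1][:, :2]
        config = SparseConfig(lasso_lambda=0.02, ridge_kappa=1e-4)
        b = elastic_net_step(theta_sqrt, y, config, problem)

        def objective(beta, target):
            img = problem.basis_j @ (problem.m_inv_diag[:, None] * beta)
            return (
                np.sum((theta_sqrt @ (target - beta)) ** 2)
                + config.ridge_kappa * np.sum(img**2)
                + config.lasso_lambda * np.sum(np.abs(img))
            )

        for j in range(2):
            got = objective(b[:, [j]], y[:, [j]])
            assert got <= objective(y[:, [j]], y[:, [j]]) + 1e-10
            assert got <= objective(np.zeros_like(y[:, [j]]), y[:, [j]]) + 1e-10


class TestSparseFit:
    def test_lambda_zero_matches_dense(self):
        pair = random_pair(3, n=40, p=5)
        dense = GcPCA("v4").fit(pair)
        sparse = SparseGcPCA(lasso_lambda=0.0, ridge_kappa=0.0, variant="v4").fit(pair)
        np.testing.assert_allclose(
            np.abs(sparse.loadings_), np.abs(dense.loadings_), atol=1e-6
        )

    def test_huge_lambda_all_zero_with_warning(self):
        pair = random_pair(4)
        with pytest.warns(RuntimeWarning, match="sparsified"):
            model = SparseGcPCA(lasso_lambda=1e6, variant="v4").fit(pair)
        assert np.abs(model.loadings_).max() == 0.0
        assert model.fully_sparsified_ == list(range(model.n_components_))

    def test_nonzero_counts_between_limits(self):
        pair = random_pair(5, n=40, p=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dense_nnz = (
                SparseGcPCA(lasso_lambda=0.0, ridge_kappa=0.0, variant="v4")
                .fit(pair)
                .nonzero_counts_.sum()
            )
            mid_nnz = (
                SparseGcPCA(lasso_lambda=0.05, variant="v4")
                .fit(pair)
                .nonzero_counts_.sum()
            )
        assert dense_nnz == 6 * 6
        assert 0 < mid_nnz < dense_nnz

    def test_objective_history_monotone(self):
        pair = random_pair(6, n=40, p=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SparseGcPCA(lasso_lambda=0.02, variant="v4").fit(pair)
        for history in (model.objective_history_, model.objective_history_b_ or []):
            diffs = np.diff(np.asarray(history))
            assert np.all(diffs <= 1e-8 * np.abs(np.asarray(history[:-1])) + 1e-10)

    def test_v1_sparse_runs_in_feature_space(self):
        pair = random_pair(7, n=40, p=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SparseGcPCA(lasso_lambda=0.05, variant="v1", alpha=1.5).fit(pair)
        assert model.loadings_.shape == (5, 5)

    def test_orthogonal_variant_rejected(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            SparseGcPCA(lasso_lambda=0.1, variant="v4.1").fit(random_pair(1))

    def test_fig1_support_concentrates_on_truth(self, fig1_truth, fig1_standardized):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SparseGcPCA(lasso_lambda=3e-3, variant="v4").fit(fig1_standardized)
        loadings = model.loadings_
        top_peaks = {int(np.abs(loadings[:, j]).argmax()) + 1 for j in (0, 1)}
        bottom_peaks = {int(np.abs(loadings[:, j]).argmax()) + 1 for j in (-1, -2)}
        assert top_peaks == set(fig1_truth.enriched_a)
        assert bottom_peaks == set(fig1_truth.enriched_b)
        # the sparsified components keep only a handful of features
        assert model.nonzero_counts_[[0, 1, -2, -1]].max() <= 10


class TestRankFeatures:
    def _model(self, loadings, eigenvalues):
        return SimpleNamespace(
            loadings_=np.asarray(loadings, dtype=float),
            eigenvalues_=np.asarray(eigenvalues, dtype=float),
        )

    def test_single_component_unit_eigenvalue(self):
        scores, _ = rank_features(self._model([[0.6], [-0.8]], [1.0]))
        np.testing.assert_allclose(scores, [0.6, 0.8])

    def test_homogeneous_in_eigenvalues(self):
        model1 = self._model([[0.6, 0.1], [-0.8, 0.3]], [1.0, 2.0])
        model2 = self._model([[0.6, 0.1], [-0.8, 0.3]], [2.0, 4.0])
        s1, _ = rank_features(model1)
        s2, _ = rank_features(model2)
        np.testing.assert_allclose(s2, 2 * s1)

    def test_two_component_closed_form(self):
        scores, ranking = rank_features(self._model([[1, 0], [0, 1]], [3.0, 4.0]))
        np.testing.assert_allclose(scores, [3.0, 4.0])
        assert ranking.tolist() == [1, 0]

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_features(self._model([[1.0]], [1.0]), component_subset=[])


def test_sparsity_path_reports_decreasing_support():
    pair = random_pair(8, n=40, p=5)
    path = gcpca.sparsity_path(pair, "v4", lambdas=[1e-4, 1e-1, 1e3])
    assert [lam for lam, _, _ in path] == [1e-4, 1e-1, 1e3]
    totals = [total for _, total, _ in path]
    assert totals[0] >= totals[-1]
    assert totals[-1] == 0
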