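"""Sparse gcPCA via the elastic-net reformulation of sparse PCA.

The dense solution diagonalizes a variant-specific target matrix Theta in the
denominator-whitened space (for v4, ``Theta = M^-1 J' (C_A - C_B) J M^-1``;
for v1/cPCA, ``Theta = C_A - alpha C_B`` in feature space). Sparsification
alternates two steps from the dense components Y:

* **B given Y** — each coefficient column solves an elastic net whose fit term
  is ``||Theta^1/2 y_j - Theta^1/2 beta_j||^2`` and whose L1/L2 penalties act
  on the *feature-space* image ``J M^-1 beta_j``, so the resulting loadings
  (not the whitened coefficients) are sparse.
* **Y given B** — a reduced-rank Procrustes rotation, ``Y = U V'`` from the
  SVD of ``Theta B``.

Theta can be indefinite (its eigenvalues are bounded below by -1 for v3/v4),
so a Tikhonov shift first raises all eigenvalues above zero; the shift changes
no eigenvectors and no eigenvalue ordering. Final loadings are ``J M^-1 B``
with nonzero columns rescaled to unit norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.utils.validation import check_is_fitted

from .core import (
    GcPCA,
    NormalizedProblem,
    VariantSpec,
    _finalize_loadings,
    build_normalized_problem,
    build_shared_basis,
    symmetric_sqrt,
    variant_spec,
)
from .preprocessing import ConditionPair, _as_matrix, center_features, compute_covariance

__all__ = [
    "SparseConfig",
    "SparseGcPCA",
    "build_theta",
    "tikhonov_repair",
    "elastic_net_step",
    "procrustes_step",
    "fit_sparse_gcpca",
    "rank_features",
    "sparsity_path",
]


@dataclass
class SparseConfig:
    """Penalties and iteration controls for the alternating sparse solver.

    ``lasso_lambda`` (L1) drives sparsity and is shared across components;
    ``ridge_kappa`` (L2) is a small stabilizer for rank-deficient problems.
    """

    lasso_lambda: float
    ridge_kappa: float = 1e-4
    n_components: int | None = None
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    tikhonov_epsilon: float | None = None
    max_inner_iterations: int = 1000
    inner_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.lasso_lambda < 0:
            raise ValueError("lasso_lambda must be >= 0")
        if self.ridge_kappa < 0:
            raise ValueError("ridge_kappa must be >= 0")
        if self.tikhonov_epsilon is not None and self.tikhonov_epsilon <= 0:
            raise ValueError("tikhonov_epsilon must be > 0")


# --------------------------------------------------------------------------
# component steps
# --------------------------------------------------------------------------

def build_theta(
    variant: VariantSpec,
    problem: NormalizedProblem | None,
    *,
    cov_a: np.ndarray | None = None,
    cov_b: np.ndarray | None = None,
) -> np.ndarray:
    """Variant-specific sparse target matrix Theta.

    Ratio variants (v2-v4) read Theta directly off the whitened problem
    (``M^-1 J' N J M^-1``); v1 needs the raw covariances and returns
    ``C_A - alpha C_B`` in feature space.
    """
    if variant.name == "v1":
        if cov_a is None or cov_b is None:
            raise ValueError("v1 needs cov_a and cov_b to build Theta")
        theta = cov_a - variant.alpha * cov_b
        return 0.5 * (theta + theta.T)
    if problem is None:
        raise ValueError(f"variant {variant.name} needs a NormalizedProblem")
    return problem.reduced_matrix


def tikhonov_repair(theta: np.ndarray, epsilon: float) -> np.ndarray:
    """Shift an indefinite symmetric matrix to positive definiteness.

    Adds ``(|lambda_min| + epsilon) I`` when the smallest eigenvalue is
    non-positive; eigenvectors and eigenvalue ordering are unchanged.
    """
    theta = 0.5 * (theta + np.asarray(theta, dtype=float).T)
    lam_min = np.linalg.eigvalsh(theta)[0]
    if lam_min > 0:
        return theta
    return theta + (abs(lam_min) + epsilon) * np.eye(theta.shape[0])


def _design_matrix(theta_sqrt: np.ndarray, problem: NormalizedProblem | None):
    """Design for the feature-space reparameterization of the elastic net.

    With ``w = J M^-1 beta`` (so ``beta = M J' w``), the fit term
    ``Theta^1/2 beta`` becomes ``(Theta^1/2 M J') w`` and the penalties act
    directly on ``w``. For v1 the whitening is trivial and the design is
    ``Theta^1/2`` itself.
    """
    if problem is None:
        return theta_sqrt
    return theta_sqrt @ problem.sqrt_m @ problem.basis_j.T


def _elastic_net_coefficients(
    theta_sqrt: np.ndarray,
    rotation_y: np.ndarray,
    config: SparseConfig,
    problem: NormalizedProblem | None,
) -> np.ndarray:
    """Feature-space coefficients w minimizing the reparameterized elastic net."""
    design = _design_matrix(theta_sqrt, problem)
    n_rows = design.shape[0]
    targets = theta_sqrt @ np.atleast_2d(rotation_y.T).T
    lam, kappa = config.lasso_lambda, config.ridge_kappa

    if lam == 0 and kappa == 0:
        w, *_ = np.linalg.lstsq(design, targets, rcond=None)
    elif lam == 0:
        gram = design.T @ design + kappa * np.eye(design.shape[1])
        w = np.linalg.solve(gram, design.T @ targets)
    else:
        # map ||r - Dw||^2 + kappa||w||^2 + lambda||w||_1 onto sklearn's
        # 1/(2n)||r - Dw||^2 + a*l1*||w||_1 + a*(1-l1)/2*||w||^2
        enet_alpha = (lam / 2.0 + kappa) / n_rows
        l1_ratio = (lam / 2.0) / (lam / 2.0 + kappa)
        solver = ElasticNet(
            alpha=enet_alpha,
            l1_ratio=l1_ratio,
            fit_intercept=False,
            max_iter=config.max_inner_iterations,
            tol=config.inner_tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            solver.fit(design, targets)
        w = solver.coef_.T
        if w.ndim == 1:
            w = w[:, None]
        n_iter = np.max(solver.n_iter_) if solver.n_iter_ is not None else 0
        if n_iter >= config.max_inner_iterations:
            warnings.warn(
                "elastic-net inner solver hit max_inner_iterations; "
                "coefficients may not be fully converged",
                RuntimeWarning,
            )
    return np.atleast_2d(w)


def elastic_net_step(
    theta_sqrt: np.ndarray,
    rotation_y: np.ndarray,
    config: SparseConfig,
    problem: NormalizedProblem | None,
) -> np.ndarray:
    """Solve the penalized regression for every component column.

    Returns the whitened-space coefficient matrix B whose feature-space image
    ``J M^-1 B`` carries the elastic-net penalties.
    """
    w = _elastic_net_coefficients(theta_sqrt, rotation_y, config, problem)
    if problem is None:
        return w
    return problem.sqrt_m @ (problem.basis_j.T @ w)


def procrustes_step(theta_sqrt: np.ndarray, coefficient_matrix_b: np.ndarray) -> np.ndarray:
    """Orthonormal rotation best aligned with ``Theta B`` (SVD polar factor)."""
    b = np.atleast_2d(np.asarray(coefficient_matrix_b, dtype=float))
    target = theta_sqrt @ (theta_sqrt @ b)
    u, svals, vt = np.linalg.svd(target, full_matrices=False)
    if svals.size and svals[-1] <= 1e-12 * max(svals[0], 1.0):
        raise np.linalg.LinAlgError(
            "coefficient matrix is rank-deficient; reduce n_components or "
            "lasso_lambda"
        )
    return u @ vt


def _penalized_objective(theta_sqrt, y, b, config, problem) -> float:
    """Joint objective ``||T - T B Y'||_F^2 + penalties`` of the alternating scheme.

    Written in the expanded form valid for orthonormal-column Y; both the
    coefficient update and the Procrustes rotation decrease it, so it is the
    quantity to monitor for monotone convergence.
    """
    tb = theta_sqrt @ b
    ty = theta_sqrt @ y
    w = b if problem is None else problem.basis_j @ (problem.m_inv_diag[:, None] * b)
    return float(
        np.sum(theta_sqrt**2)
        - 2.0 * np.sum(tb * ty)
        + np.sum(tb**2)
        + config.ridge_kappa * np.sum(w**2)
        + config.lasso_lambda * np.sum(np.abs(w))
    )


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

def _alternate(theta, y0, config: SparseConfig, problem, n_features: int):
    """Run the B-step / Y-step alternation from dense components ``y0``.

    Returns feature-space coefficients w, whitened coefficients B, the final
    rotation Y, the objective history, iterations used and a convergence flag.
    """
    evals = np.linalg.eigvalsh(theta)
    eps = config.tikhonov_epsilon
    if eps is None:
        eps = max(1e-6 * float(np.mean(np.abs(evals))), 1e-12)
    theta_plus = tikhonov_repair(theta, eps)
    theta_sqrt = symmetric_sqrt(theta_plus)

    y = y0
    k, m = y0.shape
    b_mat = np.zeros((k, m))
    w_mat = np.zeros((n_features, m))
    history: list[float] = []
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iterations + 1):
        w_new = _elastic_net_coefficients(theta_sqrt, y, config, problem)
        b_new = (
            w_new
            if problem is None
            else problem.sqrt_m @ (problem.basis_j.T @ w_new)
        )
        history.append(_penalized_objective(theta_sqrt, y, b_new, config, problem))
        change = np.linalg.norm(b_new - b_mat)
        scale = max(np.linalg.norm(b_mat), 1e-12)
        b_mat, w_mat = b_new, w_new
        col_norms = np.linalg.norm(b_mat, axis=0)
        if not np.any(col_norms > 0):
            converged = True
            break
        if change / scale < config.convergence_tol:
            converged = True
            break
        nonzero = col_norms > 0
        try:
            y_rot = procrustes_step(theta_sqrt, b_mat[:, nonzero])
        except np.linalg.LinAlgError:
            warnings.warn(
                "coefficient matrix became rank-deficient during the "
                "alternating iterations; stopping early (consider a smaller "
                "lasso_lambda or fewer components)",
                RuntimeWarning,
            )
            converged = True
            break
        y = y.copy()
        y[:, nonzero] = y_rot
    if not converged:
        warnings.warn(
            f"sparse gcPCA did not converge in {config.max_iterations} "
            f"iterations (last objective {history[-1]:.6g})",
            RuntimeWarning,
        )
    return w_mat, b_mat, y, history, n_iter, converged


class SparseGcPCA(TransformerMixin, BaseEstimator):
    """Sparse gcPCA with elastic-net feature selection.

    Parameters
    ----------
    lasso_lambda : float
        L1 penalty on the feature-space loadings; the knob controlling
        sparsity. There is no universal default — sweep a grid with
        :func:`sparsity_path` to choose one.
    variant : str, default="v4"
        ``v1`` (needs ``alpha``), ``v2``, ``v3`` or ``v4``. Orthogonal
        ``.1`` variants cannot be sparsified.
    ridge_kappa : float, default=1e-4
        Small L2 penalty repairing rank deficiency.
    n_components : int, optional
        How many leading components to sparsify (default: all; for symmetric
        variants the trailing components are the B-enriched ones, so the
        default keeps both ends).

    Attributes
    ----------
    loadings_ : ndarray of shape (p, k)
        Sparse feature-space loadings, unit-norm nonzero columns, ordered by
        the dense eigenvalues (descending).
    eigenvalues_ : ndarray
        Dense-variant eigenvalues of the sparsified components.
    n_iter_ : int
        Outer alternating iterations used.
    objective_history_ : list of float
        Penalized objective after each outer iteration (non-increasing up to
        solver tolerance).
    """

    def __init__(
        self,
        lasso_lambda: float,
        *,
        variant: str = "v4",
        alpha: float | None = None,
        ridge_kappa: float = 1e-4,
        n_components: int | None = None,
        max_iterations: int = 200,
        convergence_tol: float = 1e-6,
        tikhonov_epsilon: float | None = None,
        center: bool = True,
        rank_tol: float = 1e-10,
    ):
        self.lasso_lambda = lasso_lambda
        self.variant = variant
        self.alpha = alpha
        self.ridge_kappa = ridge_kappa
        self.n_components = n_components
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.tikhonov_epsilon = tikhonov_epsilon
        self.center = center
        self.rank_tol = rank_tol

    def _config(self) -> SparseConfig:
        return SparseConfig(
            lasso_lambda=self.lasso_lambda,
            ridge_kappa=self.ridge_kappa,
            n_components=self.n_components,
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
            tikhonov_epsilon=self.tikhonov_epsilon,
        )

    def fit(self, X, Y=None):
        """Fit the sparse contrast to condition A (``X``) versus B (``Y``)."""
        spec = variant_spec(self.variant, self.alpha)
        if spec.orthogonal:
            raise ValueError(
                "sparse and orthogonal constraints are mutually exclusive; "
                f"use the base variant instead of {spec.name}"
            )
        config = self._config()

        if isinstance(X, ConditionPair):
            pair = X
        else:
            if Y is None:
                raise ValueError("fit requires both conditions: fit(A, B)")
            pair = ConditionPair(X, Y)
        a = center_features(pair.data_a) if self.center else pair.data_a
        b = center_features(pair.data_b) if self.center else pair.data_b
        cov_a = compute_covariance(a).values
        cov_b = compute_covariance(b).values

        if spec.name == "v1":
            problem = None
            theta = build_theta(spec, None, cov_a=cov_a, cov_b=cov_b)
        else:
            basis, _ = build_shared_basis(ConditionPair(a, b), self.rank_tol)
            problem = build_normalized_problem(cov_a, cov_b, spec, basis, self.rank_tol)
            theta = build_theta(spec, problem)

        dense_evals, dense_y = np.linalg.eigh(theta)
        order = np.argsort(dense_evals)[::-1]
        dense_evals, dense_y = dense_evals[order], dense_y[:, order]
        k = theta.shape[0]
        m = config.n_components if config.n_components is not None else k
        if not 1 <= m <= k:
            raise ValueError(f"n_components must be in [1, {k}]")
        n_features = pair.n_features

        # For the symmetric variant, components with negative eigenvalues are
        # B-enriched; running them through the Tikhonov-repaired Theta would
        # give the most-negative direction a near-zero target weight and the
        # lasso would zero it immediately. Antisymmetry (swapping A and B
        # negates Theta) lets us sparsify that side against -Theta instead.
        if spec.symmetric:
            sides = [
                ("pos", theta, np.flatnonzero(dense_evals[:m] >= 0)),
                ("neg", -theta, np.flatnonzero(dense_evals[:m] < 0)),
            ]
        else:
            sides = [("pos", theta, np.arange(m))]

        w_mat = np.zeros((n_features, m))
        b_mat = np.zeros((k, m))
        y_mat = np.zeros((k, m))
        histories: dict[str, list[float]] = {}
        n_iter = 0
        for side, side_theta, cols in sides:
            if cols.size == 0:
                continue
            y0 = dense_y[:, cols]
            if side == "neg":
                y0 = y0[:, ::-1]  # most B-enriched first for -Theta
            w, b_side, y_side, history, iters, _ = _alternate(
                side_theta, y0, config, problem, n_features
            )
            if side == "neg":
                w, b_side, y_side = w[:, ::-1], b_side[:, ::-1], y_side[:, ::-1]
            w_mat[:, cols] = w
            b_mat[:, cols] = b_side
            y_mat[:, cols] = y_side
            histories[side] = history
            n_iter = max(n_iter, iters)

        if not np.any(np.linalg.norm(b_mat, axis=0) > 0):
            warnings.warn(
                "all components fully sparsified (loadings are zero); "
                "lasso_lambda is likely too large",
                RuntimeWarning,
            )

        if problem is None:
            loadings = w_mat
        else:
            # project onto the shared subspace (exact identity when k = p)
            loadings = problem.basis_j @ (problem.basis_j.T @ w_mat)
            # the projection smears exact zeros by round-off; restore them
            smear = (np.abs(w_mat) == 0) & (np.abs(loadings) < 1e-10)
            loadings[smear] = 0.0
        self.loadings_ = _finalize_loadings(loadings)
        self.eigenvalues_ = dense_evals[:m]
        self.normalized_components_y_ = y_mat
        self.coefficients_b_ = b_mat
        self.theta_ = theta
        self.basis_j_ = problem.basis_j if problem is not None else np.eye(k)
        self.sqrt_m_ = problem.sqrt_m if problem is not None else np.eye(k)
        self.rank_k_ = k
        self.variant_ = spec
        self.n_features_in_ = pair.n_features
        self.feature_names_in_ = pair.feature_names
        self.n_components_ = m
        self.n_iter_ = n_iter
        self.objective_history_ = histories.get("pos", [])
        self.objective_history_b_ = histories.get("neg", None)
        self.nonzero_counts_ = (np.abs(self.loadings_) > 0).sum(axis=0)
        self.fully_sparsified_ = np.flatnonzero(self.nonzero_counts_ == 0).tolist()
        return self

    def transform(self, X) -> np.ndarray:
        """Project data onto the sparse components: ``scores = X @ loadings``."""
        check_is_fitted(self, "loadings_")
        arr = _as_matrix(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"data has {arr.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        return arr @ self.loadings_

    def fit_transform(self, X, Y=None):
        self.fit(X, Y)
        data = X.data_a if isinstance(X, ConditionPair) else X
        return self.transform(data)


def fit_sparse_gcpca(
    pair: ConditionPair,
    variant: str = "v4",
    config: SparseConfig | None = None,
    *,
    alpha: float | None = None,
    center: bool = True,
    rank_tol: float = 1e-10,
) -> SparseGcPCA:
    """Fit sparse gcPCA from a :class:`SparseConfig`; returns the estimator."""
    if config is None:
        raise ValueError("a SparseConfig (with lasso_lambda) is required")
    model = SparseGcPCA(
        lasso_lambda=config.lasso_lambda,
        variant=variant,
        alpha=alpha,
        ridge_kappa=config.ridge_kappa,
        n_components=config.n_components,
        max_iterations=config.max_iterations,
        convergence_tol=config.convergence_tol,
        tikhonov_epsilon=config.tikhonov_epsilon,
        center=center,
        rank_tol=rank_tol,
    )
    return model.fit(pair)


# --------------------------------------------------------------------------
# feature ranking and lambda exploration
# --------------------------------------------------------------------------

def rank_features(model, component_subset=None):
    """Per-feature importance: l2-norm of eigenvalue-weighted loadings.

    ``score_f = sqrt( sum_c (loading_fc * eigenvalue_c)^2 )`` over the selected
    components. Returns ``(scores, ranking)`` where ``ranking`` lists feature
    indices in descending score order.
    """
    if not hasattr(model, "loadings_"):
        raise ValueError("model is not fitted (no loadings_)")
    loadings = model.loadings_
    eigenvalues = model.eigenvalues_
    if component_subset is not None:
        component_subset = np.asarray(component_subset, dtype=int)
        if component_subset.size == 0:
            raise ValueError("component_subset must not be empty")
        loadings = loadings[:, component_subset]
        eigenvalues = eigenvalues[component_subset]
    weighted = loadings * eigenvalues
    scores = np.linalg.norm(weighted, axis=1)
    ranking = np.argsort(scores)[::-1]
    return scores, ranking


def sparsity_path(
    pair: ConditionPair,
    variant: str = "v4",
    lambdas=None,
    *,
    alpha: float | None = None,
    n_components: int | None = None,
    ridge_kappa: float = 1e-4,
    center: bool = True,
):
    """Nonzero-loading counts across a lasso_lambda grid (helper for choosing it).

    Returns a list of ``(lambda, total_nonzero, per_component_counts)`` tuples
    for a log-spaced grid (default ``10^-4 ... 10``).
    """
    if lambdas is None:
        lambdas = np.logspace(-4, 1, 8)
    out = []
    for lam in lambdas:
        model = SparseGcPCA(
            lasso_lambda=float(lam),
            variant=variant,
            alpha=alpha,
            ridge_kappa=ridge_kappa,
            n_components=n_components,
            center=center,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            model.fit(pair)
        out.append((float(lam), int(model.nonzero_counts_.sum()), model.nonzero_counts_.copy()))
    return out
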