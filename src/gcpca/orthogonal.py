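"""Feature-space-orthogonal gcPCA via iterative basis deflation.

Ratio-variant components are orthogonal in the denominator-whitened space, not
in the original feature space. The ``.1`` variants restore feature-space
orthogonality one component at a time: solve the reduced eigenproblem on the
current basis, accept the extreme eigenvector mapped back to feature space,
then deflate the basis to the orthogonal complement of the accepted component
and re-solve. For the symmetric variant the accepted extreme alternates
between the largest (A-enriched) and smallest (B-enriched) eigenvalue; the
asymmetric variants always take the largest, since their smallest eigenvalue
carries no B-enrichment meaning.
"""

from __future__ import annotations

import numpy as np

from .core import (
    VariantSpec,
    _finalize_loadings,
    build_normalized_problem,
    build_shared_basis,
)
from .preprocessing import ConditionPair

__all__ = ["deflate_basis", "fit_orthogonal_gcpca"]


def deflate_basis(basis_j: np.ndarray, x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the part of ``span(basis_j)`` orthogonal to ``x``.

    Regresses ``x`` out of the basis (``J - x x' J``) and keeps the left
    singular vectors belonging to the surviving rank, i.e. one column fewer.

    Raises if ``x`` has no component inside ``span(basis_j)`` (nothing to
    deflate).
    """
    basis_j = np.asarray(basis_j, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if abs(np.linalg.norm(x) - 1.0) > 1e-8:
        raise ValueError("x must be a unit vector")
    coords = x @ basis_j
    if np.linalg.norm(coords) <= tol:
        raise ValueError("x is orthogonal to the basis span; nothing to deflate")
    deflated = basis_j - np.outer(x, coords)
    u, svals, _ = np.linalg.svd(deflated, full_matrices=False)
    keep = basis_j.shape[1] - 1
    if keep == 0:
        return u[:, :0]
    return u[:, :keep]


def _fit_deflating(model, pair: ConditionPair, cov_a, cov_b, spec: VariantSpec) -> None:
    """Fill a :class:`~gcpca.core.GcPCA` with deflation-constrained components."""
    basis, k0 = build_shared_basis(pair, model.rank_tol)
    n_components = model.n_components if model.n_components is not None else k0

    loadings: list[np.ndarray] = []
    eigenvalues: list[float] = []
    basis_i = basis
    first_problem = None
    for i in range(n_components):
        if basis_i.shape[1] == 0:
            break
        problem = build_normalized_problem(
            cov_a, cov_b, spec, basis_i, model.rank_tol
        )
        if first_problem is None:
            first_problem = problem
        evals, y = np.linalg.eigh(problem.reduced_matrix)
        take_largest = (not spec.symmetric) or (i % 2 == 0)
        idx = evals.size - 1 if take_largest else 0
        x = problem.basis_j @ (problem.m_inv_diag * y[:, idx])
        x /= np.linalg.norm(x)
        # guard against round-off drift from previously accepted components
        for prev in loadings:
            x -= prev * (prev @ x)
        x /= np.linalg.norm(x)
        loadings.append(x)
        eigenvalues.append(float(evals[idx]))
        if problem.basis_j.shape[1] <= 1:
            basis_i = problem.basis_j[:, :0]
        else:
            basis_i = deflate_basis(problem.basis_j, x)

    order = np.argsort(eigenvalues)[::-1]
    x_mat = np.column_stack([loadings[i] for i in order])
    model.loadings_ = _finalize_loadings(x_mat)
    model.eigenvalues_ = np.asarray(eigenvalues, dtype=float)[order]
    model.normalized_components_y_ = None
    model.basis_j_ = first_problem.basis_j
    model.sqrt_m_ = first_problem.sqrt_m
    model.rank_k_ = first_problem.rank_k
    model.n_iterations_ = len(eigenvalues)


def fit_orthogonal_gcpca(
    pair: ConditionPair,
    variant: str = "v4.1",
    *,
    n_components: int | None = None,
    center: bool = True,
    rank_tol: float = 1e-10,
):
    """Fit a feature-space-orthogonal variant (``v2.1``/``v3.1``/``v4.1``)."""
    from .core import GcPCA, variant_spec

    spec = variant_spec(variant)
    if not spec.orthogonal:
        raise ValueError(
            f"{variant} has no orthogonality constraint; use fit_gcpca instead"
        )
    model = GcPCA(
        variant=variant, n_components=n_components, center=center, rank_tol=rank_tol
    )
    return model.fit(pair)
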