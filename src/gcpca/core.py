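"""Dense contrastive PCA estimators.

Given two conditions A and B with covariances ``C_A`` and ``C_B``, each variant
maximizes a Rayleigh-quotient contrast over unit feature-space directions x:

=========  ==========================================  =================
variant    objective                                   eigenvalue range
=========  ==========================================  =================
``v1``     x' (C_A - alpha C_B) x        (cPCA)        unbounded
``v2``     x' C_A x / x' C_B x                         [0, inf)
``v3``     x' (C_A - C_B) x / x' C_B x                 [-1, inf)
``v4``     x' (C_A - C_B) x / x' (C_A + C_B) x         [-1, 1]
=========  ==========================================  =================

The ratio objectives are solved on the joint principal subspace: an orthonormal
basis J of the row-wise concatenation of A and B is built (discarding
numerically-zero directions), the denominator is reduced to ``J' S J`` and its
symmetric square root M computed, and the eigendecomposition of
``M^-1 J' N J M^-1`` yields normalized-space components Y. Feature-space
loadings are ``X = J M^-1 Y`` (columns rescaled to unit norm). The ``.1``
variants (``v2.1``/``v3.1``/``v4.1``) additionally constrain loadings to be
orthogonal in feature space via iterative basis deflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import SpectralClustering
from sklearn.utils.validation import check_is_fitted

from .preprocessing import (
    ConditionPair,
    _as_matrix,
    center_features,
    compute_covariance,
)

__all__ = [
    "VariantSpec",
    "variant_spec",
    "NormalizedProblem",
    "GcPCA",
    "build_shared_basis",
    "symmetric_sqrt",
    "build_normalized_problem",
    "fit_gcpca",
    "fit_cpca",
    "transform",
    "subspace_affinity",
    "select_alphas",
]


# --------------------------------------------------------------------------
# variant registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """How a variant builds its contrast: numerator/denominator rules and flags."""

    name: str
    numerator: str  # "A" or "A-B"
    denominator: str  # "identity", "B", or "A+B"
    symmetric: bool
    orthogonal: bool
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.name == "v1":
            if self.alpha is None:
                raise ValueError("variant v1 (cPCA) requires alpha")
            if self.alpha < 0:
                raise ValueError("alpha must be >= 0")
        elif self.alpha is not None:
            raise ValueError(f"alpha is only meaningful for v1, not {self.name}")


_VARIANT_TABLE: dict[str, dict] = {
    "v1": dict(numerator="A-B", denominator="identity", symmetric=False, orthogonal=False),
    "v2": dict(numerator="A", denominator="B", symmetric=False, orthogonal=False),
    "v2.1": dict(numerator="A", denominator="B", symmetric=False, orthogonal=True),
    "v3": dict(numerator="A-B", denominator="B", symmetric=False, orthogonal=False),
    "v3.1": dict(numerator="A-B", denominator="B", symmetric=False, orthogonal=True),
    "v4": dict(numerator="A-B", denominator="A+B", symmetric=True, orthogonal=False),
    "v4.1": dict(numerator="A-B", denominator="A+B", symmetric=True, orthogonal=True),
}


def variant_spec(name: str, alpha: float | None = None) -> VariantSpec:
    """Look up a variant by name (``v1`` ... ``v4.1``); ``alpha`` only for v1."""
    try:
        fields = _VARIANT_TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; choose from {sorted(_VARIANT_TABLE)}"
        ) from None
    return VariantSpec(name=name, alpha=alpha, **fields)


# --------------------------------------------------------------------------
# numerical building blocks
# --------------------------------------------------------------------------

def build_shared_basis(pair: ConditionPair, rank_tol: float = 1e-10):
    """Orthonormal basis of the joint principal subspace of both conditions.

    The basis holds the right singular vectors of the row-wise concatenation
    ``[A; B]`` whose singular values exceed ``rank_tol`` times the largest one,
    excising directions that are zero up to numerical precision.

    Returns
    -------
    basis_j : ndarray of shape (p, k)
    rank_k : int
    """
    stacked = np.vstack([pair.data_a, pair.data_b])
    _, svals, vt = np.linalg.svd(stacked, full_matrices=False)
    if svals.size == 0 or svals[0] == 0:
        raise ValueError("all-zero data: no shared principal subspace exists")
    k = int(np.sum(svals > rank_tol * svals[0]))
    if k == 0:
        raise ValueError("all singular values fall below the rank tolerance")
    return vt[:k].T.copy(), k


def symmetric_sqrt(s: np.ndarray) -> np.ndarray:
    """Symmetric positive-definite square root M of an SPD matrix (M @ M = s)."""
    s = np.asarray(s, dtype=float)
    evals, evecs = np.linalg.eigh(0.5 * (s + s.T))
    if evals[0] <= 0:
        raise np.linalg.LinAlgError(
            f"matrix is not positive definite (smallest eigenvalue {evals[0]:.3g})"
        )
    return (evecs * np.sqrt(evals)) @ evecs.T


@dataclass
class NormalizedProblem:
    """The denominator-whitened eigenproblem of a ratio variant.

    ``basis_j`` is rotated so that ``J' (denominator) J`` is diagonal; the
    square root M is therefore diagonal too, and ``reduced_matrix`` is the
    symmetric matrix ``M^-1 J' (numerator) J M^-1`` whose eigendecomposition
    solves the variant.
    """

    basis_j: np.ndarray
    sqrt_m: np.ndarray
    reduced_matrix: np.ndarray
    rank_k: int

    @property
    def m_inv_diag(self) -> np.ndarray:
        return 1.0 / np.diag(self.sqrt_m)


def _contrast_matrices(cov_a, cov_b, variant: VariantSpec):
    num = cov_a if variant.numerator == "A" else cov_a - cov_b
    if variant.denominator == "B":
        den = cov_b
    elif variant.denominator == "A+B":
        den = cov_a + cov_b
    else:
        raise ValueError(f"variant {variant.name} has no ratio denominator")
    return num, den


def build_normalized_problem(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    variant: VariantSpec,
    basis_j: np.ndarray,
    rank_tol: float = 1e-10,
) -> NormalizedProblem:
    """Reduce a ratio variant onto the shared basis and whiten its denominator.

    Directions of ``basis_j`` along which the denominator covariance has
    (near-)zero eigenvalue are removed before forming M — the denominator for
    v2/v3 is ``C_B`` alone, which can be singular inside the joint subspace.
    """
    num, den = _contrast_matrices(cov_a, cov_b, variant)
    d = basis_j.T @ den @ basis_j
    evals, evecs = np.linalg.eigh(0.5 * (d + d.T))
    if evals.size == 0 or evals[-1] <= 0:
        raise np.linalg.LinAlgError(
            f"denominator covariance of variant {variant.name} is not positive "
            "definite on the shared basis"
        )
    keep = evals > rank_tol * evals[-1]
    if not keep.any():
        raise np.linalg.LinAlgError(
            f"variant {variant.name}: denominator is numerically singular on "
            "the shared basis"
        )
    if not keep.all():
        warnings.warn(
            f"variant {variant.name}: trimmed {int((~keep).sum())} denominator "
            "direction(s) with near-zero variance",
            RuntimeWarning,
            stacklevel=2,
        )
    j = basis_j @ evecs[:, keep]
    d_kept = evals[keep]
    sqrt_m = np.diag(np.sqrt(d_kept))
    m_inv = 1.0 / np.sqrt(d_kept)
    reduced = (j.T @ num @ j) * np.outer(m_inv, m_inv)
    reduced = 0.5 * (reduced + reduced.T)
    return NormalizedProblem(
        basis_j=j, sqrt_m=sqrt_m, reduced_matrix=reduced, rank_k=j.shape[1]
    )


def _finalize_loadings(x: np.ndarray) -> np.ndarray:
    """Unit-norm columns with a deterministic sign (largest |entry| positive)."""
    x = np.array(x, dtype=float)
    norms = np.linalg.norm(x, axis=0)
    nonzero = norms > 0
    x[:, nonzero] /= norms[nonzero]
    peak = np.abs(x).argmax(axis=0)
    signs = np.sign(x[peak, np.arange(x.shape[1])])
    signs[signs == 0] = 1.0
    return x * signs


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class GcPCA(TransformerMixin, BaseEstimator):
    """Generalized contrastive PCA of two conditions.

    Parameters
    ----------
    variant : str, default="v4"
        One of ``v1`` (cPCA, needs ``alpha``), ``v2``, ``v3``, ``v4`` or the
        feature-space-orthogonal ``v2.1``/``v3.1``/``v4.1``.
    alpha : float, optional
        cPCA trade-off parameter; required for (and exclusive to) ``v1``.
    n_components : int, optional
        Number of components to keep. Defaults to the full shared rank; note
        that for symmetric variants the B-enriched components sit at the
        *bottom* of the spectrum, so keep all components when both sides are
        of interest.
    center : bool, default=True
        Center each condition's features before estimating covariances.
    rank_tol : float, default=1e-10
        Relative tolerance for discarding numerically-zero singular values
        (shared basis) and denominator eigenvalues.

    Attributes
    ----------
    loadings_ : ndarray of shape (p, k)
        Feature-space components (gcPCs) as unit-norm columns, eigenvalue-
        descending.
    eigenvalues_ : ndarray of shape (k,)
        The contrast objective values of each component (e.g. the
        (A-B)/(A+B) index for ``v4``).
    normalized_components_y_ : ndarray or None
        Orthonormal components in the denominator-whitened space (ratio
        variants only).
    basis_j_ : ndarray of shape (p, k)
        Shared principal-subspace basis actually used.
    rank_k_ : int
        Retained rank of the shared subspace.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> A = rng.normal(size=(60, 5)) * [3.0, 1, 1, 1, 1]
    >>> B = rng.normal(size=(60, 5))
    >>> model = GcPCA(variant="v4").fit(A, B)
    >>> scores_a = model.transform(A)
    """

    def __init__(
        self,
        variant: str = "v4",
        *,
        alpha: float | None = None,
        n_components: int | None = None,
        center: bool = True,
        rank_tol: float = 1e-10,
    ):
        self.variant = variant
        self.alpha = alpha
        self.n_components = n_components
        self.center = center
        self.rank_tol = rank_tol

    # -- fitting ----------------------------------------------------------

    def _prepare(self, X, Y):
        if isinstance(X, ConditionPair):
            if Y is not None:
                raise ValueError("pass either a ConditionPair or two matrices")
            pair = X
        else:
            if Y is None:
                raise ValueError("fit requires both conditions: fit(A, B)")
            pair = ConditionPair(X, Y)
        a = center_features(pair.data_a) if self.center else pair.data_a
        b = center_features(pair.data_b) if self.center else pair.data_b
        return pair, a, b

    def fit(self, X, Y=None):
        """Fit the contrast to condition A (``X``) versus condition B (``Y``)."""
        pair, a, b = self._prepare(X, Y)
        spec = variant_spec(self.variant, self.alpha)
        self.variant_ = spec
        self.n_features_in_ = pair.n_features
        self.feature_names_in_ = pair.feature_names

        cov_a = compute_covariance(a).values
        cov_b = compute_covariance(b).values

        if spec.name == "v1":
            self._fit_cpca(cov_a, cov_b, spec)
        elif spec.orthogonal:
            from .orthogonal import _fit_deflating

            _fit_deflating(self, ConditionPair(a, b), cov_a, cov_b, spec)
        else:
            self._fit_ratio(ConditionPair(a, b), cov_a, cov_b, spec)

        if self.n_components is not None:
            if not 1 <= self.n_components <= self.loadings_.shape[1]:
                raise ValueError(
                    f"n_components must be in [1, {self.loadings_.shape[1]}]"
                )
            self.loadings_ = self.loadings_[:, : self.n_components]
            self.eigenvalues_ = self.eigenvalues_[: self.n_components]
            if self.normalized_components_y_ is not None:
                self.normalized_components_y_ = self.normalized_components_y_[
                    :, : self.n_components
                ]
        self.n_components_ = self.loadings_.shape[1]
        return self

    def _fit_cpca(self, cov_a, cov_b, spec: VariantSpec) -> None:
        contrast = cov_a - spec.alpha * cov_b
        evals, evecs = np.linalg.eigh(0.5 * (contrast + contrast.T))
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = evals[order]
        self.loadings_ = _finalize_loadings(evecs[:, order])
        self.normalized_components_y_ = None
        self.basis_j_ = np.eye(cov_a.shape[0])
        self.sqrt_m_ = np.eye(cov_a.shape[0])
        self.rank_k_ = cov_a.shape[0]

    def _fit_ratio(self, pair, cov_a, cov_b, spec: VariantSpec) -> None:
        basis, _ = build_shared_basis(pair, self.rank_tol)
        problem = build_normalized_problem(
            cov_a, cov_b, spec, basis, self.rank_tol
        )
        evals, y = np.linalg.eigh(problem.reduced_matrix)
        order = np.argsort(evals)[::-1]
        evals, y = evals[order], y[:, order]
        loadings = problem.basis_j @ (problem.m_inv_diag[:, None] * y)
        self.eigenvalues_ = evals
        self.loadings_ = _finalize_loadings(loadings)
        self.normalized_components_y_ = y
        self.basis_j_ = problem.basis_j
        self.sqrt_m_ = problem.sqrt_m
        self.rank_k_ = problem.rank_k

    # -- projection -------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Project data onto the fitted components: ``scores = X @ loadings``."""
        check_is_fitted(self, "loadings_")
        arr = _as_matrix(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"data has {arr.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        return arr @ self.loadings_

    def fit_transform(self, X, Y=None):
        """Fit to (A, B) and return the scores of condition A."""
        self.fit(X, Y)
        data = X.data_a if isinstance(X, ConditionPair) else X
        return self.transform(data)


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def fit_gcpca(
    pair: ConditionPair,
    variant: str = "v4",
    *,
    alpha: float | None = None,
    n_components: int | None = None,
    center: bool = True,
    rank_tol: float = 1e-10,
) -> GcPCA:
    """Fit any gcPCA variant to a condition pair; returns the fitted estimator."""
    model = GcPCA(
        variant=variant,
        alpha=alpha,
        n_components=n_components,
        center=center,
        rank_tol=rank_tol,
    )
    return model.fit(pair)


def fit_cpca(
    pair: ConditionPair,
    alpha: float,
    *,
    n_components: int | None = None,
    center: bool = True,
) -> GcPCA:
    """Fit cPCA (eigendecomposition of ``C_A - alpha C_B``); ``alpha=0`` is PCA of A."""
    return fit_gcpca(
        pair, "v1", alpha=alpha, n_components=n_components, center=center
    )


def transform(model: GcPCA, data) -> np.ndarray:
    """Project ``data`` onto a fitted model's components."""
    return model.transform(data)


# --------------------------------------------------------------------------
# automatic alpha selection for cPCA
# --------------------------------------------------------------------------

def subspace_affinity(q1: np.ndarray, q2: np.ndarray) -> float:
    """Product of cosines of the principal angles between two subspaces.

    ``q1`` and ``q2`` are matrices with orthonormal columns; the affinity is 1
    for identical subspaces and 0 when they share an orthogonal direction.
    """
    svals = np.linalg.svd(q1.T @ q2, compute_uv=False)
    return float(np.prod(np.clip(svals, 0.0, 1.0)))


def select_alphas(
    pair: ConditionPair,
    n_alphas: int = 40,
    alpha_min: float = 0.01,
    alpha_max: float = 1000.0,
    top_k: int = 2,
    n_clusters: int = 4,
    *,
    center: bool = True,
    random_state: int = 0,
) -> np.ndarray:
    """Candidate cPCA ``alpha`` values via clustering of cPC subspaces.

    cPCA is solved on a log-spaced alpha grid; each solution's top-``top_k``
    subspace is compared with every other via :func:`subspace_affinity`, the
    affinity matrix is spectrally clustered, and the medoid alpha of each
    cluster is returned (ascending). If clustering degenerates to fewer
    distinct solutions than clusters, fewer candidates are returned with a
    warning.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n_alphas:
        warnings.warn(
            "n_clusters exceeds the alpha grid size; clamping", RuntimeWarning
        )
        n_clusters = n_alphas
    alphas = np.logspace(np.log10(alpha_min), np.log10(alpha_max), n_alphas)
    a = center_features(pair.data_a) if center else pair.data_a
    b = center_features(pair.data_b) if center else pair.data_b
    cov_a = compute_covariance(a).values
    cov_b = compute_covariance(b).values

    bases = []
    for alpha in alphas:
        contrast = cov_a - alpha * cov_b
        _, evecs = np.linalg.eigh(0.5 * (contrast + contrast.T))
        bases.append(evecs[:, ::-1][:, :top_k])

    n = len(alphas)
    affinity = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            affinity[i, j] = affinity[j, i] = subspace_affinity(bases[i], bases[j])

    if n_clusters == 1:
        labels = np.zeros(n, dtype=int)
    else:
        clusterer = SpectralClustering(
            n_clusters=n_clusters,
            affinity="precomputed",
            random_state=random_state,
            assign_labels="discretize",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fully-connected graph warning
            labels = clusterer.fit_predict(affinity)

    medoids: list[float] = []
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        within = affinity[np.ix_(members, members)].sum(axis=1)
        medoids.append(float(alphas[members[np.argmax(within)]]))
    medoids = sorted(set(medoids))
    if len(medoids) < n_clusters:
        warnings.warn(
            f"only {len(medoids)} distinct subspace clusters found "
            f"(requested {n_clusters})",
            RuntimeWarning,
        )
    return np.asarray(medoids)
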