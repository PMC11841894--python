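"""Feature-wise transforms and covariance estimation used before a contrastive fit.

All operations work on ``(n_samples, n_features)`` arrays and act column-wise.
The fit entry points center data by default; :func:`compute_covariance` itself
does *not* center, so callers working with raw matrices should center (or
z-score) first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConditionPair",
    "CovarianceMatrix",
    "compute_covariance",
    "zscore_features",
    "l2_normalize_features",
    "center_features",
    "drop_near_zero_variance",
    "standardize_pair",
]


def _as_matrix(data, name: str = "data") -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN values; clean or impute before fitting")
    return arr


@dataclass
class ConditionPair:
    """Two data matrices sharing an identical feature axis.

    Parameters
    ----------
    data_a, data_b : ndarray of shape (n_a, p) and (n_b, p)
        Samples-by-features matrices for conditions A and B. Feature columns
        must be aligned (same features, same order).
    feature_names : list of str, optional
        Names for the ``p`` shared features.
    """

    data_a: np.ndarray
    data_b: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data_a = _as_matrix(self.data_a, "data_a")
        self.data_b = _as_matrix(self.data_b, "data_b")
        if self.data_a.shape[1] != self.data_b.shape[1]:
            raise ValueError(
                "conditions must share the feature axis: "
                f"data_a has {self.data_a.shape[1]} features, "
                f"data_b has {self.data_b.shape[1]}"
            )
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.n_features:
                raise ValueError(
                    f"feature_names has length {len(self.feature_names)}, "
                    f"expected {self.n_features}"
                )

    @property
    def n_features(self) -> int:
        return self.data_a.shape[1]


@dataclass
class CovarianceMatrix:
    """A symmetric positive semi-definite covariance estimate ``D^T D / (n - 1)``."""

    values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("covariance must be square")
        sym_err = np.abs(self.values - self.values.T).max(initial=0.0)
        scale = max(np.abs(self.values).max(initial=0.0), 1.0)
        if sym_err > 1e-8 * scale:
            raise ValueError(f"covariance not symmetric (max asymmetry {sym_err:.3g})")
        if self.n_samples < 2:
            raise ValueError("covariance requires n_samples >= 2")


def compute_covariance(data) -> CovarianceMatrix:
    """Estimate the covariance ``D^T D / (n - 1)`` of a (pre-centered) matrix.

    Centering is deliberately left to the caller so that the same primitive
    serves raw second-moment and centered-covariance uses.
    """
    arr = _as_matrix(data)
    n = arr.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples to estimate covariance, got {n}")
    cov = arr.T @ arr / (n - 1)
    cov = 0.5 * (cov + cov.T)  # kill round-off asymmetry
    return CovarianceMatrix(values=cov, n_samples=n)


def center_features(data) -> np.ndarray:
    """Subtract each column's mean."""
    arr = _as_matrix(data)
    return arr - arr.mean(axis=0, keepdims=True)


def zscore_features(data) -> np.ndarray:
    """Center each column and scale it to unit sample standard deviation.

    Raises if any column has zero variance (drop such columns first, e.g. with
    :func:`drop_near_zero_variance`).
    """
    arr = _as_matrix(data)
    centered = arr - arr.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance feature column(s) {bad.tolist()} cannot be z-scored"
        )
    return centered / sd


def l2_normalize_features(data) -> np.ndarray:
    """Scale each column to unit Euclidean norm."""
    arr = _as_matrix(data)
    norms = np.linalg.norm(arr, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"all-zero feature column(s) {bad.tolist()} cannot be normalized")
    return arr / norms


def standardize_pair(
    pair: ConditionPair, *, zscore: bool = True, l2norm: bool = True
) -> ConditionPair:
    """Z-score and/or l2-normalize features jointly across both conditions.

    The statistics are computed on the row-wise concatenation of A and B and
    the same transform is applied to both, so the *relative* variance of a
    feature between conditions is preserved while its joint scale is
    equalized. This is the standard preprocessing for contrastive fits: it
    keeps high-variance features from dominating the loadings.
    """
    stacked = np.vstack([pair.data_a, pair.data_b])
    mean = stacked.mean(axis=0, keepdims=True)
    a = pair.data_a - mean
    b = pair.data_b - mean
    stacked = stacked - mean
    if zscore:
        sd = stacked.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance feature column(s) {bad.tolist()} cannot be z-scored"
            )
        a, b, stacked = a / sd, b / sd, stacked / sd
    if l2norm:
        norms = np.linalg.norm(stacked, axis=0)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(
                f"all-zero feature column(s) {bad.tolist()} cannot be normalized"
            )
        a, b = a / norms, b / norms
    return ConditionPair(a, b, feature_names=pair.feature_names)


def drop_near_zero_variance(
    pair: ConditionPair, tol: float | None = None
) -> tuple[ConditionPair, list[int]]:
    """Remove features with (near-)zero variance across both conditions.

    Variance is measured on the row-wise concatenation of the two conditions;
    features with variance ``<= tol * max_variance`` are removed from both
    matrices. ``tol`` defaults to ``eps * p``, mirroring standard relative
    rank tolerances.

    Returns the filtered pair and the list of removed (0-based) indices.
    """
    if tol is not None and tol < 0:
        raise ValueError("tol must be >= 0")
    stacked = np.vstack([pair.data_a, pair.data_b])
    variances = stacked.var(axis=0)
    max_var = variances.max(initial=0.0)
    if tol is None:
        tol = np.finfo(float).eps * pair.n_features
    keep = variances > tol * max_var
    if not keep.any():
        raise ValueError("all features fall below the variance tolerance")
    dropped = np.flatnonzero(~keep).tolist()
    if not dropped:
        return pair, []
    names = (
        [pair.feature_names[i] for i in np.flatnonzero(keep)]
        if pair.feature_names is not None
        else None
    )
    filtered = ConditionPair(
        data_a=pair.data_a[:, keep],
        data_b=pair.data_b[:, keep],
        feature_names=names,
    )
    return filtered, dropped
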