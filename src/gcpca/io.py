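"""Reading condition matrices and writing fit artifacts.

Dense matrices travel as CSV/TSV (optional header row of feature names);
sparse count matrices as Matrix Market (``.mtx``). Fits serialize to a
directory: ``loadings.csv`` (features x components), ``eigenvalues.csv`` and
``metadata.json``, plus a sparsity report for sparse fits.
"""

from __future__ import annotations

import json
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import io as sio

from .preprocessing import ConditionPair

__all__ = [
    "load_matrix",
    "load_condition_pair",
    "save_matrix",
    "save_fit",
    "load_fit",
]


def _has_header(path: Path, sep: str) -> bool:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first:
        return False
    for token in first.split(sep):
        try:
            float(token)
        except ValueError:
            return True
    return False


def load_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Load a samples-by-features matrix from CSV/TSV/MTX.

    Returns the dense array and the feature names (None when the file has no
    header; MTX files never carry names).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return np.asarray(sio.mmread(path).todense(), dtype=float), None
    sep = "\t" if suffix in {".tsv", ".tab"} else ","
    header = 0 if _has_header(path, sep) else None
    frame = pd.read_csv(path, sep=sep, header=header)
    names = [str(c) for c in frame.columns] if header == 0 else None
    return frame.to_numpy(dtype=float), names


def load_condition_pair(path_a, path_b) -> ConditionPair:
    """Load two matrices sharing a feature axis into a :class:`ConditionPair`."""
    data_a, names_a = load_matrix(path_a)
    data_b, names_b = load_matrix(path_b)
    if names_a is not None and names_b is not None and names_a != names_b:
        raise ValueError("condition files have mismatched feature names")
    return ConditionPair(data_a, data_b, feature_names=names_a or names_b)


def save_matrix(data: np.ndarray, path, feature_names=None) -> None:
    """Write a matrix as CSV/TSV (header if names given) or MTX (sparse)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        from scipy import sparse

        sio.mmwrite(path, sparse.coo_matrix(np.asarray(data)))
        return
    sep = "\t" if suffix in {".tsv", ".tab"} else ","
    frame = pd.DataFrame(np.asarray(data), columns=feature_names)
    frame.to_csv(path, sep=sep, index=False, header=feature_names is not None)


def _component_names(n: int) -> list[str]:
    return [f"gcPC{i + 1}" for i in range(n)]


def save_fit(model, out_dir) -> Path:
    """Serialize a fitted (sparse) gcPCA model to a directory.

    Writes ``loadings.csv`` (rows = features, columns = components),
    ``eigenvalues.csv`` and ``metadata.json``; sparse fits additionally get
    ``sparsity_report.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p, k = model.loadings_.shape
    features = model.feature_names_in_ or [f"feature_{i + 1}" for i in range(p)]
    comps = _component_names(k)

    pd.DataFrame(model.loadings_, index=features, columns=comps).to_csv(
        out_dir / "loadings.csv", index_label="feature"
    )
    pd.DataFrame(
        {"component": comps, "eigenvalue": model.eigenvalues_}
    ).to_csv(out_dir / "eigenvalues.csv", index=False)

    spec = model.variant_
    meta = {
        "variant": spec.name,
        "alpha": spec.alpha,
        "symmetric": spec.symmetric,
        "orthogonal_constraint": spec.orthogonal,
        "rank_k": int(model.rank_k_),
        "n_components": int(model.n_components_),
        "n_features": int(p),
        "center": bool(model.center),
    }
    if hasattr(model, "n_iterations_"):
        meta["n_iterations"] = int(model.n_iterations_)
    if hasattr(model, "nonzero_counts_"):  # sparse fit
        meta.update(
            {
                "sparse": True,
                "lasso_lambda": model.lasso_lambda,
                "ridge_kappa": model.ridge_kappa,
                "n_iterations": int(model.n_iter_),
            }
        )
        report = {
            "lasso_lambda": model.lasso_lambda,
            "ridge_kappa": model.ridge_kappa,
            "iterations": int(model.n_iter_),
            "nonzero_counts": model.nonzero_counts_.astype(int).tolist(),
            "fully_sparsified_components": model.fully_sparsified_,
        }
        with open(out_dir / "sparsity_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out_dir


def load_fit(fit_dir) -> SimpleNamespace:
    """Load a serialized fit back into a lightweight namespace.

    The result carries ``loadings_``, ``eigenvalues_``, ``feature_names_in_``
    and ``metadata`` — enough for projection and feature ranking.
    """
    fit_dir = Path(fit_dir)
    loadings = pd.read_csv(fit_dir / "loadings.csv", index_col="feature")
    eigenvalues = pd.read_csv(fit_dir / "eigenvalues.csv")["eigenvalue"].to_numpy()
    with open(fit_dir / "metadata.json") as fh:
        metadata = json.load(fh)
    return SimpleNamespace(
        loadings_=loadings.to_numpy(),
        eigenvalues_=eigenvalues,
        feature_names_in_=[str(i) for i in loadings.index],
        n_features_in_=loadings.shape[0],
        metadata=metadata,
    )
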