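"""Class balancing and PCA on the fused feature matrix.

The PCA here is the classical eigendecomposition route: columns are
standardized (mean 0, sample sd 1), the covariance C = X^T X / (n - 1) is
formed from the standardized matrix, and its symmetric eigendecomposition
C v_i = lambda_i v_i provides the projection Z = X W_k onto the top-k
eigenvectors. When the feature dimension exceeds the sample count, the
n x n Gram matrix is decomposed instead and the eigenvectors are mapped
back — mathematically the same model, cheaper to compute.

Standardizing before the decomposition is a deliberate choice: the
handcrafted and deep blocks live on incommensurate scales, and an
unstandardized covariance would be dominated by whichever block happens
to have the largest numeric range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import rng_from
from .deepfusion import FusedMatrix
from .synthgen import DatasetManifest

__all__ = ["PCAModel", "balance_classes", "fit_pca", "transform_pca", "save_pca", "load_pca"]

_EIG_CLIP = -1e-10


@dataclass
class PCAModel:
    """Fitted PCA: standardization stats, spectrum and projection basis."""

    mean: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray  # all d, descending, >= 0
    components: np.ndarray  # d x k, orthonormal columns
    k: int
    retained_fraction: float
    standardized: bool = True

    @property
    def d(self) -> int:
        return len(self.mean)


def balance_classes(
    manifest: DatasetManifest, cap: int = 150, seed: int = 0
) -> DatasetManifest:
    """Randomly retain at most ``cap`` records per class, without replacement.

    Classes smaller than the cap are kept whole (with a warning). The
    retained records keep their original manifest order; sampling is
    deterministic in ``seed``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    kept_indices: list[int] = []
    for ci, label in enumerate(manifest.class_set):
        idx = [i for i, (_, lab) in enumerate(manifest.records) if lab == label]
        if len(idx) <= cap:
            if len(idx) < cap:
                warnings.warn(
                    f"class {label!r} has only {len(idx)} records (< cap {cap}); kept whole",
                    stacklevel=2,
                )
            kept_indices.extend(idx)
        else:
            rng = rng_from(seed, "balance", label)
            chosen = rng.choice(len(idx), size=cap, replace=False)
            kept_indices.extend(idx[j] for j in chosen)
    kept_indices.sort()
    records = tuple(manifest.records[i] for i in kept_indices)
    return DatasetManifest(records=records, class_set=manifest.class_set)


def _sign_fix(components: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(
    X: FusedMatrix | np.ndarray,
    k: int | None = None,
    variance_threshold: float = 0.95,
    standardize: bool = True,
) -> PCAModel:
    """Fit the PCA model by symmetric eigendecomposition.

    ``k`` fixes the number of retained components; otherwise the smallest
    k whose cumulative variance fraction reaches ``variance_threshold``
    is used, capped at min(d, n-1). With ``standardize=False`` the data
    are only centered (useful for hand-checkable examples).
    """
    A = X.values if isinstance(X, FusedMatrix) else np.asarray(X, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = A.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(A)):
        raise ValueError("X must be finite")

    mean = A.mean(axis=0)
    if standardize:
        scale = A.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(d)
    Xs = (A - mean) / scale

    if d <= n:
        C = Xs.T @ Xs / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(C)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    else:
        # Gram trick: eigenvectors of X X^T / (n-1) map back through X^T
        G = Xs @ Xs.T / (n - 1)
        gvals, gvecs = np.linalg.eigh(G)
        order = np.argsort(gvals)[::-1]
        gvals, gvecs = gvals[order], gvecs[:, order]
        eigvals = np.zeros(d)
        eigvals[: len(gvals)] = gvals
        eigvecs = np.zeros((d, d))
        pos = gvals > 1e-12
        V = Xs.T @ gvecs[:, pos] / np.sqrt(gvals[pos] * (n - 1))
        eigvecs[:, : V.shape[1]] = V

    if eigvals.min() < _EIG_CLIP * max(1.0, abs(eigvals.max())):
        warnings.warn("covariance produced a materially negative eigenvalue", stacklevel=2)
    eigvals = np.clip(eigvals, 0.0, None)

    total = eigvals.sum()
    k_max = min(d, n - 1)
    if k is not None:
        if not (1 <= k <= d):
            raise ValueError(f"k must be in [1, {d}]")
        k_use = k
    else:
        cum = np.cumsum(eigvals[:k_max]) / total
        k_use = int(np.searchsorted(cum, variance_threshold) + 1)
        k_use = min(k_use, k_max)

    components = _sign_fix(eigvecs[:, :k_use])
    retained = float(eigvals[:k_use].sum() / total)
    return PCAModel(
        mean=mean,
        scale=scale,
        eigenvalues=eigvals,
        components=components,
        k=k_use,
        retained_fraction=retained,
        standardized=standardize,
    )


def transform_pca(model: PCAModel, X: FusedMatrix | np.ndarray) -> np.ndarray:
    """Project: Z = ((X - mu) / scale) W_k."""
    A = X.values if isinstance(X, FusedMatrix) else np.asarray(X, dtype=np.float64)
    if A.ndim == 1:
        A = A[None, :]
    if A.shape[1] != model.d:
        raise ValueError(f"expected {model.d} columns, got {A.shape[1]}")
    return ((A - model.mean) / model.scale) @ model.components


def save_pca(model: PCAModel, path: str | Path) -> None:
    """Persist arrays as .npz with a JSON sidecar of the scalars."""
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        mean=model.mean,
        scale=model.scale,
        eigenvalues=model.eigenvalues,
        components=model.components,
    )
    sidecar = {
        "k": model.k,
        "retained_fraction": model.retained_fraction,
        "standardized": model.standardized,
        "d": model.d,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_pca(path: str | Path) -> PCAModel:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return PCAModel(
        mean=arrays["mean"],
        scale=arrays["scale"],
        eigenvalues=arrays["eigenvalues"],
        components=arrays["components"],
        k=int(sidecar["k"]),
        retained_fraction=float(sidecar["retained_fraction"]),
        standardized=bool(sidecar["standardized"]),
    )
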