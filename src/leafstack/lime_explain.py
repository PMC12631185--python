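"""Tabular LIME: local surrogate explanations of a probabilistic classifier.

To explain a prediction f(x), the method samples perturbations z around x,
weights them by the locality kernel

    pi_x(z) = exp(-D(x, z)^2 / sigma^2),

with D the Euclidean distance in standardized feature units, and fits a
sparse linear surrogate g that minimizes the kernel-weighted squared loss
between g(z) and the black box's probability for the explained class.
Sparsity is realized as hard K-feature selection (largest kernel-weighted
covariance with the response) followed by weighted ridge regression.

Perturbations are Gaussian jitter with the training set's per-feature
standard deviation, which keeps samples in the local neighborhood of x —
appropriate for the continuous fused/PCA features this package produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import Ridge

from ._rng import rng_from

__all__ = [
    "LimeConfig",
    "FeatureStats",
    "Explanation",
    "kernel_weight",
    "perturb",
    "explain_instance",
]


@dataclass(frozen=True)
class LimeConfig:
    """Sampling and surrogate settings.

    ``kernel_width=None`` means the conventional 0.75 * sqrt(d).
    """

    n_samples: int = 1000
    kernel_width: float | None = None
    n_features: int = 10
    ridge_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ValueError("kernel_width must be > 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    def width_for(self, d: int) -> float:
        return self.kernel_width if self.kernel_width is not None else 0.75 * np.sqrt(d)


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature training mean and standard deviation."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_data(cls, X: np.ndarray) -> "FeatureStats":
        X = np.asarray(X, dtype=np.float64)
        return cls(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1))


@dataclass
class Explanation:
    """K-sparse weighted-linear surrogate around one instance."""

    instance_id: str
    target_class: str
    intercept: float
    features: list[tuple[str, float]]  # (name, surrogate weight), |.| descending
    fidelity: float  # kernel-weighted R^2 of the surrogate
    config: LimeConfig

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "target_class": self.target_class,
            "intercept": self.intercept,
            "features": [{"name": n, "weight": w} for n, w in self.features],
            "fidelity": self.fidelity,
            "config": {
                "n_samples": self.config.n_samples,
                "kernel_width": self.config.kernel_width,
                "n_features": self.config.n_features,
                "ridge_alpha": self.config.ridge_alpha,
                "seed": self.config.seed,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def kernel_weight(x: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """Locality weight exp(-D(x,z)^2 / sigma^2), Euclidean D."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if x.shape != z.shape:
        raise ValueError("x and z must share a dimension")
    d2 = float(np.sum((x - z) ** 2))
    return float(np.exp(-d2 / sigma**2))


def perturb(
    x: np.ndarray,
    stats: FeatureStats,
    n_samples: int,
    seed: int,
    sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian perturbations around x, plus their locality weights.

    Samples ``z_i ~ Normal(x, diag(sd^2))``; the first row is x itself
    (weight exactly 1). Distances for the kernel are measured in
    standardized units (z - x) / sd; ``sigma`` defaults to 0.75*sqrt(d).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    sd = np.asarray(stats.sd, dtype=np.float64)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError("stats.sd must be finite and > 0 for every feature")
    d = len(x)
    if sigma is None:
        sigma = 0.75 * np.sqrt(d)
    rng = rng_from(seed, "lime-perturb")
    Z = x + sd * rng.normal(size=(n_samples, d))
    Z[0] = x
    dist = np.linalg.norm((Z - x) / sd, axis=1)
    weights = np.exp(-(dist**2) / sigma**2)
    return Z, weights


def explain_instance(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    target_class: str | int,
    cfg: LimeConfig,
    stats: FeatureStats,
    classes: Sequence | None = None,
    feature_names: Sequence[str] | None = None,
    instance_id: str = "instance-0",
) -> Explanation:
    """Fit the local surrogate for ``f``'s ``target_class`` probability at x.

    ``f`` maps an n x d matrix to row-stochastic n x m probabilities. The
    target class is resolved against ``classes`` when given, else it must
    be a column index. Feature selection keeps the K features with the
    largest |kernel-weighted covariance| with the response; the surrogate
    is a weighted ridge regression on those features in standardized
    units, reported with its kernel-weighted R^2 (local fidelity).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    d = len(x)
    if feature_names is None:
        feature_names = [f"feature_{i:03d}" for i in range(d)]
    if len(feature_names) != d:
        raise ValueError("feature_names length must match x")

    if classes is not None:
        class_list = [str(c) for c in classes]
        if str(target_class) not in class_list:
            raise ValueError(f"target class {target_class!r} unknown to the classifier")
        target_idx = class_list.index(str(target_class))
        target_name = str(target_class)
    else:
        target_idx = int(target_class)
        target_name = str(target_class)

    sigma = cfg.width_for(d)
    Z, w = perturb(x, stats, cfg.n_samples, cfg.seed, sigma=sigma)
    probs = np.asarray(f(Z), dtype=np.float64)
    if probs.ndim != 2 or target_idx >= probs.shape[1]:
        raise ValueError("classifier output does not cover the target class")
    r = probs[:, target_idx]

    # standardized design for selection and fitting
    Zs = (Z - stats.mean) / stats.sd
    wsum = w.sum()
    zbar = (w[:, None] * Zs).sum(axis=0) / wsum
    rbar = float((w * r).sum() / wsum)
    cov = ((w[:, None] * (Zs - zbar) * (r - rbar)[:, None]).sum(axis=0)) / wsum
    K = min(cfg.n_features, d)
    selected = np.sort(np.argsort(-np.abs(cov))[:K])

    ridge = Ridge(alpha=cfg.ridge_alpha)
    ridge.fit(Zs[:, selected], r, sample_weight=w)
    pred = ridge.predict(Zs[:, selected])

    ss_res = float((w * (r - pred) ** 2).sum())
    ss_tot = float((w * (r - rbar) ** 2).sum())
    fidelity = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    order = np.argsort(-np.abs(ridge.coef_))
    features = [(str(feature_names[selected[j]]), float(ridge.coef_[j])) for j in order]
    return Explanation(
        instance_id=instance_id,
        target_class=target_name,
        intercept=float(ridge.intercept_),
        features=features,
        fidelity=float(fidelity),
        config=cfg,
    )
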