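"""Base learners and the ML-to-DNN stacked hybrid classifier.

The hybrid is a two-stage stack. Stage one fits one of five classical
base learners (random forest, XGBoost, gradient boosting, k-NN, or
multinomial logistic regression) on the PCA-reduced features and emits a
class-probability vector p = M(Z) per sample. Stage two feeds those
m-dimensional probability vectors into a dense neural network head
(512 -> 256 -> 128 -> m; ReLU, dropout 0.3 after each hidden layer,
softmax output) that produces the final prediction.

Training the head on the base learner's *in-sample* probabilities would
leak labels (a strong learner's training probabilities are near one-hot),
so by default the head is trained on stratified out-of-fold (OOF)
probabilities: each row is scored by a model that never saw it. A
``naive`` flag reproduces the literal in-sample protocol for comparison.

The DNN head is implemented directly in numpy (He-uniform init, Adam,
inverted dropout, cross-entropy, early stopping on validation loss) so
the whole fit is a deterministic function of its seeds.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

from ._rng import child_seed, rng_from

__all__ = [
    "BaseLearnerConfig",
    "ProbabilityMatrix",
    "SoftmaxRegression",
    "DNNModel",
    "DNNTrainConfig",
    "StackModel",
    "fit_base",
    "oof_probabilities",
    "build_dnn",
    "dnn_forward",
    "fit_dnn",
    "fit_hybrid",
    "predict",
    "save_stack",
    "load_stack",
    "BASE_LEARNERS",
]

BASE_LEARNERS = ("rf", "xgb", "gb", "knn", "lr")


# --------------------------------------------------------------------------
# configuration and containers


@dataclass(frozen=True)
class BaseLearnerConfig:
    """Choice of base learner plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in BASE_LEARNERS:
            raise ValueError(f"unknown learner {self.name!r}; choose from {BASE_LEARNERS}")


@dataclass
class ProbabilityMatrix:
    """Row-stochastic class probabilities with bookkeeping.

    ``fold_of_row[i]`` records which cross-validation fold produced row
    ``i`` (so leakage can be audited); -1 means the probabilities came
    from a single model, not a fold protocol.
    """

    probs: np.ndarray
    classes: np.ndarray
    fold_of_row: np.ndarray | None = None

    def __post_init__(self):
        p = self.probs
        if p.ndim != 2 or p.shape[1] != len(self.classes):
            raise ValueError("probs must be n x m with m = len(classes)")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities out of [0, 1]")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("probability rows must sum to 1")


def _row_normalize(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=np.float64), 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# multinomial logistic regression (softmax over w^T x + b)


class SoftmaxRegression:
    """Multinomial logistic regression trained by gradient descent.

    Minimizes mean cross-entropy of softmax(W x + b) plus an L2 penalty
    ``l2/(2n) * ||W||^2`` (biases unpenalized), using full-batch Adam.
    The binary case reduces to the classical sigmoid model
    P(y=1|x) = 1 / (1 + exp(-(w^T x + b))).
    """

    def __init__(self, l2: float = 1.0, max_iter: int = 1000, lr: float = 0.1,
                 tol: float = 1e-7, seed: int = 0):
        self.l2 = l2
        self.max_iter = max_iter
        self.lr = lr
        self.tol = tol
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftmaxRegression":
        X = np.asarray(X, dtype=np.float64)
        self.classes_ = np.unique(y)
        m = len(self.classes_)
        n, d = X.shape
        codes = np.searchsorted(self.classes_, y)
        Y = np.zeros((n, m))
        Y[np.arange(n), codes] = 1.0

        rng = rng_from(self.seed, "softmax-regression")
        W = rng.normal(0.0, 0.01, size=(d, m))
        b = np.zeros(m)
        mW = np.zeros_like(W); vW = np.zeros_like(W)
        mb = np.zeros_like(b); vb = np.zeros_like(b)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        prev_loss = np.inf
        for t in range(1, self.max_iter + 1):
            P = _softmax(X @ W + b)
            loss = -np.mean(np.sum(Y * np.log(P + 1e-300), axis=1))
            loss += self.l2 / (2 * n) * float(np.sum(W * W))
            G = (P - Y) / n
            gW = X.T @ G + self.l2 / n * W
            gb = G.sum(axis=0)
            mW = beta1 * mW + (1 - beta1) * gW; vW = beta2 * vW + (1 - beta2) * gW**2
            mb = beta1 * mb + (1 - beta1) * gb; vb = beta2 * vb + (1 - beta2) * gb**2
            c1, c2 = 1 - beta1**t, 1 - beta2**t
            W -= self.lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
            b -= self.lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
            if abs(prev_loss - loss) < self.tol:
                break
            prev_loss = loss
        self.W_, self.b_ = W, b
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(np.asarray(X, dtype=np.float64) @ self.W_ + self.b_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# --------------------------------------------------------------------------
# base learners


def _make_estimator(cfg: BaseLearnerConfig):
    hp = dict(cfg.hyperparameters)
    seed = cfg.seed
    if cfg.name == "rf":
        defaults = dict(n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1)
        return RandomForestClassifier(**{**defaults, **hp})
    if cfg.name == "xgb":
        defaults = dict(
            n_estimators=100, max_depth=6, learning_rate=0.3, reg_lambda=1.0,
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist",
        )
        return XGBClassifier(**{**defaults, **hp})
    if cfg.name == "gb":
        defaults = dict(n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed)
        return GradientBoostingClassifier(**{**defaults, **hp})
    if cfg.name == "knn":
        defaults = dict(n_neighbors=5, metric="euclidean")
        return KNeighborsClassifier(**{**defaults, **hp})
    if cfg.name == "lr":
        defaults = dict(l2=1.0, max_iter=1000, seed=seed)
        return SoftmaxRegression(**{**defaults, **hp})
    raise AssertionError(cfg.name)


@dataclass
class FittedBase:
    """A fitted base learner with a uniform label-encoded interface."""

    estimator: object
    classes: np.ndarray

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        return _row_normalize(self.estimator.predict_proba(np.asarray(Z, dtype=np.float64)))

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(Z), axis=1)]


def fit_base(cfg: BaseLearnerConfig, Z: np.ndarray, y: Sequence) -> FittedBase:
    """Fit one base learner on reduced features ``Z`` and labels ``y``.

    Labels may be strings or integers; internally they are encoded to
    0..m-1 in sorted order, which is also the probability column order.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(Z)):
        raise ValueError("features must be finite")
    y = np.asarray(y)
    classes = np.unique(y)
    m = len(classes)
    if m < 2:
        raise ValueError("need at least two classes")
    if len(Z) < m:
        raise ValueError("need at least one sample per class")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    codes = np.searchsorted(classes, y)
    est = _make_estimator(cfg)
    est.fit(Z, codes)
    return FittedBase(estimator=est, classes=classes)


def oof_probabilities(
    cfg: BaseLearnerConfig, Z: np.ndarray, y: Sequence, folds: int = 5, seed: int = 0
) -> ProbabilityMatrix:
    """Stratified out-of-fold class probabilities (Eq-level stacking input).

    Row i's probabilities come from the model trained on the folds that
    exclude i, so no row is scored by a model that saw its label.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= folds ({folds})"
        )
    codes = np.searchsorted(classes, y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, "oof"))
    probs = np.zeros((len(y), len(classes)))
    fold_of_row = np.full(len(y), -1, dtype=np.int64)
    for fi, (train_idx, test_idx) in enumerate(skf.split(Z, codes)):
        fold_cfg = BaseLearnerConfig(
            name=cfg.name, hyperparameters=cfg.hyperparameters,
            seed=child_seed(cfg.seed, "fold", fi),
        )
        base = fit_base(fold_cfg, Z[train_idx], y[train_idx])
        probs[test_idx] = base.predict_proba(Z[test_idx])
        fold_of_row[test_idx] = fi
    return ProbabilityMatrix(probs=_row_normalize(probs), classes=classes,
                             fold_of_row=fold_of_row)


# --------------------------------------------------------------------------
# the DNN head


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class DNNModel:
    """Fully-connected head: widths (512, 256, 128, m), dropout 0.3."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout: float = 0.3
    seed: int = 0

    @property
    def layer_widths(self) -> list[int]:
        return [W.shape[1] for W in self.weights]

    @property
    def n_classes(self) -> int:
        return self.weights[-1].shape[1]


def build_dnn(
    m: int, seed: int = 0, input_dim: int | None = None,
    hidden: tuple[int, ...] = (512, 256, 128), dropout: float = 0.3,
) -> DNNModel:
    """He-uniform initialized head on an ``input_dim`` (default m) input."""
    if m < 2:
        raise ValueError("need at least 2 classes")
    input_dim = m if input_dim is None else input_dim
    widths = [input_dim, *hidden, m]
    rng = rng_from(seed, "dnn-init")
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return DNNModel(weights=weights, biases=biases, dropout=dropout, seed=seed)


def dnn_forward(
    model: DNNModel, P: np.ndarray, mode: str = "infer",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward pass: affine -> ReLU (-> dropout in train mode) per hidden
    layer, softmax on the output layer. Inference is deterministic."""
    if mode not in ("train", "infer"):
        raise ValueError("mode must be 'train' or 'infer'")
    a = np.asarray(P, dtype=np.float64)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"input width {a.shape[1]} != model input {model.weights[0].shape[0]}"
        )
    if mode == "train" and rng is None:
        raise ValueError("train mode requires an rng for dropout masks")
    n_layers = len(model.weights)
    for li, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        if li < n_layers - 1:
            a = np.maximum(z, 0.0)
            if mode == "train" and model.dropout > 0:
                keep = 1.0 - model.dropout
                mask = rng.random(a.shape) < keep
                a = a * mask / keep  # inverted dropout
        else:
            a = _softmax(z)
    return a


@dataclass(frozen=True)
class DNNTrainConfig:
    """Optimization settings for the head (Adam on cross-entropy)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 30


def _cross_entropy(P: np.ndarray, codes: np.ndarray) -> float:
    return float(-np.mean(np.log(P[np.arange(len(codes)), codes] + 1e-300)))


def fit_dnn(
    model: DNNModel,
    P_train: np.ndarray,
    y_train_codes: np.ndarray,
    P_val: np.ndarray,
    y_val_codes: np.ndarray,
    cfg: DNNTrainConfig = DNNTrainConfig(),
    seed: int = 0,
) -> dict[str, list[float]]:
    """Train the head in place; returns the per-epoch history.

    Adam with inverted dropout; early stopping on validation loss with
    the configured patience, restoring the best weights.
    """
    Xtr = np.asarray(P_train, dtype=np.float64)
    Xva = np.asarray(P_val, dtype=np.float64)
    n = len(Xtr)
    rng = rng_from(seed, "dnn-train")
    params = model.weights + model.biases
    mom = [np.zeros_like(p) for p in params]
    vel = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: dict[str, list[float]] = {
        "epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    best_val = np.inf
    best_state = None
    stale = 0
    n_layers = len(model.weights)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], y_train_codes[idx]
            # forward with cached activations
            acts = [xb]
            masks = []
            a = xb
            for li in range(n_layers):
                z = a @ model.weights[li] + model.biases[li]
                if li < n_layers - 1:
                    a = np.maximum(z, 0.0)
                    if model.dropout > 0:
                        keep = 1.0 - model.dropout
                        mask = (rng.random(a.shape) < keep) / keep
                        a = a * mask
                        masks.append(mask)
                    else:
                        masks.append(np.ones_like(a))
                    acts.append(a)
                else:
                    probs = _softmax(z)
            # backward
            Y = np.zeros_like(probs)
            Y[np.arange(len(yb)), yb] = 1.0
            delta = (probs - Y) / len(yb)
            grads_W = [None] * n_layers
            grads_b = [None] * n_layers
            for li in range(n_layers - 1, -1, -1):
                grads_W[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ model.weights[li].T
                    delta *= masks[li - 1]
                    delta[acts[li] <= 0] = 0.0
            # Adam update
            step += 1
            grads = grads_W + grads_b
            c1, c2 = 1 - beta1**step, 1 - beta2**step
            for p, g, mo, ve in zip(params, grads, mom, vel):
                mo *= beta1; mo += (1 - beta1) * g
                ve *= beta2; ve += (1 - beta2) * g * g
                p -= cfg.learning_rate * (mo / c1) / (np.sqrt(ve / c2) + eps)

        tr_probs = dnn_forward(model, Xtr, mode="infer")
        va_probs = dnn_forward(model, Xva, mode="infer")
        tr_loss = _cross_entropy(tr_probs, y_train_codes)
        va_loss = _cross_entropy(va_probs, y_val_codes)
        history["epoch"].append(epoch)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(float(np.mean(tr_probs.argmax(1) == y_train_codes)))
        history["val_loss"].append(va_loss)
        history["val_acc"].append(float(np.mean(va_probs.argmax(1) == y_val_codes)))

        if va_loss < best_val - 1e-12:
            best_val = va_loss
            best_state = ([W.copy() for W in model.weights],
                          [b.copy() for b in model.biases])
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    if best_state is not None:
        ws, bs = best_state
        for i in range(n_layers):
            model.weights[i][:] = ws[i]
            model.biases[i][:] = bs[i]
    return history


# --------------------------------------------------------------------------
# the full hybrid


@dataclass
class StackModel:
    """One fitted ML+DNN hybrid."""

    base: FittedBase
    head: DNNModel
    classes: np.ndarray
    config: BaseLearnerConfig
    history: dict[str, list[float]]
    naive: bool = False

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def fit_hybrid(
    cfg: BaseLearnerConfig,
    Z_train: np.ndarray,
    y_train: Sequence,
    Z_val: np.ndarray,
    y_val: Sequence,
    train_cfg: DNNTrainConfig = DNNTrainConfig(),
    seed: int = 0,
    folds: int = 5,
    naive: bool = False,
) -> StackModel:
    """Fit the two-stage hybrid.

    Stage-one probabilities for head training are out-of-fold by default
    (``naive=True`` uses in-sample probabilities instead). The base
    learner is refit on all of ``Z_train``; its probabilities on
    ``Z_val`` drive early stopping of the head.
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    classes = np.unique(y_train)
    extra = set(np.unique(y_val)) - set(classes.tolist())
    if extra:
        raise ValueError(f"validation labels unseen in training: {sorted(extra)}")

    base = fit_base(cfg, Z_train, y_train)
    if naive:
        P_train = base.predict_proba(Z_train)
    else:
        P_train = oof_probabilities(cfg, Z_train, y_train, folds=folds, seed=seed).probs
    P_val = base.predict_proba(Z_val)

    codes_train = np.searchsorted(classes, y_train)
    codes_val = np.searchsorted(classes, y_val)
    head = build_dnn(len(classes), seed=child_seed(seed, "head"))
    history = fit_dnn(
        head, P_train, codes_train, P_val, codes_val, cfg=train_cfg,
        seed=child_seed(seed, "head-train"),
    )
    return StackModel(base=base, head=head, classes=classes, config=cfg,
                      history=history, naive=naive)


def predict(stack: StackModel, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities) for new reduced features.

    Base probabilities feed the head in inference mode; the label is the
    argmax (ties to the lowest class index) of the head's softmax.
    """
    P = stack.base.predict_proba(Z)
    probs = dnn_forward(stack.head, P, mode="infer")
    labels = stack.classes[np.argmax(probs, axis=1)]
    return labels, probs


def predict_proba_fn(stack: StackModel):
    """The hybrid as a plain ``f(Z) -> probs`` callable (for LIME)."""

    def f(Z: np.ndarray) -> np.ndarray:
        return predict(stack, Z)[1]

    return f


def save_stack(stack: StackModel, path: str | Path) -> None:
    """Persist the hybrid (pickle) with a JSON sidecar of its metadata."""
    path = Path(path)
    with open(path.with_suffix(".pkl"), "wb") as fh:
        pickle.dump(stack, fh)
    sidecar = {
        "learner": stack.config.name,
        "seed": stack.config.seed,
        "classes": [str(c) for c in stack.classes],
        "naive": stack.naive,
        "epochs_trained": len(stack.history["epoch"]),
        "layer_widths": stack.head.layer_widths,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_stack(path: str | Path) -> StackModel:
    with open(Path(path).with_suffix(".pkl"), "rb") as fh:
        stack = pickle.load(fh)
    if not isinstance(stack, StackModel):
        raise TypeError(f"{path} does not contain a StackModel")
    return stack
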