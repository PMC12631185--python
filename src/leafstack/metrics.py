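"""Evaluation: stratified splitting, classification report, confusion
matrix, and one-vs-rest ROC/AUC.

The scalar metrics wrap scikit-learn with the policies this package
commits to: undefined precision/recall become 0 with a warning (so
weighted averages stay defined), and per-class AUCs that are undefined
(a class with no positives or no negatives in the truth) are excluded
from the macro average with a warning rather than imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from ._rng import rng_from
from .synthgen import DatasetManifest

__all__ = [
    "MetricsReport",
    "stratified_split",
    "classification_report",
    "confusion_matrix",
    "roc_auc_ovr",
    "evaluate_predictions",
]


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics."""

    class_set: list[str]
    per_class: dict[str, dict[str, float]]  # precision/recall/f1/support
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    confusion: np.ndarray  # rows = true class
    per_class_auc: dict[str, float] = field(default_factory=dict)
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "class_set": self.class_set,
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "macro": self.macro,
            "weighted": self.weighted,
            "confusion": self.confusion.tolist(),
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n by largest remainder; ties to lowest index."""
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    remainders = [e - b for e, b in zip(exact, base)]
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def stratified_split(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Per-class largest-remainder split into train/val/test manifests.

    The three outputs are disjoint and exhaustive; allocation ties go to
    the earlier split. Deterministic in ``seed``.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    parts: list[list[int]] = [[], [], []]
    for label in manifest.class_set:
        idx = [i for i, (_, lab) in enumerate(manifest.records) if lab == label]
        if len(idx) < 3:
            raise ValueError(f"class {label!r} has {len(idx)} members; needs >= 3")
        rng = rng_from(seed, "split", label)
        perm = rng.permutation(len(idx))
        sizes = _largest_remainder(len(idx), fractions)
        start = 0
        for pi, size in enumerate(sizes):
            parts[pi].extend(idx[j] for j in perm[start : start + size])
            start += size
    out = []
    for part in parts:
        part.sort()
        records = tuple(manifest.records[i] for i in part)
        out.append(DatasetManifest(records=records, class_set=manifest.class_set))
    return tuple(out)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_set: Sequence
) -> np.ndarray:
    """m x m counts; entry (i, j) = true class i predicted as class j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty inputs")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    class_set = list(class_set)
    unknown = (set(y_true) | set(y_pred)) - set(class_set)
    if unknown:
        raise ValueError(f"labels outside class_set: {sorted(map(str, unknown))}")
    return _sk_confusion(y_true, y_pred, labels=class_set)


def classification_report(
    y_true: Sequence, y_pred: Sequence, class_set: Sequence
) -> MetricsReport:
    """Per-class precision/recall/F1 with accuracy, macro and weighted
    averages, plus the confusion matrix. Undefined ratios become 0."""
    cm = confusion_matrix(y_true, y_pred, class_set)
    class_set = list(class_set)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    never_predicted = [c for j, c in enumerate(class_set) if cm[:, j].sum() == 0]
    if never_predicted:
        warnings.warn(
            f"classes never predicted (precision set to 0): {never_predicted}",
            stacklevel=2,
        )
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=class_set, zero_division=0
    )
    per_class = {
        str(c): {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, c in enumerate(class_set)
    }
    accuracy = float(np.trace(cm) / cm.sum())
    weights = support / support.sum()
    macro = {
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
    }
    weighted = {
        "precision": float((prec * weights).sum()),
        "recall": float((rec * weights).sum()),
        "f1": float((f1 * weights).sum()),
    }
    return MetricsReport(
        class_set=[str(c) for c in class_set],
        per_class=per_class,
        accuracy=accuracy,
        macro=macro,
        weighted=weighted,
        confusion=cm,
    )


def roc_auc_ovr(
    y_true: Sequence, probabilities: np.ndarray, class_set: Sequence
) -> tuple[dict[str, float], float | None]:
    """One-vs-rest per-class AUC and their unweighted (macro) mean.

    AUC per class is the area under the empirical ROC with ties handled
    by rank (the normalized Mann-Whitney statistic). Classes absent from
    ``y_true``, or present without negatives, are excluded with a warning.
    """
    y_true = np.asarray(y_true)
    P = np.asarray(probabilities, dtype=np.float64)
    class_set = list(class_set)
    if P.shape != (len(y_true), len(class_set)):
        raise ValueError("probabilities must be n x m for the class set")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-6:
        raise ValueError("probability rows must sum to 1")
    per_class: dict[str, float] = {}
    skipped = []
    for j, c in enumerate(class_set):
        pos = y_true == c
        if pos.sum() == 0 or pos.sum() == len(y_true):
            skipped.append(str(c))
            continue
        per_class[str(c)] = float(roc_auc_score(pos.astype(int), P[:, j]))
    if skipped:
        warnings.warn(f"AUC undefined for classes {skipped}; excluded from macro",
                      stacklevel=2)
    macro = float(np.mean(list(per_class.values()))) if per_class else None
    return per_class, macro


def evaluate_predictions(
    y_true: Sequence, y_pred: Sequence, probabilities: np.ndarray, class_set: Sequence
) -> MetricsReport:
    """Full report: classification scores, confusion matrix and ROC/AUC."""
    report = classification_report(y_true, y_pred, class_set)
    per_class_auc, macro_auc = roc_auc_ovr(y_true, probabilities, class_set)
    report.per_class_auc = per_class_auc
    report.macro_auc = macro_auc
    return report
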