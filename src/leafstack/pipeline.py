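"""End-to-end pipeline driver.

Runs the whole sequence — simulate (or ingest) a manifest, balance
classes, stratified split, extract and fuse features, fit PCA on the
training split, fit one hybrid per requested learner, evaluate on the
test split, and explain a handful of test instances — writing every
artifact (manifests, feature CSVs, models, metric reports, histories,
explanations, a log) under one working directory. Every stage draws its
randomness from a named sub-stream of the master seed, so two runs with
the same configuration produce byte-identical JSON reports.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from ._rng import child_seed
from .deepfusion import BackboneSpec, FusedMatrix, deep_features, fuse_rows
from .handcrafted import HandcraftedParams, extract_handcrafted, resize_image
from .hybrid_stack import (
    BASE_LEARNERS,
    BaseLearnerConfig,
    DNNTrainConfig,
    fit_hybrid,
    predict,
    predict_proba_fn,
    save_stack,
)
from .lime_explain import FeatureStats, LimeConfig, explain_instance
from .metrics import evaluate_predictions, stratified_split
from .reduction import balance_classes, fit_pca, save_pca, transform_pca
from .synthgen import (
    DatasetManifest,
    default_class_specs,
    generate_dataset,
    read_manifest,
    write_manifest,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "extract_features_for_manifest"]

logger = logging.getLogger("leafstack")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Everything a full run needs; mirrors the YAML config file."""

    workdir: str = "leafstack-run"
    manifest: str | None = None  # None -> simulate
    n_classes: int = 15
    n_per_class: int = 20
    image_side: int = 256
    balance_cap: int = 150
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    feature_params: HandcraftedParams = field(default_factory=HandcraftedParams)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    pca_k: int | None = None
    pca_variance_threshold: float = 0.95
    learners: tuple[str, ...] = ("lr",)
    dnn_train: DNNTrainConfig = field(default_factory=DNNTrainConfig)
    lime: LimeConfig = field(default_factory=LimeConfig)
    n_explanations: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "feature_params" in kwargs:
            kwargs["feature_params"] = HandcraftedParams(**kwargs["feature_params"])
        if "backbone" in kwargs:
            kwargs["backbone"] = BackboneSpec(**kwargs["backbone"])
        if "dnn_train" in kwargs:
            kwargs["dnn_train"] = DNNTrainConfig(**kwargs["dnn_train"])
        if "lime" in kwargs:
            kwargs["lime"] = LimeConfig(**kwargs["lime"])
        if "split_fractions" in kwargs:
            kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
        if "learners" in kwargs:
            kwargs["learners"] = tuple(kwargs["learners"])
        return cls(**kwargs)

    def resolved_learners(self) -> tuple[str, ...]:
        if self.learners == ("all",) or "all" in self.learners:
            return BASE_LEARNERS
        return self.learners


def extract_features_for_manifest(
    manifest: DatasetManifest,
    image_root: str | Path,
    params: HandcraftedParams,
    backbone: BackboneSpec,
) -> tuple[FusedMatrix, np.ndarray]:
    """Load, resize, extract handcrafted + deep features, fuse.

    Returns the fused matrix (rows in manifest order) and the labels.
    """
    image_root = Path(image_root)
    hand, deep, labels = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unsegmentable images are flagged, not fatal
        for rel_path, label in manifest.records:
            img = np.asarray(Image.open(image_root / rel_path).convert("RGB"))
            resized = resize_image(img, params.side)
            hand.append(extract_handcrafted(resized, params))
            deep.append(deep_features(resized, backbone))
            labels.append(label)
    return fuse_rows(hand, deep), np.asarray(labels)


def _save_fused_csv(fused: FusedMatrix, labels: np.ndarray, path: Path) -> None:
    df = pd.DataFrame(fused.values, columns=fused.column_names)
    df["label"] = labels
    df.to_csv(path, index=False)


def _history_to_csv(history: dict[str, list[float]], path: Path) -> None:
    pd.DataFrame(history).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of artifact paths
    and headline metrics (also written to ``summary.json``)."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(workdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        # ---- simulate or ingest -------------------------------------------
        stage = "simulate"
        if config.manifest is None:
            specs = default_class_specs(config.n_classes)
            image_root = workdir / "images"
            manifest = generate_dataset(
                specs, config.n_per_class, image_root,
                seed=child_seed(config.seed, "simulate"), side=config.image_side,
            )
            logger.info("simulated %d images over %d classes", len(manifest),
                        len(manifest.class_set))
        else:
            manifest_path = Path(config.manifest)
            manifest = read_manifest(manifest_path)
            image_root = manifest_path.parent
            logger.info("ingested manifest with %d records", len(manifest))

        # ---- balance + split ----------------------------------------------
        stage = "balance"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            balanced = balance_classes(manifest, cap=config.balance_cap,
                                       seed=child_seed(config.seed, "balance"))
        write_manifest(balanced, workdir / "manifest_balanced.csv")

        stage = "split"
        train_m, val_m, test_m = stratified_split(
            balanced, config.split_fractions, seed=child_seed(config.seed, "split")
        )
        for name, m in (("train", train_m), ("val", val_m), ("test", test_m)):
            write_manifest(m, workdir / f"manifest_{name}.csv")
        logger.info("split sizes: train=%d val=%d test=%d",
                    len(train_m), len(val_m), len(test_m))

        # ---- features -----------------------------------------------------
        stage = "features"
        fused = {}
        labels = {}
        for name, m in (("train", train_m), ("val", val_m), ("test", test_m)):
            fused[name], labels[name] = extract_features_for_manifest(
                m, image_root, config.feature_params, config.backbone
            )
            _save_fused_csv(fused[name], labels[name], workdir / f"features_{name}.csv")
        logger.info("fused dimension: %d", fused["train"].values.shape[1])

        # ---- PCA ----------------------------------------------------------
        stage = "reduce"
        pca = fit_pca(fused["train"], k=config.pca_k,
                      variance_threshold=config.pca_variance_threshold)
        save_pca(pca, workdir / "pca_model")
        Z = {name: transform_pca(pca, fused[name]) for name in fused}
        for name in Z:
            pd.DataFrame(
                Z[name], columns=[f"pc.{i:03d}" for i in range(pca.k)]
            ).assign(label=labels[name]).to_csv(workdir / f"reduced_{name}.csv", index=False)
        logger.info("PCA retained k=%d components (%.3f of variance)",
                    pca.k, pca.retained_fraction)

        # ---- hybrids ------------------------------------------------------
        summary: dict = {
            "workdir": str(workdir),
            "n_images": len(balanced),
            "classes": list(balanced.class_set),
            "fused_dim": int(fused["train"].values.shape[1]),
            "pca_k": int(pca.k),
            "pca_retained_fraction": float(pca.retained_fraction),
            "learners": {},
        }
        class_set = list(balanced.class_set)
        min_class = min(
            int(np.sum(labels["train"] == c)) for c in np.unique(labels["train"])
        )
        folds = max(2, min(5, min_class))
        first_stack = None
        for learner in config.resolved_learners():
            stage = f"train:{learner}"
            cfg = BaseLearnerConfig(name=learner,
                                    seed=child_seed(config.seed, "base", learner))
            stack = fit_hybrid(
                cfg, Z["train"], labels["train"], Z["val"], labels["val"],
                train_cfg=config.dnn_train, seed=child_seed(config.seed, "stack", learner),
                folds=folds,
            )
            save_stack(stack, workdir / f"model_{learner}")
            _history_to_csv(stack.history, workdir / f"history_{learner}.csv")
            if first_stack is None:
                first_stack = stack

            stage = f"evaluate:{learner}"
            y_pred, probs = predict(stack, Z["test"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = evaluate_predictions(labels["test"], y_pred, probs, class_set)
            report.save(workdir / f"report_{learner}.json")
            pd.DataFrame(report.confusion, index=class_set, columns=class_set).to_csv(
                workdir / f"confusion_{learner}.csv"
            )
            summary["learners"][learner] = {
                "test_accuracy": report.accuracy,
                "weighted_f1": report.weighted["f1"],
                "macro_auc": report.macro_auc,
                "epochs_trained": len(stack.history["epoch"]),
            }
            logger.info("%s+DNN test accuracy %.4f", learner, report.accuracy)

        # ---- explanations -------------------------------------------------
        stage = "explain"
        stats = FeatureStats.from_data(Z["train"])
        f = predict_proba_fn(first_stack)
        n_explain = min(config.n_explanations, len(Z["test"]))
        feature_names = [f"pc.{i:03d}" for i in range(pca.k)]
        for i in range(n_explain):
            true_label = labels["test"][i]
            expl = explain_instance(
                f, Z["test"][i], true_label,
                LimeConfig(
                    n_samples=config.lime.n_samples,
                    kernel_width=config.lime.kernel_width,
                    n_features=min(config.lime.n_features, pca.k),
                    ridge_alpha=config.lime.ridge_alpha,
                    seed=child_seed(config.seed, "lime", i),
                ),
                stats, classes=first_stack.classes, feature_names=feature_names,
                instance_id=test_m.records[i][0],
            )
            expl.save(workdir / f"explanation_{i:02d}.json")

        stage = "summary"
        (workdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    except PipelineError:
        raise
    except Exception as exc:  # tag the failing stage
        logger.exception("stage %s failed", stage)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
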