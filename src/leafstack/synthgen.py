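"""Synthetic leaf images and feature tables for end-to-end testing.

The generator emulates the statistical structure of controlled-condition
leaf photographs: a single centered leaf (an ellipse of a class-specific
base color) on a uniform dark background, with class-dependent circular
lesions, additive gray-level texture noise, and class-dependent
eccentricity. The signals are deliberately simple — the point is that
color, texture and shape descriptors all carry class information, so the
downstream pipeline has something real to learn, deterministically.

A companion Gaussian-blob feature-table generator provides a controlled
stand-in for the reduced feature matrices consumed by the stacking stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import disk, ellipse

from ._rng import child_seed, rng_from

__all__ = [
    "ClassSpec",
    "DatasetManifest",
    "FeatureTableSpec",
    "generate_leaf_image",
    "generate_dataset",
    "generate_feature_table",
    "feature_table_means",
    "default_class_specs",
]

DEFAULT_IMAGE_SIDE = 256
DEFAULT_BACKGROUND = (40, 40, 40)


def _check_rgb(name: str, value) -> tuple[int, int, int]:
    triple = tuple(int(v) for v in value)
    if len(triple) != 3 or any(v < 0 or v > 255 for v in triple):
        raise ValueError(f"{name} must be an RGB triple in [0, 255], got {value!r}")
    return triple


@dataclass(frozen=True)
class ClassSpec:
    """Rendering recipe for one synthetic disease class.

    Parameters
    ----------
    name:
        Class label.
    base_color:
        Healthy-tissue RGB color of the leaf ellipse.
    lesion_count_range:
        Inclusive (low, high) range for the number of circular lesions.
    lesion_color:
        RGB color of lesion disks.
    lesion_radius_range:
        Inclusive (low, high) lesion radius in pixels.
    texture_noise_sd:
        Standard deviation (gray levels, 0-255 scale) of the additive
        per-pixel luminance noise on the leaf region.
    eccentricity:
        Eccentricity of the leaf ellipse in [0, 1); 0 is a circle.
    background_color:
        Uniform background RGB.
    """

    name: str
    base_color: tuple[int, int, int]
    lesion_count_range: tuple[int, int] = (0, 0)
    lesion_color: tuple[int, int, int] = (110, 80, 30)
    lesion_radius_range: tuple[int, int] = (4, 9)
    texture_noise_sd: float = 0.0
    eccentricity: float = 0.3
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND

    def __post_init__(self):
        object.__setattr__(self, "base_color", _check_rgb("base_color", self.base_color))
        object.__setattr__(self, "lesion_color", _check_rgb("lesion_color", self.lesion_color))
        object.__setattr__(
            self, "background_color", _check_rgb("background_color", self.background_color)
        )
        lo, hi = self.lesion_count_range
        if lo < 0 or lo > hi:
            raise ValueError("lesion_count_range must satisfy 0 <= low <= high")
        rlo, rhi = self.lesion_radius_range
        if rlo < 1 or rlo > rhi:
            raise ValueError("lesion_radius_range must satisfy 1 <= low <= high")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ValueError("eccentricity must be in [0, 1)")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")


@dataclass(frozen=True)
class DatasetManifest:
    """Image paths and labels, plus the sorted label set."""

    records: tuple[tuple[str, str], ...]
    class_set: tuple[str, ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("manifest must be non-empty")
        paths = [p for p, _ in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")
        missing = {lab for _, lab in self.records} - set(self.class_set)
        if missing:
            raise ValueError(f"labels outside class_set: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FeatureTableSpec:
    """Design of a Gaussian-blob feature table.

    Class ``c`` is drawn from a spherical Gaussian with per-feature
    standard deviation ``noise_sd`` around a class-specific mean; the
    means are placed so pairwise distances equal
    ``separation * noise_sd`` (exactly when ``dim >= n_classes``).
    """

    n_per_class: int
    n_classes: int
    dim: int
    separation: float
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_class, self.n_classes, self.dim) < 1:
            raise ValueError("n_per_class, n_classes and dim must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _leaf_axes(spec: ClassSpec, side: int) -> tuple[float, float]:
    a = 0.42 * side
    b = a * float(np.sqrt(1.0 - spec.eccentricity**2))
    return a, b


def generate_leaf_image(
    spec: ClassSpec,
    seed: int,
    side: int = DEFAULT_IMAGE_SIDE,
    return_meta: bool = False,
):
    """Render one synthetic leaf image.

    Draws a centered ellipse of ``base_color`` on ``background_color``,
    stamps the sampled number of lesion disks (clipped to the leaf), and
    adds per-pixel gray-level noise over the leaf region. Deterministic
    given ``(spec, seed)``.

    Returns the HxWx3 uint8 image, or ``(image, meta)`` with the leaf
    mask and lesion geometry when ``return_meta`` is true.
    """
    rng = np.random.default_rng(seed)
    a, b = _leaf_axes(spec, side)
    if spec.lesion_count_range[1] > 0 and spec.lesion_radius_range[1] > b:
        raise ValueError(
            f"lesion radius up to {spec.lesion_radius_range[1]} exceeds the "
            f"leaf minor semi-axis {b:.1f}"
        )

    img = np.empty((side, side, 3), dtype=np.float64)
    img[:] = spec.background_color
    center = (side / 2.0, side / 2.0)
    angle = rng.uniform(0.0, np.pi)
    rr, cc = ellipse(center[0], center[1], b, a, shape=(side, side), rotation=angle)
    leaf_mask = np.zeros((side, side), dtype=bool)
    leaf_mask[rr, cc] = True
    img[leaf_mask] = spec.base_color

    n_lesions = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
    lesions: list[tuple[float, float, int]] = []
    lesion_mask = np.zeros((side, side), dtype=bool)
    for _ in range(n_lesions):
        # sample a center uniformly inside the (unrotated) ellipse, then rotate
        while True:
            u, v = rng.uniform(-1.0, 1.0, size=2)
            if u * u + v * v <= 1.0:
                break
        dy, dx = u * b * 0.8, v * a * 0.8
        cy = center[0] + dy * np.cos(angle) - dx * np.sin(angle)
        cx = center[1] + dy * np.sin(angle) + dx * np.cos(angle)
        radius = int(rng.integers(spec.lesion_radius_range[0], spec.lesion_radius_range[1] + 1))
        lrr, lcc = disk((cy, cx), radius, shape=(side, side))
        keep = leaf_mask[lrr, lcc]
        lesion_mask[lrr[keep], lcc[keep]] = True
        lesions.append((float(cy), float(cx), radius))
    img[lesion_mask] = spec.lesion_color

    if spec.texture_noise_sd > 0:
        noise = rng.normal(0.0, spec.texture_noise_sd, size=(side, side))
        img[leaf_mask] += noise[leaf_mask][:, None]

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if return_meta:
        meta = {
            "leaf_mask": leaf_mask,
            "lesion_mask": lesion_mask,
            "lesions": lesions,
            "angle": float(angle),
            "axes": (a, b),
        }
        return out, meta
    return out


def generate_dataset(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    out_dir: str | Path,
    seed: int,
    side: int = DEFAULT_IMAGE_SIDE,
) -> DatasetManifest:
    """Write ``n_per_class`` PNGs per class plus a ``manifest.csv``.

    Per-image seeds are derived from the master seed and the (class,
    image) indices, so generation is reproducible and order-independent.
    The manifest stores paths relative to its own directory.
    """
    if len(specs) < 2:
        raise ValueError("need at least two class specs")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("class spec names must be unique")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[tuple[str, str]] = []
    for ci, spec in enumerate(specs):
        cls_dir = out_dir / spec.name
        cls_dir.mkdir(exist_ok=True)
        for ii in range(n_per_class):
            img = generate_leaf_image(spec, child_seed(seed, "image", ci, ii), side=side)
            rel = f"{spec.name}/{spec.name}_{ii:04d}.png"
            Image.fromarray(img).save(out_dir / rel)
            records.append((rel, spec.name))

    manifest = DatasetManifest(records=tuple(records), class_set=tuple(sorted(set(names))))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(manifest.records)


def read_manifest(path: str | Path) -> DatasetManifest:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["path", "label"]:
            raise ValueError(f"manifest header must be path,label, got {header!r}")
        records = tuple((row[0], row[1]) for row in reader)
    labels = tuple(sorted({lab for _, lab in records}))
    return DatasetManifest(records=records, class_set=labels)


def feature_table_means(spec: FeatureTableSpec) -> np.ndarray:
    """Design class means of :func:`generate_feature_table` (m x d).

    For ``dim >= n_classes`` the means sit on scaled standard-basis
    vectors, so every pairwise distance is exactly
    ``separation * noise_sd``. For ``dim < n_classes`` means are random
    unit directions scaled to the same magnitude (distances approximate).
    """
    m, d = spec.n_classes, spec.dim
    scale = spec.separation * spec.noise_sd / np.sqrt(2.0)
    if d >= m:
        means = np.zeros((m, d))
        means[np.arange(m), np.arange(m)] = scale
        return means
    rng = rng_from(spec.seed, "means")
    dirs = rng.normal(size=(m, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * scale


def generate_feature_table(spec: FeatureTableSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the Gaussian-blob table: (X of n x d, y of n labels)."""
    means = feature_table_means(spec)
    rng = rng_from(spec.seed, "table")
    n = spec.n_per_class * spec.n_classes
    X = np.empty((n, spec.dim))
    y = np.empty(n, dtype=np.int64)
    row = 0
    for c in range(spec.n_classes):
        X[row : row + spec.n_per_class] = means[c] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_per_class, spec.dim)
        )
        y[row : row + spec.n_per_class] = c
        row += spec.n_per_class
    return X, y


def default_class_specs(n_classes: int = 15, seed: int = 2024) -> list[ClassSpec]:
    """Fifteen leaf-disease classes with distinct color/texture/shape signals.

    Class names follow the usual bell pepper / potato / tomato disease
    nomenclature. Base hue drifts across classes, lesion load and texture
    noise grow with disease severity, and eccentricity separates the
    species' leaf shapes.
    """
    names = [
        "Pepper_bell_Bacterial_spot",
        "Pepper_bell_healthy",
        "Potato_Early_blight",
        "Potato_Late_blight",
        "Potato_healthy",
        "Tomato_Bacterial_spot",
        "Tomato_Early_blight",
        "Tomato_Late_blight",
        "Tomato_Leaf_Mold",
        "Tomato_Septoria_leaf_spot",
        "Tomato_Spider_mites",
        "Tomato_Target_Spot",
        "Tomato_YellowLeaf_Curl_Virus",
        "Tomato_mosaic_virus",
        "Tomato_healthy",
    ]
    if not (2 <= n_classes <= len(names)):
        raise ValueError(f"n_classes must be in [2, {len(names)}]")
    rng = rng_from(seed, "class-specs")
    specs = []
    for i, name in enumerate(names[:n_classes]):
        healthy = name.endswith("healthy")
        green = 150 - 6 * i + int(rng.integers(-5, 6))
        base = (30 + 4 * i, int(np.clip(green, 60, 200)), 30 + 2 * i)
        lesion_hue = (
            (150 - 4 * i, 110 - 3 * i, 25),  # browns/yellows drifting per class
        )[0]
        count = (0, 0) if healthy else (2 + i % 4, 5 + i % 5)
        specs.append(
            ClassSpec(
                name=name,
                base_color=base,
                lesion_count_range=count,
                lesion_color=lesion_hue,
                lesion_radius_range=(4, 8 + i % 4),
                texture_noise_sd=1.0 + (0.0 if healthy else 2.0 + 0.8 * (i % 5)),
                eccentricity=0.15 + 0.05 * (i % 10),
            )
        )
    return specs
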