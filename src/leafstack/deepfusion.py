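"""Deep feature extraction (convolutional backbone + GAP) and fusion.

The deep half of the feature pipeline is ``f_deep = GAP(phi(x; theta))``:
a convolutional feature extractor whose final maps are reduced by global
average pooling. The backbone is pluggable: the default is a seeded
random-weight surrogate network (three stride-2 ReLU conv layers), which
has the same interface and pooling math as a pretrained network while
keeping the package self-contained; an ``external`` hook accepts any
user-supplied callable (e.g. a real pretrained extractor).

Fusion is the ordered concatenation F = [f_traditional || f_deep].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._rng import rng_from
from .handcrafted import HandcraftedVector, _check_image

__all__ = [
    "BackboneSpec",
    "SurrogateBackbone",
    "FusedMatrix",
    "conv2d",
    "gap",
    "deep_features",
    "fuse",
    "fuse_rows",
]


def conv2d(x: np.ndarray, weights: np.ndarray, bias: np.ndarray, stride: int = 1) -> np.ndarray:
    """2-D multi-channel convolution (cross-correlation), zero-padded 'same'.

    ``x``: H x W x C_in; ``weights``: kh x kw x C_in x C_out; output
    ceil(H/stride) x ceil(W/stride) x C_out.
    """
    kh, kw, cin, cout = weights.shape
    if x.shape[2] != cin:
        raise ValueError(f"channel mismatch: input {x.shape[2]}, kernel {cin}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((ph, ph), (pw, pw), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(0, 1))
    windows = windows[::stride, ::stride]  # H' x W' x C_in x kh x kw
    return np.einsum("hwcij,ijco->hwo", windows, weights, optimize=True) + bias


def gap(feature_maps: np.ndarray) -> np.ndarray:
    """Global average pooling: mean over spatial positions per channel."""
    fm = np.asarray(feature_maps, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError("expected H x W x C feature maps")
    return fm.mean(axis=(0, 1))


@dataclass(frozen=True)
class BackboneSpec:
    """Configuration of the deep feature extractor.

    ``kind='surrogate'`` builds a seeded random-weight conv net with
    ``output_dim`` channels; ``kind='external'`` wraps ``external_fn``,
    a callable mapping an RGB image to a feature vector.
    """

    kind: str = "surrogate"
    seed: int = 7
    output_dim: int = 64
    input_side: int = 224
    external_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.kind not in ("surrogate", "external"):
            raise ValueError(f"unknown backbone kind {self.kind!r}")
        if self.output_dim < 0:
            raise ValueError("output_dim must be >= 0")
        if self.kind == "external" and self.external_fn is None:
            raise ValueError("external backbone requires external_fn")


class SurrogateBackbone:
    """Seeded random-weight convolutional feature extractor.

    Three 3x3 stride-2 convolutions (channels 3 -> 16 -> 32 -> D) with
    He-scaled Gaussian weights drawn once from ``seed``, ReLU activations
    (or none, for linearity tests), followed by GAP. A pure, deterministic
    function of ``(seed, image)``.
    """

    def __init__(self, seed: int = 7, output_dim: int = 64, activation: str = "relu"):
        if activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        self.seed = seed
        self.output_dim = output_dim
        self.activation = activation
        rng = rng_from(seed, "surrogate-backbone")
        channels = [3, 16, 32, output_dim]
        self.layers = []
        for cin, cout in zip(channels[:-1], channels[1:]):
            scale = np.sqrt(2.0 / (3 * 3 * cin))
            W = rng.normal(0.0, scale, size=(3, 3, cin, cout))
            b = np.zeros(cout)
            self.layers.append((W, b))

    def __call__(self, img: np.ndarray) -> np.ndarray:
        x = _check_image(img).astype(np.float64) / 255.0
        for W, b in self.layers:
            x = conv2d(x, W, b, stride=2)
            if self.activation == "relu":
                x = np.maximum(x, 0.0)
        return gap(x)


def deep_features(img: np.ndarray, backbone: BackboneSpec) -> np.ndarray:
    """Extract the D-dimensional GAP descriptor for one image."""
    img = _check_image(img)
    if img.shape[0] != backbone.input_side or img.shape[1] != backbone.input_side:
        raise ValueError(
            f"image side {img.shape[:2]} does not match backbone input_side "
            f"{backbone.input_side}; resize first"
        )
    if backbone.output_dim == 0:
        return np.empty(0)
    if backbone.kind == "external":
        out = np.asarray(backbone.external_fn(img), dtype=np.float64).ravel()
        if out.size != backbone.output_dim:
            raise ValueError(
                f"external backbone returned {out.size} features, expected "
                f"{backbone.output_dim}"
            )
        return out
    net = SurrogateBackbone(seed=backbone.seed, output_dim=backbone.output_dim)
    return net(img)


@dataclass
class FusedMatrix:
    """Fused feature matrix with named columns and the block boundary."""

    values: np.ndarray
    column_names: list[str]
    n_traditional: int

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names must match the matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused matrix must be finite")

    @property
    def traditional(self) -> np.ndarray:
        return self.values[:, : self.n_traditional]

    @property
    def deep(self) -> np.ndarray:
        return self.values[:, self.n_traditional :]


def fuse(f_trad: HandcraftedVector | np.ndarray, f_deep: np.ndarray) -> np.ndarray:
    """One fused row: handcrafted block first, deep block second."""
    trad = f_trad.values if isinstance(f_trad, HandcraftedVector) else np.asarray(f_trad)
    f_deep = np.asarray(f_deep, dtype=np.float64)
    row = np.concatenate([np.asarray(trad, dtype=np.float64), f_deep])
    if not np.all(np.isfinite(row)):
        raise ValueError("fused vector must be finite")
    return row


def fuse_rows(
    handcrafted_vectors: Sequence[HandcraftedVector], deep_vectors: Sequence[np.ndarray]
) -> FusedMatrix:
    """Stack per-image fused rows into a named FusedMatrix."""
    if len(handcrafted_vectors) != len(deep_vectors):
        raise ValueError("need one deep vector per handcrafted vector")
    if not handcrafted_vectors:
        raise ValueError("empty input")
    trad_names = handcrafted_vectors[0].feature_names
    d_deep = len(np.asarray(deep_vectors[0]).ravel())
    names = trad_names + [f"deep.{i:03d}" for i in range(d_deep)]
    rows = [fuse(h, d) for h, d in zip(handcrafted_vectors, deep_vectors)]
    return FusedMatrix(
        values=np.vstack(rows), column_names=names, n_traditional=len(trad_names)
    )
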