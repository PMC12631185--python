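"""Handcrafted leaf-image descriptors and their fixed-layout fusion block.

Implements the classical half of the feature pipeline: per-channel HSV and
CIE-LAB color histograms, dominant colors via k-means on RGB pixels, local
binary pattern (LBP) texture codes, gray-level co-occurrence (GLCM)
contrast and angular second moment, and shape descriptors (area, perimeter,
circularity) of the segmented leaf. :func:`extract_handcrafted` assembles
the blocks in a fixed, documented order.

Conventions that the literature leaves open and we pin down:

* color histograms use ``B`` equal-width bins on each channel mapped to
  [0, 1] — HSV channels are already in [0, 1]; LAB channels are mapped by
  their nominal ranges (L/100, (a+128)/255, (b+128)/255);
* LBP uses ``P = 8`` integer-offset neighbors on the radius-1 ring,
  counter-clockwise from (row, col+1), with s(z) = 1 iff z >= 0;
* GLCM uses 8 gray levels, distance 1, the four standard angles,
  symmetrized and normalized, features averaged over angles;
* grayscale is BT.601 luma scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize
from scipy import ndimage

__all__ = [
    "UnsegmentableImageError",
    "HandcraftedParams",
    "HandcraftedVector",
    "resize_image",
    "color_histogram",
    "dominant_colors",
    "kmeans_rgb",
    "to_gray",
    "lbp_histogram",
    "glcm_features",
    "segment_leaf",
    "shape_descriptors",
    "extract_handcrafted",
]


class UnsegmentableImageError(ValueError):
    """Raised when an image has no intensity structure to segment."""


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    return img


def resize_image(img: np.ndarray, side: int = 224) -> np.ndarray:
    """Plain bilinear rescale to ``side x side`` (aspect not preserved)."""
    img = _check_image(img)
    if side < 1:
        raise ValueError("side must be >= 1")
    if img.shape[0] == side and img.shape[1] == side:
        return img.astype(np.uint8, copy=True)
    out = _sk_resize(
        img.astype(np.float64),
        (side, side, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _channels_01(img: np.ndarray, space: str) -> np.ndarray:
    """Convert to the requested space with every channel mapped to [0, 1]."""
    rgb01 = _check_image(img).astype(np.float64) / 255.0
    space = space.upper()
    if space == "HSV":
        return skcolor.rgb2hsv(rgb01)
    if space == "LAB":
        lab = skcolor.rgb2lab(rgb01)
        out = np.empty_like(lab)
        out[..., 0] = lab[..., 0] / 100.0
        out[..., 1] = (lab[..., 1] + 128.0) / 255.0
        out[..., 2] = (lab[..., 2] + 128.0) / 255.0
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown color space {space!r} (expected HSV or LAB)")


def color_histogram(
    img: np.ndarray, space: str, bins_per_channel: int = 8, normalize: bool = False
) -> np.ndarray:
    """Per-channel histogram H_c(b) over B equal-width bins on [0, 1].

    Returns the three channel blocks concatenated (length 3*B). Without
    normalization each channel's counts sum to the pixel count; with it,
    each channel block sums to 1.
    """
    if bins_per_channel < 1:
        raise ValueError("bins_per_channel must be >= 1")
    chans = _channels_01(img, space)
    blocks = []
    for c in range(3):
        counts, _ = np.histogram(chans[..., c].ravel(), bins=bins_per_channel, range=(0.0, 1.0))
        counts = counts.astype(np.float64)
        if normalize:
            counts /= counts.sum()
        blocks.append(counts)
    return np.concatenate(blocks)


def kmeans_rgb(
    pixels: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 100,
    tol: float = 1e-4,
    return_history: bool = False,
):
    """Lloyd's k-means on pixel triples with k-means++ initialization.

    Centroid j is the mean of its assigned pixels. Empty clusters are
    re-seeded at the point farthest from its current centroid. Returns
    ``(centroids, counts)`` and, optionally, the per-iteration objective
    (within-cluster sum of squares), which is non-increasing.
    """
    X = np.asarray(pixels, dtype=np.float64)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} pixels, got {n}")
    rng = np.random.default_rng(seed)

    # k-means++ seeding
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))

    history: list[float] = []
    assign = np.zeros(n, dtype=np.int64)
    for _ in range(max_iter):
        dist2 = np.sum((X[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        assign = np.argmin(dist2, axis=1)
        history.append(float(dist2[np.arange(n), assign].sum()))
        new_centroids = centroids.copy()
        for j in range(k):
            members = assign == j
            if members.any():
                new_centroids[j] = X[members].mean(axis=0)
            else:
                # re-seed at the point farthest from its assigned centroid
                far = int(np.argmax(dist2[np.arange(n), assign]))
                new_centroids[j] = X[far]
        shift = float(np.max(np.linalg.norm(new_centroids - centroids, axis=1)))
        centroids = new_centroids
        if shift <= tol:
            break
    dist2 = np.sum((X[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    assign = np.argmin(dist2, axis=1)
    history.append(float(dist2[np.arange(n), assign].sum()))
    counts = np.bincount(assign, minlength=k)
    if return_history:
        return centroids, counts, history
    return centroids, counts


def dominant_colors(
    img: np.ndarray, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant colors by k-means over RGB pixels.

    Returns ``(centroids, proportions)`` with clusters sorted by
    descending size, ties broken lexicographically on the centroid. The
    first centroid is "the" dominant color.
    """
    img = _check_image(img)
    pixels = img.reshape(-1, 3).astype(np.float64)
    centroids, counts = kmeans_rgb(pixels, k=k, seed=seed)
    order = sorted(
        range(k), key=lambda j: (-counts[j], tuple(np.round(centroids[j], 9)))
    )
    centroids = centroids[order]
    props = counts[order] / counts.sum()
    return centroids, props


def to_gray(img: np.ndarray) -> np.ndarray:
    """BT.601 luma in [0, 1]: (0.299 R + 0.587 G + 0.114 B) / 255."""
    img = _check_image(img).astype(np.float64)
    return (0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]) / 255.0


def _lbp_offsets(P: int, R: int) -> list[tuple[int, int]]:
    """Integer ring offsets, counter-clockwise from (row, col+R)."""
    offsets = []
    for p in range(P):
        theta = 2.0 * np.pi * p / P
        dr = -int(round(R * np.sin(theta)))
        dc = int(round(R * np.cos(theta)))
        offsets.append((dr, dc))
    return offsets


def lbp_histogram(
    gray: np.ndarray, P: int = 8, R: int = 1, normalize: bool = False
) -> np.ndarray:
    """Histogram of LBP codes sum_p s(g_p - g_c) 2^p, s(z)=1 iff z>=0.

    Neighbors sit at integer offsets on the radius-``R`` ring (no
    interpolation); only pixels with a complete neighborhood contribute,
    so the un-normalized histogram sums to (H-2R)(W-2R).
    """
    g = np.asarray(gray, dtype=np.float64)
    H, W = g.shape
    if H <= 2 * R or W <= 2 * R:
        raise ValueError(f"image {g.shape} too small for LBP radius {R}")
    center = g[R : H - R, R : W - R]
    codes = np.zeros_like(center, dtype=np.int64)
    for p, (dr, dc) in enumerate(_lbp_offsets(P, R)):
        neighbor = g[R + dr : H - R + dr, R + dc : W - R + dc]
        codes += (neighbor >= center).astype(np.int64) << p
    hist = np.bincount(codes.ravel(), minlength=2**P).astype(np.float64)
    if normalize:
        hist /= hist.sum()
    return hist


def glcm_features(
    gray: np.ndarray,
    levels: int = 8,
    angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
    distance: int = 1,
    symmetric: bool = True,
) -> tuple[float, float]:
    """Co-occurrence contrast and angular second moment, angle-averaged.

    Intensities in [0, 1] are quantized to ``levels`` gray levels by
    ``min(floor(g * levels), levels - 1)``; the co-occurrence matrix is
    accumulated at the given pixel distance for each angle, symmetrized
    and normalized to probabilities P(i, j). Contrast is
    ``sum (i-j)^2 P(i,j)`` and ASM is ``sum P(i,j)^2``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2 or min(g.shape) < 2:
        raise ValueError("need a 2-D image with both sides >= 2")
    q = np.minimum((g * levels).astype(np.int64), levels - 1).astype(np.uint8)
    glcm = graycomatrix(
        q, distances=[distance], angles=list(angles), levels=levels,
        symmetric=symmetric, normed=True,
    )
    contrast = float(graycoprops(glcm, "contrast").mean())
    asm = float(graycoprops(glcm, "ASM").mean())
    return contrast, asm


def segment_leaf(img: np.ndarray) -> np.ndarray:
    """Foreground mask of the leaf.

    Otsu-thresholds the grayscale image, takes as foreground the binary
    class with fewer border-touching pixels (the leaf is centered, the
    background reaches the frame), keeps the largest 8-connected
    component and fills interior holes.
    """
    gray = to_gray(img)
    if float(gray.max() - gray.min()) == 0.0:
        raise UnsegmentableImageError("constant image: no threshold exists")
    thr = threshold_otsu(gray)
    fg = gray > thr
    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if fg[border].sum() > (~fg)[border].sum():
        fg = ~fg
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise UnsegmentableImageError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    fg = labels == int(np.argmax(sizes))
    return ndimage.binary_fill_holes(fg)


def shape_descriptors(mask: np.ndarray) -> tuple[float, float, float]:
    """(area, perimeter, circularity) of a binary mask.

    Area is the foreground pixel count; the perimeter is the arc length
    of the longest sub-pixel contour traced at level 0.5 on a lightly
    smoothed (Gaussian sigma = 1 px) copy of the mask — tracing the raw
    binary staircase overestimates curved perimeters by ~5%, which the
    smoothing removes. Circularity is 4*pi*A / P^2 (1 for an ideal disk).
    """
    mask = np.asarray(mask, dtype=bool)
    A = float(mask.sum())
    if A == 0:
        raise ValueError("empty mask has no shape")
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2), 1.0)
    contours = measure.find_contours(padded, 0.5)
    perimeter = max(
        float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))) for c in contours
    )
    circ = 4.0 * np.pi * A / perimeter**2
    return A, perimeter, circ


@dataclass(frozen=True)
class HandcraftedParams:
    """Knobs of the handcrafted extractor (defaults give a 321-dim vector)."""

    side: int = 224
    color_bins: int = 8
    lbp_neighbors: int = 8
    lbp_radius: int = 1
    glcm_levels: int = 8
    kmeans_seed: int = 0
    normalize_histograms: bool = True


@dataclass(frozen=True)
class HandcraftedVector:
    """Fixed-layout handcrafted descriptor with named blocks."""

    values: np.ndarray
    blocks: dict[str, slice]
    segmentation_failed: bool = False

    def block(self, name: str) -> np.ndarray:
        return self.values[self.blocks[name]]

    @property
    def feature_names(self) -> list[str]:
        names = [""] * len(self.values)
        for block, sl in self.blocks.items():
            for i, j in enumerate(range(sl.start, sl.stop)):
                names[j] = f"{block}.{i:03d}"
        return names


def block_layout(params: HandcraftedParams) -> dict[str, slice]:
    """Block name -> slice, in the fixed concatenation order."""
    B, P = params.color_bins, params.lbp_neighbors
    sizes = [
        ("hsv", 3 * B),
        ("lab", 3 * B),
        ("dominant", 12),
        ("lbp", 2**P),
        ("glcm", 2),
        ("shape", 3),
    ]
    layout, start = {}, 0
    for name, size in sizes:
        layout[name] = slice(start, start + size)
        start += size
    return layout


def extract_handcrafted(
    img: np.ndarray, params: HandcraftedParams = HandcraftedParams()
) -> HandcraftedVector:
    """Resize, compute every descriptor block and concatenate.

    Block order: hsv (3B) | lab (3B) | dominant (9 centroids scaled to
    [0,1] + 3 proportions) | lbp (2^P) | glcm (contrast, ASM) | shape
    (A, perimeter, circularity). With defaults the dimension is
    24 + 24 + 12 + 256 + 2 + 3 = 321. An unsegmentable image yields a
    zero shape block and a warning instead of an error.
    """
    img = resize_image(img, params.side)
    layout = block_layout(params)

    hsv = color_histogram(img, "HSV", params.color_bins, normalize=params.normalize_histograms)
    lab = color_histogram(img, "LAB", params.color_bins, normalize=params.normalize_histograms)
    centroids, props = dominant_colors(img, k=3, seed=params.kmeans_seed)
    dom = np.concatenate([centroids.ravel() / 255.0, props])
    gray = to_gray(img)
    lbp = lbp_histogram(
        gray, P=params.lbp_neighbors, R=params.lbp_radius,
        normalize=params.normalize_histograms,
    )
    contrast, asm = glcm_features(gray, levels=params.glcm_levels)

    failed = False
    try:
        mask = segment_leaf(img)
        shape = np.array(shape_descriptors(mask))
    except UnsegmentableImageError:
        warnings.warn("unsegmentable image: shape block set to zeros", stacklevel=2)
        shape = np.zeros(3)
        failed = True

    values = np.concatenate([hsv, lab, dom, lbp, [contrast, asm], shape])
    assert len(values) == layout["shape"].stop
    return HandcraftedVector(values=values, blocks=layout, segmentation_failed=failed)
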