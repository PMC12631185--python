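# Methods

This note records the algorithms, parameter choices and numerical
conventions implemented in `leafstack`, plus what the synthetic-data
validation does and does not establish.

## Synthetic data

**Leaf images** (`synthgen.generate_leaf_image`). Each class is a
`ClassSpec`: base RGB leaf color, lesion count range and color, lesion
radius range, texture noise standard deviation, and ellipse eccentricity.
An image (default 256×256) is a dark background (RGB 40,40,40) with a
centered, randomly rotated ellipse of semi-major axis 0.42·side and minor
axis derived from the eccentricity. Circular lesions are placed uniformly
inside the leaf and clipped to it; a single per-pixel gray offset
(N(0, noise_sd)) is added to leaf pixels only. A lesion radius larger than
the minor semi-axis is rejected at spec validation. Images are
reproducible from `(spec, seed)` alone.

**Feature tables** (`synthgen.generate_feature_table`). Isotropic Gaussian
blobs with class means placed so that all pairwise mean distances equal
`separation · sd` exactly (scaled orthonormal basis vectors when the
dimension allows it). `separation=0` gives label-free noise — the
chance-level control used by the tests.

Synthetic data exercises the full code path but is deliberately easy:
classes differ by designed color/texture/shape signals. Passing results
demonstrate **correctness and determinism of the pipeline**, not
field-image performance; accuracy numbers on this data say nothing about
real leaf photographs.

## Handcrafted descriptors (321 dims)

Images are resized to 224×224 (bilinear, clipped, rounded to uint8)
before descriptor extraction. Block layout:
`hsv(24) | lab(24) | dominant(12) | lbp(256) | glcm(2) | shape(3)`.

- **Color histograms**: 8 bins per channel over [0,1]. HSV channels are
  already in [0,1]; LAB uses fixed affine maps L/100, (a+128)/255,
  (b+128)/255 so bin edges do not depend on the image. Histograms are
  count-conserving and (by default) normalized to unit mass per channel.
- **Dominant colors**: our own Lloyd k-means (k-means++ init, empty
  clusters re-seeded at the farthest point) on RGB pixels, k=4; the block
  stores centroids sorted by decreasing cluster size (ties broken
  lexicographically) scaled to [0,1].
- **LBP**: hand-written, P=8 neighbors, R=1, integer offsets
  counter-clockwise starting at (row, col+1), comparison s(z)=1 iff z≥0;
  256-bin code histogram.
- **GLCM**: gray image quantized to 8 levels (`min(⌊g·L⌋, L−1)`);
  co-occurrence at distance 1, four angles, symmetric and normalized
  (via `skimage.graycomatrix`); contrast and ASM averaged over angles.
- **Shape**: Otsu threshold; the foreground is the class with fewer
  border pixels; largest 8-connected component; holes filled. Area is
  the pixel count. The perimeter comes from the longest
  `find_contours(level=0.5)` contour of the mask after padding by 2 and
  Gaussian smoothing with σ=1 — marching squares on a raw binary mask
  overestimates curved perimeters by ≈5%, which would bias circularity
  4πA/P² (a unit disk must score ≈1; we measure 0.985–0.99 for disks and
  π/4±5% for squares). An unsegmentable image (uniform, empty) yields a
  zeroed shape block and a warning rather than an error.

## Deep features and fusion

The default backbone is a **seeded random-convolution surrogate**: three
3×3, stride-2 convolution layers (3→16→32→D, default D=64), He-scaled
Gaussian weights drawn from the backbone seed, ReLU, then global average
pooling. Random convolutional features are a standard cheap stand-in for
pretrained embeddings; the `BackboneSpec(kind="external")` hook accepts
any `image → vector` callable for real CNNs. Fusion is plain
concatenation, handcrafted block first.

## Balancing, PCA

Classes are capped at 150 samples each (per-class seeded subsampling,
original order preserved; a warning is logged for classes under the cap).
PCA standardizes columns (ddof=1; zero-variance columns get scale 1),
then eigendecomposes the covariance — or its n×n Gram counterpart when
d > n — clips tiny negative eigenvalues, and fixes component signs by
making the largest-magnitude loading positive. k is either given or the
smallest number of components reaching the variance threshold (default
0.95), capped at min(d, n−1). The implementation is cross-checked against
SVD to 1e−8 in the tests.

## Hybrid stacking

Base learners: random forest (100 trees, √d features), XGBoost
(100 rounds, depth 6, lr 0.3, hist), gradient boosting (100, lr 0.1,
depth 3), k-NN (k=5, Euclidean), and a hand-written multinomial softmax
regression (full-batch Adam, L2). All run single-threaded for
determinism; XGBoost's float32 probability rows are renormalized.

The meta-learner input is the base learner's **out-of-fold** class
probabilities from stratified 5-fold cross-fitting (the pipeline clamps
folds to `max(2, min(5, smallest class count))` for tiny runs). The head
is a NumPy dense network 512→256→128→m with ReLU, inverted dropout 0.3
and softmax, trained by Adam (lr 1e−3, batch 32, ≤300 epochs) with
early stopping on validation loss (patience 30, best weights restored).
A `naive=True` flag trains on in-sample probabilities instead, kept only
to demonstrate the leakage it causes.

## LIME

For instance x: draw n=1000 perturbations z ~ N(x, diag(sd²)) using
per-feature training standard deviations (first row is x itself); weight
by exp(−D²/σ²) with D the Euclidean distance in standardized units and
σ = 0.75·√d by default; select the K most relevant features by
kernel-weighted covariance with the target-class probability; fit
`Ridge(alpha=1.0)` with those sample weights. Fidelity is the
kernel-weighted R² of the local fit. The tests verify sign and rank
recovery on a known linear-logit black box.

## Metrics and splits

Stratified 70/15/15 split by largest-remainder apportionment per class
(remainder ties go to the lowest split index), requiring ≥3 samples per
class. Reports use scikit-learn with `zero_division=0` plus an explicit
warning for never-predicted classes; one-vs-rest ROC AUC skips classes
absent from the evaluation labels and averages the defined ones.

## Determinism

Every random stream is derived from one master seed via
`child_seed(master, *names)` — SHA-256 of the name tuple reduced mod
2³¹−1 — so adding a stage never perturbs another stage's stream. All JSON
artifacts are written with sorted keys; two runs with the same seed are
byte-identical (tested end-to-end).

## Default problem sizes

The acceptance script and pipeline defaults (15 classes × 20 images at
256×256; blob tables of 3 classes × 200 samples in 10 dims) were chosen
so a full run completes in ~2 minutes on one core while leaving enough
test samples (45 images; 90 blob rows) for stable accuracy estimates.

## Limitations

- The surrogate backbone is untrained; its features are generic random
  projections, not disease-tuned embeddings.
- Segmentation assumes one leaf on a uniform dark background.
- The DNN head implementation favors clarity over speed (pure NumPy).
- LIME is tabular-only; it explains reduced feature coordinates, which
  after PCA are linear mixtures of the original descriptors.
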