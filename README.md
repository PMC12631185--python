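# leafstack

Hybrid machine-learning pipeline for plant-leaf disease classification:
handcrafted image descriptors fused with deep features, PCA reduction, and
stacked "classic learner + dense network" classifiers with LIME
explanations. The package ships a synthetic leaf-image generator so the
whole pipeline runs end-to-end, deterministically, with no external data.

## The science

Leaf diseases show up in images as changes of **color** (chlorosis,
browning), **texture** (lesion speckle, necrotic roughness) and **shape**
(deformation, tissue loss). The pipeline encodes each cue explicitly and
combines them with learned features:

1. **Handcrafted descriptors** (321 dims): 8-bin HSV and LAB channel
   histograms; four dominant RGB colors from k-means; a 256-bin local
   binary pattern (LBP, P=8, R=1) histogram; gray-level co-occurrence
   matrix (GLCM) contrast and angular second moment; and leaf area,
   perimeter and circularity from Otsu segmentation.
2. **Deep features** (64 dims by default) from a pluggable backbone and
   global average pooling. The default is a seeded random-convolution
   surrogate (three stride-2 conv layers), which is deterministic and
   dependency-free; any callable — e.g. a pretrained CNN — can be plugged
   in via `BackboneSpec(kind="external", external_fn=...)`.
3. **Fusion + reduction**: the two blocks are concatenated and reduced by
   PCA (eigendecomposition of the standardized covariance) to the smallest
   number of components retaining 95% of variance. Classes are first
   balanced by capping each class at 150 samples.
4. **Hybrid stacking**: a base learner (random forest, XGBoost, gradient
   boosting, k-NN, or logistic/softmax regression) produces
   **out-of-fold** class probabilities via stratified 5-fold
   cross-fitting; a small dense network (512→256→128→m, ReLU,
   dropout 0.3, softmax) is trained on those probabilities with Adam and
   early stopping. Out-of-fold stacking matters: in-sample probabilities
   from a strong base learner encode the training labels almost exactly,
   and a meta-learner trained on them overfits.
5. **Explanation**: a from-scratch tabular LIME perturbs an instance with
   Gaussian noise, weights neighbors by an exponential kernel on
   standardized distance, and fits weighted ridge regression to the
   predicted class probability. Reported *fidelity* is the kernel-weighted
   R² of that local surrogate.

Evaluation uses a stratified 70/15/15 split, per-class precision/recall/F1,
confusion matrices, and one-vs-rest ROC AUC.

## Worked example

Train a hybrid on a separable synthetic feature table
(`examples/04_hybrid_stacking.py`):

```python
from leafstack.hybrid_stack import BaseLearnerConfig, fit_hybrid, predict
from leafstack.synthgen import FeatureTableSpec, generate_feature_table

spec = FeatureTableSpec(n_per_class=200, n_classes=3, dim=10,
                        separation=6.0, seed=42)
X, y = generate_feature_table(spec)
# ... split into train/val/test (see the example script) ...
stack = fit_hybrid(BaseLearnerConfig("lr", seed=1),
                   X[tr], y[tr], X[va], y[va], seed=42)
labels, probs = predict(stack, X[te])
```

Output:

```
base learner: SoftmaxRegression
DNN head widths: [512, 256, 128, 3], dropout 0.3
trained for 39 epochs (early stopping on validation loss)

test accuracy: 1.000 on 90 samples
```

The image pipeline runs the same way from the CLI. Each stage is also
available as its own subcommand (`simulate`, `features`, `reduce`,
`train`, `evaluate`, `explain`):

```bash
leafstack run --seed 1 --out runs/demo --learner rf
```

On the default synthetic dataset (15 disease classes, 20 images each,
256×256), a full run with all five hybrids takes under two minutes and
produced, at seed 1:

| hybrid | test accuracy (n=45) | weighted F1 | macro AUC |
|--------|---------------------:|------------:|----------:|
| rf + DNN  | 97.8% | 0.977 | 1.000 |
| lr + DNN  | 93.3% | 0.927 | 1.000 |
| knn + DNN | 93.3% | 0.931 | 0.998 |
| xgb + DNN | 93.3% | 0.927 | 0.998 |
| gb + DNN  | 84.4% | 0.846 | 0.979 |

PCA kept 104 of 385 fused dimensions (95.05% of variance). On the
Gaussian-blob sanity checks the lr+DNN hybrid scored 100% on well-separated
classes and 25.6% (chance ≈ 33% ± sampling noise) at zero separation, and
LIME recovered a linear black box's weight signs and ranking exactly
(Spearman ρ = 1.0).

More narrative walkthroughs live in `examples/` (synthetic data,
handcrafted features, fusion + PCA, stacking, LIME) and the methods
write-up in `docs/methods.md`.

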