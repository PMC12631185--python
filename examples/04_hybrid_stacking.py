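"""Train an ML+DNN hybrid on a separable synthetic feature table.

The hybrid stacks a classic base learner (here logistic regression; rf,
xgb, gb and knn are also available) with a small dense network trained
on the base learner's out-of-fold class probabilities. Out-of-fold
stacking prevents the meta-learner from seeing in-sample probabilities,
which would leak the training labels.

Run:  python examples/04_hybrid_stacking.py
"""

import numpy as np

from leafstack.hybrid_stack import BaseLearnerConfig, fit_hybrid, predict
from leafstack.synthgen import FeatureTableSpec, generate_feature_table

spec = FeatureTableSpec(n_per_class=200, n_classes=3, dim=10, separation=6.0, seed=42)
X, y = generate_feature_table(spec)

rng = np.random.default_rng(42)
idx = rng.permutation(len(y))
tr, va, te = idx[:420], idx[420:510], idx[510:]

stack = fit_hybrid(
    BaseLearnerConfig("lr", seed=1),
    X[tr], y[tr], X[va], y[va], seed=42,
)
print(f"base learner: {stack.base.estimator.__class__.__name__}")
print(f"DNN head widths: {stack.head.layer_widths}, dropout {stack.head.dropout}")
print(f"trained for {len(stack.history['epoch'])} epochs "
      f"(early stopping on validation loss)")

labels, probs = predict(stack, X[te])
print(f"\ntest accuracy: {np.mean(labels == y[te]):.3f} on {len(te)} samples")
print("probability rows sum to", np.round(probs.sum(axis=1)[:3], 9))
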