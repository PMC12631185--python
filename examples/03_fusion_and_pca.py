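"""Fuse handcrafted + deep features and reduce them with PCA.

Deep features come from a seeded random-convolution surrogate backbone
(three stride-2 conv layers + global average pooling); any callable can
be plugged in instead via BackboneSpec(kind="external"). Fusion simply
concatenates the handcrafted block with the deep block, and PCA keeps
the smallest number of standardized principal components reaching the
requested variance fraction.

Run:  python examples/03_fusion_and_pca.py
"""

import numpy as np

from leafstack.deepfusion import BackboneSpec, deep_features, fuse_rows
from leafstack.handcrafted import HandcraftedParams, extract_handcrafted, resize_image
from leafstack.reduction import fit_pca, transform_pca
from leafstack.synthgen import default_class_specs, generate_leaf_image

specs = default_class_specs(n_classes=3)
params = HandcraftedParams()
backbone = BackboneSpec(kind="surrogate", seed=7, output_dim=64)

hand, deep = [], []
for ci, spec in enumerate(specs):
    for i in range(6):
        img = generate_leaf_image(spec, seed=100 * ci + i, side=256)
        hv = extract_handcrafted(img, params)
        hand.append(hv)
        # deep_features expects the backbone's input side (224 by default)
        deep.append(deep_features(resize_image(img, backbone.input_side), backbone))

fused = fuse_rows(hand, deep)
print(f"fused matrix: {fused.values.shape} "
      f"({fused.n_traditional} handcrafted + "
      f"{fused.values.shape[1] - fused.n_traditional} deep columns)")
print("first columns:", fused.column_names[:3], "...", fused.column_names[-2:])

model = fit_pca(fused.values, variance_threshold=0.95)
Z = transform_pca(model, fused.values)
print(f"\nPCA kept k={model.k} of {fused.values.shape[1]} dimensions, "
      f"retaining {model.retained_fraction:.1%} of variance")
print("eigenvalue spectrum head:", np.round(model.eigenvalues[:5], 2))
print("reduced shape:", Z.shape)
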