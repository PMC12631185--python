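"""Extract the handcrafted descriptor vector from one synthetic leaf.

The 321-dimensional vector concatenates six blocks:
  hsv (24)   8-bin histograms per HSV channel
  lab (24)   8-bin histograms per LAB channel
  dominant (12)  k=4 dominant RGB centroids via k-means
  lbp (256)  local binary pattern code histogram (P=8, R=1)
  glcm (2)   gray-level co-occurrence contrast and ASM
  shape (3)  leaf area, perimeter, circularity from Otsu segmentation

Run:  python examples/02_handcrafted_features.py
"""

import numpy as np

from leafstack.handcrafted import HandcraftedParams, extract_handcrafted
from leafstack.synthgen import default_class_specs, generate_leaf_image

spec = default_class_specs(n_classes=3)[0]
img = generate_leaf_image(spec, seed=5, side=256)

params = HandcraftedParams()  # side=224, 8 color bins, 8 GLCM levels
vec = extract_handcrafted(img, params)

print(f"feature vector length: {len(vec.values)}")
for name, sl in vec.blocks.items():
    block = vec.values[sl]
    print(f"  {name:9s} dim={sl.stop - sl.start:3d}  "
          f"min={block.min():8.3f}  max={block.max():8.3f}")

# Normalized histograms sum to one per channel.
hsv = vec.values[vec.blocks["hsv"]]
print("\nHSV channel masses:", np.round([hsv[i * 8:(i + 1) * 8].sum() for i in range(3)], 6))

area, perimeter, circularity = vec.values[vec.blocks["shape"]]
print(f"shape: area={area:.0f} px, perimeter={perimeter:.1f} px, "
      f"circularity={circularity:.3f} (1.0 = perfect disk)")
print("segmentation failed:", vec.segmentation_failed)
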