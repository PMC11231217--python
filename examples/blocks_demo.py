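"""Run the toy seven-dot image through the three building blocks.

Shows what each block does to a feature map: the MA block refines
features at constant spatial size, the FCN block fans out into three
activation branches (3x channels) before merging back, and the
attention gate produces a (0,1) mask that rescales the skip features.
"""

import numpy as np

from icnet import AttentionBlock, FCNBlock, MABlock, make_dots_image

image, mask = make_dots_image(7, image_size=64, seed=0)
x = image[None]  # (1, 64, 64, 3)
print(f"input image {x.shape}, {int(mask.max())} discs")

rng = np.random.default_rng(0)
ma = MABlock(3, 16, rng=rng)
y = ma(x)
print(f"MA block    -> {y.shape}  (conv-BN-ReLU-conv, spatial size preserved)")

fcn = FCNBlock(16, 16, rng=rng)
z = fcn(y)
print(f"FCN block   -> {z.shape}  (pre-merge width {fcn.intermediate_width()} = 3x filters)")

gate = AttentionBlock(16, 16, 16, rng=rng)
gated = gate(y, z)
m = gate.last_mask()
print(f"attention   -> {gated.shape}  mask in ({m.min():.3f}, {m.max():.3f})")
print("the mask rescales each skip pixel by its predicted relevance; "
      "values near 1 pass through, values near 0 are suppressed")
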