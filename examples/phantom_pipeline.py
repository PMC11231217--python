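"""Generate a multimodal tumor phantom and push it through preprocessing.

The phantom is an ellipsoidal brain with nested spherical tumor shells
(enhancing inside core inside whole tumor) in four MRI contrasts. The
pipeline maps BraTS label codes {0,1,2,4} to {0,1,2,3}, normalizes each
volume to [0,1], slices axially, and one-hot encodes the masks.
"""

import numpy as np

from icnet import PhantomSpec, batch_generator, extract_slices, make_tumor_phantom

spec = PhantomSpec(seed=0)
sample = make_tumor_phantom(spec)
labels = sample.labels
print(f"phantom volume {labels.shape}, modalities {sorted(sample.modalities)}")
for code, name in ((2, "edema"), (1, "necrotic core"), (4, "enhancing")):
    print(f"  label {code} ({name}): {int((labels == code).sum())} voxels")

et, tc = labels == 4, np.isin(labels, (1, 4))
wt = np.isin(labels, (1, 2, 4))
print(f"nesting ET⊆TC⊆WT exact: {bool(np.all(~et | tc) and np.all(~tc | wt))}")

slices = extract_slices(sample, target_size=(64, 64),
                        modalities=("flair", "t1ce"), drop_empty=True)
print(f"{len(slices)} tumor-bearing 64x64 slices (FLAIR + T1ce channels)")

xb, yb = next(iter(batch_generator(slices, batch_size=4, seed=0)))
print(f"one batch: images {xb.shape} in [{xb.min():.2f}, {xb.max():.2f}], "
      f"one-hot masks {yb.shape}, per-pixel sums all 1: "
      f"{bool(np.allclose(yb.sum(-1), 1.0))}")
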