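"""Generate a synthetic neuropil-like label volume and its raw-like image.

Builds the study's stand-in data: dense, space-filling 3D instances
separated by thin membrane-like walls, plus a degraded intensity volume.
"""

import numpy as np

from bootseg import SynthConfig, generate_synthetic_labels, simulate_raw

cfg = SynthConfig(shape=(64, 64, 64), instance_range=(8, 20), seed=7)
labels = generate_synthetic_labels(cfg)
raw = simulate_raw(labels, cfg)

sizes = np.bincount(labels.data.ravel())[1:]
print(f"volume {labels.shape}, voxel size {labels.voxel_size} nm")
print(f"instances: {labels.ids().size} "
      f"(sizes {sizes.min()}..{sizes.max()} voxels)")
print(f"foreground fraction: {(labels.data > 0).mean():.3f}")
print(f"raw intensity: membranes {raw.data[labels.data == 0].mean():.2f}, "
      f"interiors {raw.data[labels.data > 0].mean():.2f}")
# The instance count sits inside the configured range, most of the volume is
# foreground (walls are thin), and membranes are darker than cell interiors.
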