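"""Build the segmentation network and look at its structure.

The encoder follows ConvNeXt (4x4 stride-4 stem, four stages); a U-net++
style nested grid of custom batch-norm blocks decodes back to 1/4 resolution;
two transpose-conv stages with ConvNeXt blocks restore full resolution.
"""

import numpy as np

from rnadotseg.netarch import NetworkConfig, build_network
from rnadotseg.nn.autograd import Tensor

config = NetworkConfig(backbone_size="tiny", input_size=64, upscale_dropout=0.15)
model = build_network(config, seed=0).eval()

counts = model.parameter_counts()
print(f"parameters: total {counts['total']:,}, backbone {counts['backbone']:,}")

x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 64, 64)).astype(np.float32))
endpoints = model.backbone(x)
print("encoder endpoints (C, H):",
      [(e.shape[1], e.shape[2]) for e in endpoints],
      "= 1/4 .. 1/32 of input resolution")
print(f"nested decoder nodes: {len(model.decoder.nodes)} (U-net++ grid over 4 levels)")

out = model(x)
print(f"output: {out.shape}, values in [{out.data.min():.3f}, {out.data.max():.3f}]"
      " -> per-pixel dot probability")

model.freeze_backbone(True)
print("after freezing the backbone:", model.parameter_counts())
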