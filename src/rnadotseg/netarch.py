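"""Segmentation network: ConvNeXt encoder, nested (U-net++ style) decoder of
custom regularized upscaling blocks, and a two-stage 4x final upsampler.

The encoder follows the ConvNeXt design: a 4x4 stride-4 stem, then four
stages of residual blocks (7x7 depthwise convolution, channel layer
normalisation, 4x pointwise expansion with GELU, layer scale, stochastic
depth).  Because the stem already downsamples 4x, the densely nested decoder
grid operates only between 1/4 and 1/32 resolution; a final section of two
[transpose-conv 2x + 3 ConvNeXt blocks] stages brings the map back to full
resolution, ending in a 1-channel sigmoid head.

Decoder nodes use a custom variant of the ConvNeXt block in which layer
normalisation is swapped for batch normalisation, a second batch
normalisation sits on the skip path, DropOut (rather than DropPath) is
applied before the branch point, and a closing activation follows the
residual sum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from .nn.autograd import Tensor, concat
from .nn.layers import (
    Module, ModuleList, Conv2d, DepthwiseConv2d, ConvTranspose2x2,
    LayerNorm, BatchNorm2d, Dropout, DropPath, GELU, Sigmoid, LayerScale,
)

__all__ = [
    "BACKBONE_SPECS", "NetworkConfig", "ConvNeXtBlock", "UpscaleBlock",
    "Backbone", "NestedDecoder", "FinalSection", "DotSegNet",
    "build_network", "load_backbone_weights", "save_checkpoint", "load_checkpoint",
]

logger = logging.getLogger(__name__)

# depths and widths per stage; "tiny" is a reduced desk-scale preset for CPU
# experiments, not a published ConvNeXt size
BACKBONE_SPECS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "base": ((3, 3, 27, 3), (128, 256, 512, 1024)),
    "small": ((3, 3, 27, 3), (96, 192, 384, 768)),
    "tiny": ((2, 2, 4, 2), (32, 64, 128, 256)),
}


@dataclass
class NetworkConfig:
    backbone_size: str = "base"
    backbone_droppath: float = 0.0     # d, stochastic-depth rate in the encoder
    upscale_dropout: float = 0.15      # r, DropOut in the decoder blocks
    final_section_mode: str = "none"   # none | dropout | droppath
    final_section_rate: float = 0.0
    input_size: int = 224
    output_channels: int = 1

    def __post_init__(self):
        if self.backbone_size not in BACKBONE_SPECS:
            raise ValueError(f"unknown backbone size {self.backbone_size!r}; "
                             f"known: {sorted(BACKBONE_SPECS)}")
        for name in ("backbone_droppath", "upscale_dropout", "final_section_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.final_section_mode not in ("none", "dropout", "droppath"):
            raise ValueError(f"unknown final_section_mode {self.final_section_mode!r}")
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls(**json.loads(s))


class ConvNeXtBlock(Module):
    """Residual ConvNeXt block; deterministic when droppath_rate is 0.

    `ls_init` sets the layer-scale starting value: 1e-6 (the ConvNeXt
    convention) in the deep pretrainable encoder, 1.0 in the shallow
    from-scratch sections so their residual branches carry signal from the
    first step.
    """

    def __init__(self, width: int, droppath_rate: float, rng: np.random.Generator,
                 ls_init: float = 1e-6):
        super().__init__()
        self.dwconv = DepthwiseConv2d(width, 7, rng=rng)
        self.norm = LayerNorm(width)
        self.pw1 = Conv2d(width, 4 * width, 1, rng=rng)
        self.act = GELU()
        self.pw2 = Conv2d(4 * width, width, 1, rng=rng)
        self.scale = LayerScale(width, init=ls_init)
        self.droppath = DropPath(droppath_rate) if droppath_rate > 0 else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.pw2(self.act(self.pw1(self.norm(self.dwconv(x)))))
        h = self.scale(h)
        if self.droppath is not None:
            h = self.droppath(h)
        return x + h


class UpscaleBlock(Module):
    """Custom decoder block: batch norm in place of layer norm, a second batch
    norm on the skip path, DropOut before the branch point, and a closing
    activation after the residual sum."""

    def __init__(self, width: int, dropout_rate: float, rng: np.random.Generator):
        super().__init__()
        self.dropout = Dropout(dropout_rate) if dropout_rate > 0 else None
        self.dwconv = DepthwiseConv2d(width, 7, rng=rng)
        self.norm = BatchNorm2d(width)
        self.pw1 = Conv2d(width, 4 * width, 1, rng=rng)
        self.act = GELU()
        self.pw2 = Conv2d(4 * width, width, 1, rng=rng)
        self.scale = LayerScale(width, init=1.0)
        self.skip_norm = BatchNorm2d(width)
        self.final_act = GELU()

    def forward(self, x: Tensor) -> Tensor:
        h = self.dropout(x) if self.dropout is not None else x
        main = self.scale(self.pw2(self.act(self.pw1(self.norm(self.dwconv(h))))))
        return self.final_act(main + self.skip_norm(h))


class Backbone(Module):
    """Stem + four ConvNeXt stages; emits endpoints at 1/4 .. 1/32 resolution.

    DropPath rates grow linearly with block depth up to the configured d,
    the stochastic-depth convention ConvNeXt uses.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        depths, widths = BACKBONE_SPECS[config.backbone_size]
        self.widths = widths
        self.stem_conv = Conv2d(3, widths[0], 4, stride=4, rng=rng)
        self.stem_norm = LayerNorm(widths[0])
        total = sum(depths)
        rates = np.linspace(0.0, config.backbone_droppath, total) if total > 1 \
            else np.zeros(1)
        self.stages = ModuleList()
        self.downsamples = ModuleList()
        k = 0
        for i, (d, w) in enumerate(zip(depths, widths)):
            stage = ModuleList()
            for _ in range(d):
                stage.append(ConvNeXtBlock(w, float(rates[k]), rng))
                k += 1
            self.stages.append(_Sequential(stage))
            if i < 3:
                self.downsamples.append(_Sequential(ModuleList([
                    LayerNorm(w), Conv2d(w, widths[i + 1], 2, stride=2, rng=rng)])))

    def forward(self, x: Tensor) -> list[Tensor]:
        h = self.stem_norm(self.stem_conv(x))
        endpoints = []
        for i, stage in enumerate(self.stages):
            h = stage(h)
            endpoints.append(h)
            if i < 3:
                h = self.downsamples[i](h)
        return endpoints


class _Sequential(Module):
    def __init__(self, mods: ModuleList):
        super().__init__()
        self.mods = mods

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class _DecoderNode(Module):
    """One nested-decoder node: upsample the lower-level input, concatenate all
    same-level predecessors, project to the level width, one custom block."""

    def __init__(self, level_width: int, lower_width: int, n_same_level: int,
                 dropout_rate: float, rng: np.random.Generator):
        super().__init__()
        self.up = ConvTranspose2x2(lower_width, level_width, rng=rng)
        self.proj = Conv2d((n_same_level + 1) * level_width, level_width, 1, rng=rng)
        self.block = UpscaleBlock(level_width, dropout_rate, rng)

    def forward(self, same_level: list[Tensor], lower: Tensor) -> Tensor:
        cat = concat(same_level + [self.up(lower)], axis=1)
        return self.block(self.proj(cat))


class NestedDecoder(Module):
    """U-net++ node grid over the four encoder levels below the stem.

    Nodes X[i][j] (level i, column j >= 1, i + j <= 3) take all same-level
    predecessors X[i][0..j-1] plus the upsampled X[i+1][j-1]; the output is
    X[0][3] at 1/4 of input resolution.  Four levels give six such nodes.
    """

    def __init__(self, widths: tuple[int, ...], dropout_rate: float,
                 rng: np.random.Generator):
        super().__init__()
        self.nodes = ModuleList()
        self._index: dict[tuple[int, int], int] = {}
        for j in range(1, 4):
            for i in range(0, 4 - j):
                self._index[(i, j)] = len(self.nodes)
                self.nodes.append(_DecoderNode(widths[i], widths[i + 1], j,
                                               dropout_rate, rng))

    def forward(self, endpoints: list[Tensor]) -> Tensor:
        if len(endpoints) != 4:
            raise ValueError(f"expected 4 encoder endpoints, got {len(endpoints)}")
        for a, b in zip(endpoints, endpoints[1:]):
            if (a.shape[2] != 2 * b.shape[2]) or (a.shape[3] != 2 * b.shape[3]):
                raise ValueError("endpoint resolutions must halve level to level")
        X: dict[tuple[int, int], Tensor] = {(i, 0): e for i, e in enumerate(endpoints)}
        for j in range(1, 4):
            for i in range(0, 4 - j):
                node = self.nodes[self._index[(i, j)]]
                X[(i, j)] = node([X[(i, k)] for k in range(j)], X[(i + 1, j - 1)])
        return X[(0, 3)]


class FinalSection(Module):
    """Two [stride-2 transpose conv + 3 ConvNeXt blocks] stages, then a
    1-channel 1x1 projection with sigmoid.  Output head bias starts at -4,
    the prior log-odds of the rare positive (dot) class."""

    def __init__(self, in_width: int, config: NetworkConfig,
                 rng: np.random.Generator):
        super().__init__()
        mode, rate = config.final_section_mode, config.final_section_rate
        dp = rate if mode == "droppath" else 0.0
        w1, w2 = max(in_width // 2, 8), max(in_width // 4, 8)
        self.up1 = ConvTranspose2x2(in_width, w1, rng=rng)
        self.blocks1 = ModuleList([ConvNeXtBlock(w1, dp, rng, ls_init=1.0)
                                   for _ in range(3)])
        self.up2 = ConvTranspose2x2(w1, w2, rng=rng)
        self.blocks2 = ModuleList([ConvNeXtBlock(w2, dp, rng, ls_init=1.0)
                                   for _ in range(3)])
        if mode == "dropout" and rate > 0:
            self.drops1 = ModuleList([Dropout(rate) for _ in range(3)])
            self.drops2 = ModuleList([Dropout(rate) for _ in range(3)])
        else:
            self.drops1 = self.drops2 = None
        self.head = Conv2d(w2, config.output_channels, 1, rng=rng, bias_init=-4.0)
        self.out_act = Sigmoid()

    def _run(self, x, up, blocks, drops):
        x = up(x)
        for k, b in enumerate(blocks):
            x = b(x)
            if drops is not None:
                x = drops[k](x)
        return x

    def forward(self, x: Tensor) -> Tensor:
        x = self._run(x, self.up1, self.blocks1, self.drops1)
        x = self._run(x, self.up2, self.blocks2, self.drops2)
        return self.out_act(self.head(x))


class DotSegNet(Module):
    """Full network: H x W x 3 in, H x W x 1 segmentation probabilities out."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = Backbone(config, rng)
        self.decoder = NestedDecoder(self.backbone.widths, config.upscale_dropout, rng)
        self.final = FinalSection(self.backbone.widths[0], config, rng)
        self._backbone_frozen = False

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size {x.shape[2:]} not divisible by 32")
        return self.final(self.decoder(self.backbone(x)))

    # -- backbone freezing ------------------------------------------------

    def freeze_backbone(self, frozen: bool = True) -> "DotSegNet":
        for p in self.backbone.parameters():
            p.trainable = not frozen
        self._backbone_frozen = frozen
        return self

    @property
    def backbone_frozen(self) -> bool:
        return self._backbone_frozen

    def parameter_counts(self) -> dict[str, int]:
        bb = sum(p.data.size for p in self.backbone.parameters())
        total = sum(p.data.size for p in self.parameters())
        trainable = sum(p.data.size for p in self.parameters()
                        if getattr(p, "trainable", True))
        return {"backbone": bb, "total": total, "trainable": trainable,
                "non_trainable": total - trainable}


def build_network(config: NetworkConfig, seed: int = 0) -> DotSegNet:
    return DotSegNet(config, seed=seed)


def load_backbone_weights(model: DotSegNet, weights_source=None) -> DotSegNet:
    """Replace backbone parameters from a checkpoint dict or .npz path.

    With no source the model keeps its random initialisation (a notice is
    logged); non-backbone parameters are never touched.  A shape mismatch
    raises before any parameter is modified.
    """
    if weights_source is None:
        logger.warning("no backbone weights supplied; keeping random initialisation")
        return model
    if isinstance(weights_source, (str, bytes)) or hasattr(weights_source, "__fspath__"):
        with np.load(weights_source) as npz:
            weights = {k: npz[k] for k in npz.files}
    else:
        weights = dict(weights_source)
    weights = {k.removeprefix("backbone."): v for k, v in weights.items()}
    params = dict(model.backbone.named_parameters())
    for k, p in params.items():
        if k not in weights:
            raise KeyError(f"backbone weights missing tensor '{k}'")
        if p.data.shape != weights[k].shape:
            raise ValueError(f"shape mismatch for backbone tensor '{k}': "
                             f"model {p.data.shape} vs source {weights[k].shape}")
    for k, p in params.items():
        p.data = np.asarray(weights[k], dtype=p.data.dtype).copy()
    return model


def save_checkpoint(model: DotSegNet, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> DotSegNet:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    config = NetworkConfig.from_json(state.pop("__config__").tobytes().decode())
    model = DotSegNet(config)
    model.load_state_dict(state)
    return model
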