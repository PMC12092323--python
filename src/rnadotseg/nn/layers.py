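"""Neural-network layers built on the autograd core.

The inventory is intentionally small: exactly the layers the dot-segmentation
network is assembled from.  Modules follow the familiar container pattern —
``parameters()``, ``train()``/``eval()``, ``state_dict()`` — so the trainer
and checkpoints stay framework-agnostic.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor
from . import ops

__all__ = [
    "Module", "ModuleList", "Conv2d", "DepthwiseConv2d", "ConvTranspose2x2",
    "LayerNorm", "BatchNorm2d", "Dropout", "DropPath", "GELU", "Sigmoid",
    "LayerScale",
]


DTYPE = np.float32  # parameter/activation precision of the network


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +/-2 std, the ConvNeXt initialisation."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(DTYPE)


class Module:
    def __init__(self):
        self.training = True

    # recursive traversal over attributes and ModuleLists
    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield f"{name}.{i}", m

    def modules(self):
        yield self
        for _, c in self._children():
            yield from c.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, c in self._children():
            yield from c.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, c in self._children():
            yield from c.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def set_rng(self, rng: np.random.Generator):
        """Attach one generator to every stochastic layer (dropout/droppath)."""
        for m in self.modules():
            if isinstance(m, (Dropout, DropPath)):
                m.rng = rng
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for k, p in params.items():
            if p.data.shape != d[k].shape:
                raise ValueError(f"shape mismatch for '{k}': "
                                 f"model {p.data.shape} vs checkpoint {d[k].shape}")
        for k, p in params.items():
            p.data = d[k].copy()
        for k, _ in self.named_buffers():
            self._set_buffer(k, d[k].copy())
        return self

    def _set_buffer(self, dotted: str, value: np.ndarray):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value)

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class ModuleList(list):
    pass


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 bias_init: float = 0.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = Parameter(trunc_normal(rng, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.full(out_ch, bias_init, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, ch: int, kernel: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.pad = kernel // 2
        self.weight = Parameter(trunc_normal(rng, (ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(ch, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ops.depthwise_conv2d(x, self.weight, self.bias, self.pad)


class ConvTranspose2x2(Module):
    """Stride-2, kernel-2 transpose convolution: exact 2x spatial upsampling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(trunc_normal(rng, (in_ch, out_ch, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv_transpose2x2(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalisation over the channel axis of NCHW maps (ConvNeXt style)."""

    def __init__(self, ch: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(ch, dtype=DTYPE))
        self.beta = Parameter(np.zeros(ch, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xhat = xc * (var + self.eps) ** (-0.5)
        C = self.gamma.data.shape[0]
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.01):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch, dtype=DTYPE))
        self.beta = Parameter(np.zeros(ch, dtype=DTYPE))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)

    def named_buffers(self, prefix: str = ""):
        yield prefix + "running_mean", self.running_mean
        yield prefix + "running_var", self.running_var

    def forward(self, x: Tensor) -> Tensor:
        C = self.gamma.data.shape[0]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += (self.momentum * (mu.data.ravel() - self.running_mean)).astype(DTYPE)
            self.running_var += (self.momentum * (var.data.ravel() - self.running_var)).astype(DTYPE)
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
            xc = x - mu
        xhat = xc * (var + self.eps) ** (-0.5)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class Dropout(Module):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = float(rate)
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        rng = self.rng or np.random.default_rng(0)
        keep = 1.0 - self.rate
        mask = ((rng.random(x.data.shape) < keep) / keep).astype(x.data.dtype)
        return x * Tensor(mask)


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = float(rate)
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        rng = self.rng or np.random.default_rng(0)
        keep = 1.0 - self.rate
        n = x.data.shape[0]
        mask = ((rng.random((n,) + (1,) * (x.data.ndim - 1)) < keep) / keep).astype(x.data.dtype)
        return x * Tensor(mask)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class LayerScale(Module):
    """Per-channel learnable scaling of the residual branch (gamma init 1e-6)."""

    def __init__(self, ch: int, init: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.full(ch, init, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        C = self.gamma.data.shape[0]
        return x * self.gamma.reshape(1, C, 1, 1)
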