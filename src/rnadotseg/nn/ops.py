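"""Convolution primitives with hand-written gradients.

All tensors are NCHW.  Pointwise (1x1) convolutions reduce to a single
matmul; depthwise convolutions use shifted elementwise multiply-adds over the
kernel support, which vectorises far better in numpy than strided window
views; general strided convolutions (the stem and downsample layers) go
through ``sliding_window_view`` + ``tensordot``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = ["conv2d", "depthwise_conv2d", "conv_transpose2x2"]


def _node(data, prev, backward):
    needs = any(p.requires_grad or p._prev for p in prev)
    out = Tensor(data, _prev=prev if needs else ())
    if needs:
        out._backward = backward
    return out


def _conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    O = w.data.shape[0]
    wm = w.data.reshape(O, C)
    xf = x.data.reshape(N, C, H * W)
    out = np.einsum("oc,ncp->nop", wm, xf, optimize=True).reshape(N, O, H, W)
    out += b.data[None, :, None, None]

    def backward(g):
        gf = g.reshape(N, O, H * W)
        if w.requires_grad:
            gw = np.einsum("nop,ncp->oc", gf, xf, optimize=True)
            w._accumulate(gw.reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gx = np.einsum("oc,nop->ncp", wm, gf, optimize=True)
            x._accumulate(gx.reshape(N, C, H, W))

    return _node(out, (x, w, b), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; w has shape (O, C, kh, kw), b shape (O,)."""
    O, C, kh, kw = w.data.shape
    if kh == kw == 1 and stride == 1 and pad == 0:
        return _conv1x1(x, w, b)

    _, _, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # N,OH,OW,O
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    out += b.data[None, :, None, None]
    OH, OW = out.shape[2], out.shape[3]

    def backward(g):
        if w.requires_grad:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # O,C,kh,kw
            w._accumulate(gw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gxp = np.zeros((g.shape[0], C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    # g: N,O,OH,OW ; w[:,:,i,j]: O,C
                    gxp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += \
                        np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j],
                                  optimize=True)
            gx = gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp
            x._accumulate(gx)

    return _node(out, (x, w, b), backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Per-channel (grouped, groups=C) convolution; w shape (C, kh, kw)."""
    N, C, H, W = x.data.shape
    _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    out = np.empty((N, C, H, W), dtype=x.data.dtype)
    out[:] = b.data[None, :, None, None]
    for i in range(kh):
        for j in range(kw):
            out += xp[:, :, i:i + H, j:j + W] * w.data[None, :, i, j, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, i, j] = (g * xp[:, :, i:i + H, j:j + W]).sum(axis=(0, 2, 3))
            w._accumulate(gw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + H, j:j + W] += g * w.data[None, :, i, j, None, None]
            gx = gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp
            x._accumulate(gx)

    return _node(out, (x, w, b), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transpose convolution, kernel 2x2 and stride 2 (exact 2x upsampling).

    w has shape (C, O, 2, 2); each input pixel expands into a 2x2 output block,
    so blocks do not overlap and the op is a pure reshape of an einsum.
    """
    N, C, H, W = x.data.shape
    _, O, _, _ = w.data.shape
    t = np.einsum("nchw,coab->nohawb", x.data, w.data, optimize=True)
    out = np.ascontiguousarray(t).reshape(N, O, 2 * H, 2 * W)
    out += b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(N, O, H, 2, W, 2)
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nohawb->coab", x.data, g6, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            x._accumulate(np.einsum("nohawb,coab->nchw", g6, w.data, optimize=True))

    return _node(out, (x, w, b), backward)
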