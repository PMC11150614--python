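"""Structured differentiable ops: convolution, pooling, resampling, norms.

Convolution is implemented with an im2col/col2im pair so both the
forward pass and the weight/input gradients reduce to single matrix
products, which is the only way a pure-numpy network trains at a usable
speed on one CPU core.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "avg_pool2d",
    "upsample_bilinear",
    "layer_norm",
    "batch_norm_train",
    "pad_reflect",
]


def _window_view(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Strided (N,C,Ho,Wo,kh,kw) view of the (padded) input; no copy."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return view[:, :, ::stride, ::stride]


def _conv1x1(x: Tensor, weight: Tensor, bias, stride: int):
    """Fast path: a 1x1 convolution is a per-pixel channel matmul."""
    w2 = weight.data.reshape(weight.data.shape[0], weight.data.shape[1])
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    out = np.tensordot(w2, xs, axes=(1, 1)).transpose(1, 0, 2, 3)
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dxs = np.tensordot(w2.T, g, axes=(1, 1)).transpose(1, 0, 2, 3)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
            else:
                dx = dxs
            x._accumulate(dx)

    return Tensor._make(np.ascontiguousarray(out), parents, bwd)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. ``x``: (N,C,H,W); ``weight``: (O,C,kh,kw)."""
    o, c, kh, kw = weight.data.shape
    if kh == 1 and kw == 1 and padding == 0:
        return _conv1x1(x, weight, bias, stride)
    view = _window_view(x.data, kh, kw, stride, padding)
    # out[n,o,i,j] = sum_{c,u,v} w[o,c,u,v] * view[n,c,i,j,u,v]
    out = np.tensordot(weight.data, view,
                       axes=([1, 2, 3], [1, 4, 5])).transpose(1, 0, 2, 3)
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.tensordot(g, view, axes=([0, 2, 3], [0, 2, 3]))
            weight._accumulate(dw)
        if x.requires_grad:
            # input gradient = transposed convolution: dilate g by the
            # stride, pad by (k-1-p), correlate with the 180-degree
            # rotated kernel with in/out channels swapped
            n, _, ho, wo = g.shape
            h, w = x.data.shape[2], x.data.shape[3]
            if stride > 1:
                gd = np.zeros((n, o, (ho - 1) * stride + 1,
                               (wo - 1) * stride + 1), dtype=np.float32)
                gd[:, :, ::stride, ::stride] = g
            else:
                gd = g
            ph, pw = kh - 1 - padding, kw - 1 - padding
            # dilated map may still be short of the input size on the
            # far edge; pad asymmetrically to compensate
            extra_h = h - (gd.shape[2] + 2 * ph - kh + 1)
            extra_w = w - (gd.shape[3] + 2 * pw - kw + 1)
            gd = np.pad(gd, ((0, 0), (0, 0), (ph, ph + extra_h), (pw, pw + extra_w)))
            wrot = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gview = np.lib.stride_tricks.sliding_window_view(gd, (kh, kw), axis=(2, 3))
            dx = np.tensordot(wrot, gview,
                              axes=([1, 2, 3], [1, 4, 5])).transpose(1, 0, 2, 3)
            x._accumulate(np.ascontiguousarray(dx))

    return Tensor._make(np.ascontiguousarray(out), parents, bwd)


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping mean pooling; spatial dims must divide ``factor``."""
    n, c, h, w = x.data.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {h}x{w} not divisible by pool factor {factor}")
    ho, wo = h // factor, w // factor
    out = x.data.reshape(n, c, ho, factor, wo, factor).mean(axis=(3, 5))
    inv = 1.0 / (factor * factor)

    def bwd(g):
        if x.requires_grad:
            gexp = np.broadcast_to(
                g[:, :, :, None, :, None], (n, c, ho, factor, wo, factor))
            x._accumulate((gexp * inv).reshape(n, c, h, w))

    return Tensor._make(out, (x,), bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centres)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling to (out_h, out_w); exact for constant fields."""
    n, c, h, w = x.data.shape
    ah = _interp_matrix(out_h, h)
    aw = _interp_matrix(out_w, w)
    out = np.matmul(np.matmul(ah, x.data), aw.T)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(ah.T, g), aw))

    return Tensor._make(out, (x,), bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then apply the affine pair."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    out = xhat * gamma.data + beta.data

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate((dxhat - m1 - xhat * m2) / std)

    return Tensor._make(out, (x, gamma, beta), bwd)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalisation over (N,H,W) per channel, training statistics.

    Returns ``(out, batch_mean, batch_var)``; the caller owns the running
    averages.
    """
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    gb = gamma.data.reshape(1, -1, 1, 1)
    out = xhat * gb + beta.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gb
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accumulate((dxhat - m1 - xhat * m2) / std)

    out_t = Tensor._make(out, (x, gamma, beta), bwd)
    return out_t, mu.reshape(-1), var.reshape(-1)


def pad_reflect(x: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Reflect-pad trailing spatial dims of an (…,H,W) array up to target."""
    h, w = x.shape[-2], x.shape[-1]
    ph, pw = target_h - h, target_w - w
    if ph < 0 or pw < 0:
        raise ValueError("target smaller than input")
    if ph == 0 and pw == 0:
        return x
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad, mode="reflect")
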