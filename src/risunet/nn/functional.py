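"""Structured 2D ops (convolution, pooling, batch norm) with custom adjoints.

All feature maps are NCHW float64.  Convolutions are stride-1 with "same"
zero padding (the only variant the architecture uses); the 2x stride
transposed convolution used for decoder upsampling has a 2x2 kernel, so its
output patches do not overlap and both passes reduce to einsums.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, make


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2D convolution (cross-correlation).

    ``x``: (N, Cin, H, W); ``weight``: (Cout, Cin, k, k), k odd;
    ``bias``: (Cout,) or None.  Output: (N, Cout, H, W).
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs kernel {cin_w}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # (N, Cin, H, W, kh, kw) view -> (N*H*W, Cin*kh*kw) matrix
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, cin * kh * kw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out_data = cols @ wmat.T
    if bias is not None:
        out_data += bias.data
    out_data = out_data.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = make(out_data, parents)
    if out.requires_grad:
        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
            if weight.requires_grad:
                weight.accumulate((gmat.T @ cols).reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias.accumulate(gmat.sum(axis=0))
            if x.requires_grad:
                dcols = (gmat @ wmat).reshape(n, h, w, cin, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                x.accumulate(dxp[:, :, ph:ph + h, pw:pw + w])
        out._backward = backward
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2-kernel, stride-2 transposed convolution (exact 2x upsampling).

    ``x``: (N, Cin, H, W); ``weight``: (Cin, Cout, 2, 2).
    Output: (N, Cout, 2H, 2W); patches are disjoint.
    """
    n, cin, h, w = x.shape
    cin_w, cout, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs kernel {cin_w}")
    out_data = np.einsum("nchw,cokl->nohkwl", x.data, weight.data, optimize=True)
    out_data = out_data.reshape(n, cout, h * kh, w * kw)
    if bias is not None:
        out_data += bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = make(out_data, parents)
    if out.requires_grad:
        def backward(g):
            g6 = g.reshape(n, cout, h, kh, w, kw)
            if x.requires_grad:
                x.accumulate(np.einsum("nohkwl,cokl->nchw", g6, weight.data, optimize=True))
            if weight.requires_grad:
                weight.accumulate(np.einsum("nchw,nohkwl->cokl", x.data, g6, optimize=True))
            if bias is not None and bias.requires_grad:
                bias.accumulate(g.sum(axis=(0, 2, 3)))
        out._backward = backward
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d needs even spatial dims, got {(h, w)}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    out = make(out_data, (x,))
    if out.requires_grad:
        def backward(g):
            dxr = np.zeros((n, c, h // 2, w // 2, 4))
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x.accumulate(dx.reshape(n, c, h, w))
        out._backward = backward
    return out


def max_pool3x3_same(x: Tensor) -> Tensor:
    """3x3 max pooling, stride 1, same padding (resolution preserved)."""
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    win = sliding_window_view(xp, (3, 3), axis=(2, 3)).reshape(n, c, h, w, 9)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    out = make(out_data, (x,))
    if out.requires_grad:
        def backward(g):
            di, dj = idx // 3, idx % 3
            ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            rows = ii[None, None] + di  # positions in the padded array
            cols = jj[None, None] + dj
            nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            nn = nn[:, :, None, None]
            cc = cc[:, :, None, None]
            dxp = np.zeros((n, c, h + 2, w + 2))
            np.add.at(dxp, (nn, cc, rows, cols), g)
            x.accumulate(dxp[:, :, 1:1 + h, 1:1 + w])
        out._backward = backward
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map: ``x`` (N, Cin) @ ``weight``.T (Cin, Cout) + ``bias``."""
    out_data = x.data @ weight.data.T
    if bias is not None:
        out_data = out_data + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = make(out_data, parents)
    if out.requires_grad:
        def backward(g):
            if x.requires_grad:
                x.accumulate(g @ weight.data)
            if weight.requires_grad:
                weight.accumulate(g.T @ x.data)
            if bias is not None and bias.requires_grad:
                bias.accumulate(g.sum(axis=0))
        out._backward = backward
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode the batch statistics are used and the running buffers
    are updated in place (unbiased variance, exponential moving average).
    In eval mode the running buffers are used, making the op elementwise.
    """
    n, c, h, w = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    out = make(out_data, (x, gamma, beta))
    if out.requires_grad:
        def backward(g):
            if gamma.requires_grad:
                gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta.accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                scale = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
                if training:
                    m = n * h * w
                    g_mean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                    gx_mean = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                    x.accumulate(scale * (g - g_mean - xhat * gx_mean))
                else:
                    x.accumulate(scale * g)
        out._backward = backward
    return out
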