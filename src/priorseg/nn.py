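"""Minimal deterministic NumPy backend for small 3D convolutional networks.

Everything runs in float32 on the CPU. Convolutions are expressed as
im2col + matrix multiplication so the heavy lifting is a single BLAS GEMM;
gradients for the input of a stride-1 'same' convolution are themselves a
convolution with the kernel flipped and the channel axes swapped, so the
same code path serves forward and backward. No operation uses threading
or nondeterministic reductions: identical inputs, weights and seeds give
bit-identical results.

Tensors are channel-first: ``(C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*27) patch matrix for a 3x3x3 'same' conv."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C,D,H,W,3,3,3)
    c = x.shape[0]
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(-1, c * 27)


def conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 'same' 3D convolution. ``w``: (Cout, Cin, 3, 3, 3)."""
    cout = w.shape[0]
    out = _im2col(x) @ w.reshape(cout, -1).T
    if b is not None:
        out += b
    d, h, wd = x.shape[1:]
    return np.ascontiguousarray(out.reshape(d, h, wd, cout).transpose(3, 0, 1, 2))


def conv3x3_backward(x, w, dout):
    """Gradients of conv3x3 w.r.t. (x, w, b)."""
    cout = w.shape[0]
    dout_mat = dout.transpose(1, 2, 3, 0).reshape(-1, cout)
    dw = (dout_mat.T @ _im2col(x)).reshape(w.shape)
    db = dout.sum(axis=(1, 2, 3))
    # input gradient: convolve dout with spatially flipped, channel-swapped kernel
    w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    dx = conv3x3(dout, w_t)
    return dx, dw, db


def conv1x1(x, w, b=None):
    """Pointwise convolution. ``w``: (Cout, Cin)."""
    c = x.shape[0]
    out = w @ x.reshape(c, -1)
    if b is not None:
        out += b[:, None]
    return out.reshape((w.shape[0],) + x.shape[1:])


def conv1x1_backward(x, w, dout):
    c, cout = x.shape[0], w.shape[0]
    dw = dout.reshape(cout, -1) @ x.reshape(c, -1).T
    db = dout.sum(axis=(1, 2, 3))
    dx = (w.T @ dout.reshape(cout, -1)).reshape(x.shape)
    return dx, dw, db


def maxpool(x, factors):
    """Block max-pool by per-axis ``factors``; returns (out, argmax cache)."""
    c, d, h, w = x.shape
    f0, f1, f2 = factors
    xr = (
        x.reshape(c, d // f0, f0, h // f1, f1, w // f2, f2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, d // f0, h // f1, w // f2, f0 * f1 * f2)
    )
    idx = xr.argmax(-1)
    out = np.take_along_axis(xr, idx[..., None], -1)[..., 0]
    return out, idx


def maxpool_backward(dout, idx, factors):
    f0, f1, f2 = factors
    c, d2, h2, w2 = dout.shape
    g = np.zeros(dout.shape + (f0 * f1 * f2,), dtype=dout.dtype)
    np.put_along_axis(g, idx[..., None], dout[..., None], -1)
    return (
        g.reshape(c, d2, h2, w2, f0, f1, f2)
        .transpose(0, 1, 4, 2, 5, 3, 6)
        .reshape(c, d2 * f0, h2 * f1, w2 * f2)
    )


def upsample(x, factors):
    """Nearest-neighbor upsampling by per-axis integer factors."""
    out = x
    for ax, f in zip((1, 2, 3), factors):
        if f > 1:
            out = np.repeat(out, f, axis=ax)
    return out


def upsample_backward(dout, factors):
    c = dout.shape[0]
    f0, f1, f2 = factors
    d, h, w = (s // f for s, f in zip(dout.shape[1:], factors))
    return (
        dout.reshape(c, d, f0, h, f1, w, f2).sum(axis=(2, 4, 6)).astype(dout.dtype)
    )


def instance_norm(x, gamma, beta, eps: float = 1e-5):
    """Per-channel normalization over the spatial axes.

    Keeps activations O(1) at every depth, which protects the sigmoid
    head from saturating — with a pure Dice loss a saturated head has no
    usable gradient. Returns (out, cache) for the backward pass.
    """
    mean = x.mean(axis=(1, 2, 3), keepdims=True)
    var = x.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv
    out = gamma[:, None, None, None] * xhat + beta[:, None, None, None]
    return out.astype(np.float32), (xhat, inv, gamma)


def instance_norm_backward(dout, cache):
    xhat, inv, gamma = cache
    dgamma = (dout * xhat).sum(axis=(1, 2, 3))
    dbeta = dout.sum(axis=(1, 2, 3))
    dxhat = dout * gamma[:, None, None, None]
    m = dxhat.mean(axis=(1, 2, 3), keepdims=True)
    mx = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx.astype(np.float32), dgamma, dbeta


def leaky_relu(x, alpha: float = 0.1):
    """Leaky ReLU; the small negative slope avoids dead units in tiny nets."""
    return np.where(x > 0, x, alpha * x).astype(np.float32)


def leaky_relu_grad(pre, alpha: float = 0.1):
    """Derivative of leaky ReLU evaluated at the pre-activation."""
    return np.where(pre > 0, np.float32(1.0), np.float32(alpha))


def sigmoid(x):
    """Numerically stable sigmoid with output strictly inside (0, 1)."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos].astype(np.float64)))
    ex = np.exp(x[~pos].astype(np.float64))
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, 1e-12, 1.0 - 1e-12)


class Adam:
    """Adam with decoupled-from-schedule L2 weight decay added to gradients."""

    def __init__(self, params: dict, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k].astype(np.float32)
            if self.weight_decay and k.endswith(".w"):
                g = g + np.float32(self.weight_decay) * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= np.float32(lr) * mhat / (np.sqrt(vhat) + self.eps)
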