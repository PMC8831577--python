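"""Minimal CPU neural-network kernels for the reference slice segmenter.

Implements exactly what the tiny encoder-decoder needs — 3x3 same-padding
convolution, 2x2 max pooling, nearest-neighbour upsampling, sigmoid, the
soft Dice loss, and Adam — as float32 numpy with hand-written backward
passes.  Activations are kept channels-last (N, H, W, C) so the im2col
gather is a cheap concatenation and each convolution is one BLAS matmul,
which keeps a full training run on 64x64 slabs to a couple of minutes on
one core.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32

_OFFSETS = [(i, j) for i in range(3) for j in range(3)]


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution, channels-last.

    x: (N, H, W, C); w: (9*C, F) with rows ordered (kernel offset, channel);
    b: (F,).  Returns (y, xp) with y: (N, H, W, F) and the padded input kept
    for the backward pass.  Runs as 9 full-grid GEMMs with shift-accumulate,
    so every memory copy is a contiguous row segment.
    """
    n, h, wd, c = x.shape
    f = w.shape[1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    xf = xp.reshape(-1, c)
    w9 = w.reshape(9, c, f)
    y = np.empty((n, h, wd, f), dtype=F32)
    y[:] = b
    for idx, (i, j) in enumerate(_OFFSETS):
        full = (xf @ w9[idx]).reshape(n, h + 2, wd + 2, f)
        y += full[:, i : i + h, j : j + wd, :]
    return y, xp


def conv2d_backward(
    dy: np.ndarray, xp: np.ndarray, w: np.ndarray, x_shape, need_dx: bool = True
):
    """Gradients of :func:`conv2d_forward` w.r.t. weights, bias and input.

    ``need_dx=False`` (first layer) skips the input-gradient accumulation.
    """
    n, h, wd, c = x_shape
    f = w.shape[1]
    w9 = w.reshape(9, c, f)
    dyf = dy.reshape(-1, f)
    dw = np.empty((9, c, f), dtype=F32)
    dxp = np.zeros_like(xp) if need_dx else None
    xf = xp.reshape(-1, c)
    buf = np.zeros((n, h + 2, wd + 2, f), dtype=F32)
    for idx, (i, j) in enumerate(_OFFSETS):
        if need_dx:
            dxp[:, i : i + h, j : j + wd, :] += (dyf @ w9[idx].T).reshape(n, h, wd, c)
        buf[:, i : i + h, j : j + wd, :] = dy
        dw[idx] = xf.T @ buf.reshape(-1, f)
        buf[:, i : i + h, j : j + wd, :] = 0.0
    dx = dxp[:, 1:-1, 1:-1, :] if need_dx else None
    return dw.reshape(9 * c, f), dy.sum(axis=(0, 1, 2)), dx


def maxpool2_forward(x: np.ndarray):
    """2x2/stride-2 max pool; returns (y, x, y) pair needed for backward."""
    a = x[:, 0::2, 0::2]
    b = x[:, 0::2, 1::2]
    c = x[:, 1::2, 0::2]
    d = x[:, 1::2, 1::2]
    y = np.maximum(np.maximum(a, b), np.maximum(c, d))
    return y, (x, y)


def maxpool2_backward(dy: np.ndarray, cache):
    x, y = cache
    dx = np.zeros_like(x)
    # ties propagate to every maximal position; harmless for optimization
    for si, sj in ((0, 0), (0, 1), (1, 0), (1, 1)):
        view = x[:, si::2, sj::2]
        dx[:, si::2, sj::2] = (view == y) * dy
    return dx


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_dice_batch(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-6):
    """Mean soft Dice loss over a batch and its gradient w.r.t. pred.

    pred, truth: (N, H, W) with pred in [0, 1].  Per sample:
    loss = 1 - (2 Σ p t + eps) / (Σ p + Σ t + eps).
    """
    n = pred.shape[0]
    p = pred.reshape(n, -1)
    t = truth.reshape(n, -1).astype(F32)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom
    # d loss_n / d p_i = -(2 t_i denom - num) / denom^2
    grad = -(2.0 * t * denom[:, None] - num[:, None]) / (denom[:, None] ** 2)
    grad /= n  # mean over the batch
    return float(loss.mean()), grad.reshape(pred.shape).astype(F32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
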