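"""Minimal float32 CNN layers with manual backprop.

Just enough machinery for the row-scoring U-Net: 3x3 same-padded
convolution, a 1x3 stride-2 column-reducing convolution, ReLU, 2x2 max
pooling, nearest-neighbour x2 upsampling, and Adam. Arrays are
channels-first, (batch, channels, rows, cols); the convolution inner
loops run over the contiguous column axis so the numba-compiled kernels
vectorize, which is what lets the whole training protocol run on one CPU
core in a few minutes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32

_JIT = dict(fastmath=True, cache=True, nogil=True)


# ---------------------------------------------------------------- 3x3, s1, p1


@njit(**_JIT)
def _c3_fwd(xp, W, b, y):
    # xp (B,Ci,H+2,W+2), W (Co,Ci,3,3), y (B,Co,H,Wd)
    B, Co, H, Wd = y.shape
    Ci = xp.shape[1]
    for bb in range(B):
        for co in range(Co):
            for h in range(H):
                row = y[bb, co, h]
                row[:] = b[co]
                for ci in range(Ci):
                    for i in range(3):
                        xrow = xp[bb, ci, h + i]
                        w0 = W[co, ci, i, 0]
                        w1 = W[co, ci, i, 1]
                        w2 = W[co, ci, i, 2]
                        for w in range(Wd):
                            row[w] += w0 * xrow[w] + w1 * xrow[w + 1] + w2 * xrow[w + 2]


# The input gradient of a 3x3/s1/p1 convolution is itself such a
# convolution of the (padded) output gradient with the spatially flipped,
# channel-transposed kernel, so _c3_fwd doubles as the dx kernel; the
# gather form vectorizes where a scatter would not.


@njit(**_JIT)
def _c3_dw(xp, dy, dW, db):
    B, Co, H, Wd = dy.shape
    Ci = xp.shape[1]
    dW[:] = 0.0
    db[:] = 0.0
    for bb in range(B):
        for co in range(Co):
            for h in range(H):
                dyrow = dy[bb, co, h]
                s = F32(0.0)
                for w in range(Wd):
                    s += dyrow[w]
                db[co] += s
                for ci in range(Ci):
                    for i in range(3):
                        xrow = xp[bb, ci, h + i]
                        for j in range(3):
                            acc = F32(0.0)
                            for w in range(Wd):
                                acc += xrow[w + j] * dyrow[w]
                            dW[co, ci, i, j] += acc


# ----------------------------------------------------- 1x3, column stride 2


@njit(**_JIT)
def _r3_fwd(xp, W, b, y):
    # xp (B,Ci,H,Wd+2) width-padded, W (Co,Ci,3), y (B,Co,H,Wo); Wo = Wd//2
    B, Co, H, Wo = y.shape
    Ci = xp.shape[1]
    for bb in range(B):
        for co in range(Co):
            for h in range(H):
                row = y[bb, co, h]
                row[:] = b[co]
                for ci in range(Ci):
                    xrow = xp[bb, ci, h]
                    w0 = W[co, ci, 0]
                    w1 = W[co, ci, 1]
                    w2 = W[co, ci, 2]
                    for w in range(Wo):
                        p = 2 * w
                        row[w] += w0 * xrow[p] + w1 * xrow[p + 1] + w2 * xrow[p + 2]


@njit(**_JIT)
def _r3_dx(dy, W, dxp):
    B, Co, H, Wo = dy.shape
    Ci = dxp.shape[1]
    for bb in range(B):
        for ci in range(Ci):
            for h in range(H):
                xrow = dxp[bb, ci, h]
                for co in range(Co):
                    dyrow = dy[bb, co, h]
                    w0 = W[co, ci, 0]
                    w1 = W[co, ci, 1]
                    w2 = W[co, ci, 2]
                    for w in range(Wo):
                        p = 2 * w
                        d = dyrow[w]
                        xrow[p] += w0 * d
                        xrow[p + 1] += w1 * d
                        xrow[p + 2] += w2 * d


@njit(**_JIT)
def _r3_dw(xp, dy, dW, db):
    B, Co, H, Wo = dy.shape
    Ci = xp.shape[1]
    dW[:] = 0.0
    db[:] = 0.0
    for bb in range(B):
        for co in range(Co):
            for h in range(H):
                dyrow = dy[bb, co, h]
                s = F32(0.0)
                for w in range(Wo):
                    s += dyrow[w]
                db[co] += s
                for ci in range(Ci):
                    xrow = xp[bb, ci, h]
                    a0 = F32(0.0)
                    a1 = F32(0.0)
                    a2 = F32(0.0)
                    for w in range(Wo):
                        p = 2 * w
                        d = dyrow[w]
                        a0 += xrow[p] * d
                        a1 += xrow[p + 1] * d
                        a2 += xrow[p + 2] * d
                    dW[co, ci, 0] += a0
                    dW[co, ci, 1] += a1
                    dW[co, ci, 2] += a2


# ----------------------------------------------------------------- layers


class Conv3x3:
    """3x3 convolution, stride 1, same padding; weights (c_out, c_in, 3, 3).

    ``input_layer=True`` skips the input gradient, which the first layer
    of a network never needs.
    """

    def __init__(self, c_in, c_out, *, rng, input_layer=False):
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, 3, 3)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.input_layer = input_layer
        self._xp = None

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])

    def forward(self, x):
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        y = np.empty((B, self.W.shape[0], H, W), dtype=F32)
        _c3_fwd(xp, self.W, self.b, y)
        self._xp = xp
        return y

    def backward(self, dy):
        xp = self._xp
        self.dW = np.empty_like(self.W)
        self.db = np.empty_like(self.b)
        _c3_dw(xp, dy, self.dW, self.db)
        self._xp = None
        if self.input_layer:
            return None
        Wt = np.ascontiguousarray(self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dx = np.empty((dy.shape[0], Wt.shape[0]) + dy.shape[2:], dtype=F32)
        _c3_fwd(dyp, Wt, np.zeros(Wt.shape[0], dtype=F32), dx)
        return dx


class ConvRow3Stride2:
    """1x3 convolution with column stride 2 and width padding 1.

    Halves the number of columns; the width-collapsing head stacks these
    until the residual width is projected away. Weights (c_out, c_in, 3).
    """

    def __init__(self, c_in, c_out, *, rng):
        std = np.sqrt(2.0 / (c_in * 3))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, 3)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self._xp = None

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])

    def forward(self, x):
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (1, 1)))
        y = np.empty((B, self.W.shape[0], H, W // 2), dtype=F32)
        _r3_fwd(xp, self.W, self.b, y)
        self._xp = xp
        return y

    def backward(self, dy):
        xp = self._xp
        self.dW = np.empty_like(self.W)
        self.db = np.empty_like(self.b)
        _r3_dw(xp, dy, self.dW, self.db)
        dxp = np.zeros_like(xp)
        _r3_dx(dy, self.W, dxp)
        self._xp = None
        return dxp[:, :, :, 1:-1]


class RowProjection:
    """Collapse the residual width: per row, a dense map (c_in x width) -> 1 logit."""

    def __init__(self, c_in, width, *, rng, bias_init=0.0):
        std = np.sqrt(2.0 / (c_in * width))
        self.W = rng.normal(0.0, std, size=(c_in, width)).astype(F32)
        self.b = np.full(1, bias_init, dtype=F32)
        self._x = None

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])

    def forward(self, x):
        # x (B,C,H,w) -> logits (B,H)
        self._x = x
        return np.tensordot(x, self.W, axes=([1, 3], [0, 1])) + self.b[0]

    def backward(self, dz):
        # dz (B,H)
        x = self._x
        self.dW = np.einsum("bchw,bh->cw", x, dz).astype(F32)
        self.db = np.array([dz.sum()], dtype=F32)
        dx = dz[:, None, :, None] * self.W[None, :, None, :]
        self._x = None
        return dx.astype(F32)


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        out = np.maximum(x, F32(0.0), out=x)  # we own the conv output
        self._out = out
        return out

    def backward(self, dy):
        dy = dy * (self._out > 0)
        self._out = None
        return dy


class MaxPool2:
    """2x2 max pooling.

    The backward mask routes gradient to every block entry equal to the
    block maximum; exact positive-valued ties are measure-zero with
    float activations, and tied zeros are killed by the preceding ReLU's
    own gradient mask.
    """

    params: list = []
    grads: list = []

    def forward(self, x):
        B, C, H, W = x.shape
        # stepwise single-axis reductions keep the reads contiguous
        rows = np.maximum(x[:, :, 0::2, :], x[:, :, 1::2, :])
        y = np.maximum(rows[:, :, :, 0::2], rows[:, :, :, 1::2])
        self._x, self._y = x, y
        return y

    def backward(self, dy):
        x, y = self._x, self._y
        B, C, H, W = x.shape
        yb = y.repeat(2, axis=2).repeat(2, axis=3)
        dyb = dy.repeat(2, axis=2).repeat(2, axis=3)
        dx = np.where(x == yb, dyb, F32(0.0))
        self._x = self._y = None
        return dx


class Upsample2:
    """Nearest-neighbour x2 in both spatial axes."""

    params: list = []
    grads: list = []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        rows = dy[:, :, 0::2, :] + dy[:, :, 1::2, :]
        return rows[:, :, :, 0::2] + rows[:, :, :, 1::2]


# ------------------------------------------------------------- loss & optim


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy over all entries; returns (loss, dloss/dz)."""
    # softplus(z) - y*z in numerically stable form
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z.astype(np.float64)) - y) / z.size
    return float(loss), dz.astype(F32)


class Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
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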