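"""Minimal CPU neural-network primitives used by the U-Net.

Implements exactly the operations the segmentation network needs — 3x3
"same"-padded convolution, 1x1 convolution, 2x2 max pooling, 2x2 stride-2
transposed convolution, ReLU, sigmoid, binary cross-entropy on logits, and
the Adam optimizer — with explicit forward/backward passes on numpy arrays.

Convolutions are evaluated as nine shifted BLAS matmuls rather than an
im2col buffer: on a single CPU core this avoids the large memory-bound
column copy and runs close to GEMM speed.

All tensors are NCHW. Parameters default to float32; float64 is supported
(used by the numerical-gradient tests).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3x3",
    "Conv1x1",
    "MaxPool2x2",
    "ConvTranspose2x2",
    "ReLU",
    "sigmoid",
    "bce_with_logits",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv3x3:
    """3x3 convolution, stride 1, zero ("same") padding, preserves H and W."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(_he_init(rng, (out_ch, in_ch, 3, 3), in_ch * 9, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._xp = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        out = np.zeros((n, self.out_ch, h * w), dtype=x.dtype)
        W = self.w.value
        for ky in range(3):
            for kx in range(3):
                xs = xp[:, :, ky:ky + h, kx:kx + w].reshape(n, c, h * w)
                # (out_ch, in_ch) @ (n, in_ch, HW) -> (n, out_ch, HW)
                out += np.matmul(W[:, :, ky, kx], xs)
        out += self.b.value[None, :, None]
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, c = xp.shape[0], self.in_ch
        h, w = dout.shape[2], dout.shape[3]
        do = dout.reshape(n, self.out_ch, h * w)
        self.b.grad += do.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        W = self.w.value
        dW = self.w.grad
        for ky in range(3):
            for kx in range(3):
                xs = xp[:, :, ky:ky + h, kx:kx + w].reshape(n, c, h * w)
                # dW: sum_n (out_ch, HW) @ (HW, in_ch)
                dW[:, :, ky, kx] += np.einsum(
                    "nfp,ncp->fc", do, xs, optimize=True)
                # dx: (in_ch, out_ch) @ (n, out_ch, HW)
                dxs = np.matmul(W[:, :, ky, kx].T, do)
                dxp[:, :, ky:ky + h, kx:kx + w] += dxs.reshape(n, c, h, w)
        self._xp = None
        return dxp[:, :, 1:-1, 1:-1]


class Conv1x1:
    """1x1 convolution (per-pixel linear map across channels)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(_he_init(rng, (out_ch, in_ch), in_ch, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        out = np.matmul(self.w.value, x.reshape(n, c, h * w))
        out += self.b.value[None, :, None]
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        do = dout.reshape(n, self.out_ch, h * w)
        xr = x.reshape(n, c, h * w)
        self.b.grad += do.sum(axis=(0, 2))
        self.w.grad += np.einsum("nfp,ncp->fc", do, xr, optimize=True)
        dx = np.matmul(self.w.value.T, do)
        self._x = None
        return dx.reshape(n, c, h, w)


class MaxPool2x2:
    """2x2 max pooling with stride 2; requires even spatial dimensions."""

    params: list = []

    def __init__(self):
        self._argmax = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool input must have even H, W; got {h}x{w}")
        xb = x.reshape(n, c, h // 2, 2, w // 2, 2)
        blocks = xb.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = blocks.argmax(axis=-1)
        self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, self._argmax[..., None], dout[..., None],
                          axis=-1)
        dx = dblocks.reshape(n, c, h // 2, w // 2, 2, 2)
        dx = dx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        self._argmax = None
        return dx


class ConvTranspose2x2:
    """Learned 2x upsampling: transposed convolution, 2x2 kernel, stride 2.

    Each input pixel emits a 2x2 output block, so output is exactly twice
    the input size in both dimensions — the inverse of the 2x2 pooling step.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        Wr = self.w.value.reshape(c, self.out_ch * 4)
        # (n, HW, C) @ (C, F*4) -> (n, HW, F*4)
        t = np.matmul(x.reshape(n, c, h * w).transpose(0, 2, 1), Wr)
        t = t.reshape(n, h, w, self.out_ch, 2, 2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_ch, 2 * h, 2 * w)
        out += self.b.value[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dt = dout.reshape(n, self.out_ch, h, 2, w, 2)
        dt = dt.transpose(0, 2, 4, 1, 3, 5).reshape(n, h * w, self.out_ch * 4)
        xr = x.reshape(n, c, h * w)
        self.w.grad += np.einsum("ncp,npk->ck", xr, dt,
                                 optimize=True).reshape(self.w.value.shape)
        Wr = self.w.value.reshape(c, self.out_ch * 4)
        dx = np.matmul(dt, Wr.T).transpose(0, 2, 1).reshape(n, c, h, w)
        self._x = None
        return np.ascontiguousarray(dx)


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, dout.dtype.type(0))
        self._mask = None
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits.

    Returns (loss, dloss/dz). Uses the log1p(exp(-|z|)) form so large
    logits never overflow; the gradient is sigmoid(z) - y, scaled by 1/N.
    """
    n = z.size
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / n
    return loss, dz


class Adam:
    """Adam optimizer over a flat list of Params."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
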