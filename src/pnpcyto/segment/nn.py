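"""Minimal CPU neural-network building blocks (numpy, float32).

Just enough machinery for a small encoder-decoder segmentation network:
3x3 convolution (zero padding, stride 1), ReLU, 2x2 max pooling,
nearest-neighbor upsampling, a 1x1 sigmoid head and a soft-Dice loss,
optimized with Adam.  Activations use a channel-first ``(C, N, H, W)``
layout: the convolution runs as nine shifted GEMMs ``(F, C) @ (C, N*H*W)``
whose slice copies stay row-contiguous, which keeps the hot loop inside
BLAS and the copies near memcpy speed on a single core.  All layers
implement an explicit backward pass; gradients are exact (verified against
the adjoint identity in the test suite).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

#: Magnitudes below this are flushed to zero in gradients and optimizer
#: state: they are numerically irrelevant but drive float32 arithmetic into
#: the subnormal range, where every operation takes a microcode assist and
#: late-training epochs slow down severalfold.
_TINY = np.float32(1e-30)


def flush_subnormals(a: np.ndarray) -> np.ndarray:
    """Zero entries with magnitude below the float32 subnormal guard."""
    a[np.abs(a) < _TINY] = 0.0
    return a


class Param:
    """A learnable tensor with its gradient and Adam state."""

    __slots__ = ("data", "grad", "m", "v")

    def __init__(self, data: np.ndarray):
        self.data = data.astype(np.float32)
        self.grad = np.zeros_like(self.data)
        self.m = np.zeros_like(self.data)
        self.v = np.zeros_like(self.data)


try:
    from ._kernels import conv3x3 as _nb_conv3x3
    from ._kernels import conv3x3_grad_w as _nb_conv3x3_grad_w

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving).

    Weights are ``(3, 3, F, C)``: one ``(F, C)`` mixing matrix per tap.
    The hot path is a direct single-threaded numba kernel; a pure-numpy
    GEMM path (``backend="numpy"``) computes the same map and serves as
    the reference in tests.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 backend: str = "numba"):
        scale = np.sqrt(2.0 / (in_ch * 9))
        self.W = Param(rng.normal(0.0, scale, (3, 3, out_ch, in_ch)))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch
        self.backend = backend if _HAVE_NUMBA else "numpy"
        self._xp: Optional[np.ndarray] = None

    @property
    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (0, 0), (1, 1), (1, 1)))
        y = np.empty((self.out_ch, n, h, w), dtype=np.float32)
        if self.backend == "numba":
            _nb_conv3x3(xp, self.W.data, self.b.data, y)
        else:
            yf = y.reshape(self.out_ch, -1)
            yf[:] = self.b.data[:, None]
            for di in range(3):
                for dj in range(3):
                    xs = np.ascontiguousarray(xp[:, :, di : di + h, dj : dj + w])
                    yf += self.W.data[di, dj] @ xs.reshape(c, -1)
        self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        c = self.in_ch
        _, n, h, w = dy.shape
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dx = np.empty((c, n, h, w), dtype=np.float32)
        # input gradient = correlation of padded dy with the flipped kernel
        w_flip = np.ascontiguousarray(self.W.data[::-1, ::-1].transpose(0, 1, 3, 2))
        if self.backend == "numba":
            _nb_conv3x3(dyp, w_flip, np.zeros(c, dtype=np.float32), dx)
            _nb_conv3x3_grad_w(xp, dy, self.W.grad, self.b.grad)
        else:
            dxf = dx.reshape(c, -1)
            dxf[:] = 0.0
            dyf = dy.reshape(self.out_ch, -1)
            for di in range(3):
                for dj in range(3):
                    ds = np.ascontiguousarray(dyp[:, :, di : di + h, dj : dj + w])
                    dxf += w_flip[di, dj] @ ds.reshape(self.out_ch, -1)
                    xs = np.ascontiguousarray(xp[:, :, di : di + h, dj : dj + w])
                    self.W.grad[di, dj] += dyf @ xs.reshape(c, -1).T
            self.b.grad += dyf.sum(axis=1)
        self._xp = None
        return dx


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))


class MaxPool2:
    """2x2 max pooling; spatial dims must be even.  Gradient routes to the
    first maximal element of each window (deterministic tie-break)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a = x[:, :, 0::2, 0::2]
        b = x[:, :, 0::2, 1::2]
        c = x[:, :, 1::2, 0::2]
        d = x[:, :, 1::2, 1::2]
        m = np.maximum(np.maximum(a, b), np.maximum(c, d))
        self._m = m
        return m

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, m = self._x, self._m
        dx = np.zeros_like(x)
        remaining = np.ones(dy.shape, dtype=bool)
        for di in (0, 1):
            for dj in (0, 1):
                sl = (slice(None), slice(None), slice(di, None, 2), slice(dj, None, 2))
                hit = (x[sl] == m) & remaining
                dx[sl] = np.where(hit, dy, np.float32(0.0))
                remaining &= ~hit
        self._x = self._m = None
        return dx


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h2, w2 = dy.shape
        return dy.reshape(c, n, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Conv1x1:
    """1x1 convolution head."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_ch)
        self.W = Param(rng.normal(0.0, scale, (out_ch, in_ch)))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    @property
    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        c = x.shape[0]
        y = self.W.data @ x.reshape(c, -1) + self.b.data[:, None]
        return y.reshape((self.out_ch,) + x.shape[1:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(self.in_ch, -1)
        dyf = np.ascontiguousarray(dy).reshape(self.out_ch, -1)
        self.W.grad += dyf @ xf.T
        self.b.grad += dyf.sum(axis=1)
        self._x = None
        return (self.W.data.T @ dyf).reshape(x.shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_dice_loss(
    p: np.ndarray, target: np.ndarray, smooth: float = 1.0
) -> Tuple[float, np.ndarray]:
    """Mean soft-Dice loss over the batch and its gradient w.r.t. ``p``.

    ``p`` and ``target`` are ``(N, H, W)``; the loss is
    ``1 - mean_i (2*sum(p_i t_i) + s) / (sum(p_i) + sum(t_i) + s)``.
    """
    n = p.shape[0]
    pf = p.reshape(n, -1).astype(np.float64)
    tf = target.reshape(n, -1).astype(np.float64)
    inter = (pf * tf).sum(axis=1)
    denom = pf.sum(axis=1) + tf.sum(axis=1) + smooth
    dice = (2.0 * inter + smooth) / denom
    loss = float(1.0 - dice.mean())
    ddice_dp = (2.0 * tf * denom[:, None] - (2.0 * inter + smooth)[:, None]) / (
        denom[:, None] ** 2
    )
    grad = (-ddice_dp / n).reshape(p.shape).astype(np.float32)
    return loss, grad


def hard_dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A|+|B|) of two boolean masks (1.0 if both empty)."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p in self.params:
            flush_subnormals(p.grad)
            p.m = flush_subnormals(b1 * p.m + (1 - b1) * p.grad)
            p.v = flush_subnormals(b2 * p.v + (1 - b2) * p.grad**2)
            p.data -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)
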