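"""Numba JIT kernels for the 3x3 convolution (single-threaded).

Direct convolution over ``(C, N, H, W)`` activations: no im2col buffers,
so the working set stays in cache and a single CPU core sustains the
arithmetic.  ``conv3x3`` computes ``y[f] = b[f] + sum_c W[.,.,f,c] * x[c]``
on inputs pre-padded by one pixel; the same kernel evaluates the input
gradient when handed the spatially flipped, transposed kernel.  The three
horizontal taps are fused into one vectorizable pass per input row.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def conv3x3(xp, w, b, y):  # pragma: no cover - exercised via Conv3x3
    """xp: (C, N, H+2, W+2); w: (3, 3, F, C); b: (F,); y: (F, N, H, W)."""
    c_in, n_batch = xp.shape[0], xp.shape[1]
    n_out, h, wd = y.shape[0], y.shape[2], y.shape[3]
    tmp = np.empty(wd, np.float32)
    for n in range(n_batch):
        for f in range(n_out):
            for i in range(h):
                for j in range(wd):
                    tmp[j] = b[f]
                for c in range(c_in):
                    for di in range(3):
                        xrow = xp[c, n, i + di]
                        w0 = w[di, 0, f, c]
                        w1 = w[di, 1, f, c]
                        w2 = w[di, 2, f, c]
                        for j in range(wd):
                            tmp[j] += w0 * xrow[j] + w1 * xrow[j + 1] + w2 * xrow[j + 2]
                y[f, n, i, :] = tmp


@njit(fastmath=True, cache=True)
def conv3x3_grad_w(xp, dy, dw, db):  # pragma: no cover
    """Accumulate weight/bias gradients: dw (3, 3, F, C), db (F,)."""
    c_in, n_batch = xp.shape[0], xp.shape[1]
    n_out, h, wd = dy.shape[0], dy.shape[2], dy.shape[3]
    for f in range(n_out):
        acc_b = np.float32(0.0)
        for n in range(n_batch):
            for i in range(h):
                dyrow = dy[f, n, i]
                for j in range(wd):
                    acc_b += dyrow[j]
                for c in range(c_in):
                    for di in range(3):
                        xrow = xp[c, n, i + di]
                        a0 = np.float32(0.0)
                        a1 = np.float32(0.0)
                        a2 = np.float32(0.0)
                        for j in range(wd):
                            d = dyrow[j]
                            a0 += d * xrow[j]
                            a1 += d * xrow[j + 1]
                            a2 += d * xrow[j + 2]
                        dw[di, 0, f, c] += a0
                        dw[di, 1, f, c] += a1
                        dw[di, 2, f, c] += a2
        db[f] += acc_b
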