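"""A small encoder-decoder ("U") segmentation network in pure numpy.

Sized to train on a single CPU core in minutes at 82x82 crops: by default
3 resolution levels with two 3x3 convolutions per block and a doubling
channel ladder (~30k parameters at base 8).  Inputs of arbitrary size are
reflect-padded to a multiple of the pooling factor and the output cropped
back.  Activations are ``(C, N, H, W)`` internally (see ``nn``); the public
interface takes and returns ``(N, H, W)`` arrays.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .nn import (Conv1x1, Conv3x3, MaxPool2, Param, ReLU, Upsample2,
                 flush_subnormals, sigmoid)


class _Block:
    """Two 3x3 conv + ReLU pairs."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1, self.r1 = Conv3x3(in_ch, out_ch, rng), ReLU()
        self.c2, self.r2 = Conv3x3(out_ch, out_ch, rng), ReLU()

    @property
    def params(self) -> List[Param]:
        return self.c1.params + self.c2.params

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class UNet:
    """Encoder-decoder with skip connections and a sigmoid pixel head."""

    def __init__(self, levels: int = 3, base_channels: int = 8, in_channels: int = 1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.factor = 2 ** (levels - 1)
        self.chans = [base_channels * 2**i for i in range(levels)]
        self.enc: List[_Block] = []
        c_in = in_channels
        for c in self.chans[:-1]:
            self.enc.append(_Block(c_in, c, rng))
            c_in = c
        self.bottleneck = _Block(c_in, self.chans[-1], rng)
        self.dec: List[_Block] = []
        c_in = self.chans[-1]
        for c in reversed(self.chans[:-1]):
            self.dec.append(_Block(c_in + c, c, rng))
            c_in = c
        self.head = Conv1x1(c_in, 1, rng)
        self.pool = [MaxPool2() for _ in range(levels - 1)]
        self.up = [Upsample2() for _ in range(levels - 1)]

    @property
    def params(self) -> List[Param]:
        out: List[Param] = []
        for b in self.enc:
            out += b.params
        out += self.bottleneck.params
        for b in self.dec:
            out += b.params
        out += self.head.params
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def _pad(self, x: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
        h, w = x.shape[2:4]
        ph = (-h) % self.factor
        pw = (-w) % self.factor
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability map ``(N, H, W)`` for a batch ``(N, H, W[, C_in])``."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]  # (N, H, W) -> (C=1, N, H, W)
        x, self._hw = self._pad(x)
        skips = []
        for blk, pool in zip(self.enc, self.pool):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for blk, up, skip in zip(self.dec, self.up, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = blk.forward(x)
        z = self.head.forward(x)
        self._p_full = sigmoid(z[0])
        h, w = self._hw
        return self._p_full[:, :h, :w]

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate the gradient w.r.t. the (cropped) probability map."""
        h, w = self._hw
        dp_full = np.zeros_like(self._p_full)
        dp_full[:, :h, :w] = dp
        dz = (dp_full * self._p_full * (1.0 - self._p_full)).astype(np.float32)
        flush_subnormals(dz)
        dx = self.head.backward(dz[None])
        dskips = []
        for blk, up, n_skip in zip(
            reversed(self.dec), reversed(self.up), reversed(self._skip_channels)
        ):
            dcat = blk.backward(dx)
            dskips.append(dcat[:n_skip])
            dx = up.backward(np.ascontiguousarray(dcat[n_skip:]))
        # dskips were collected shallowest-last; deepest encoder goes first
        dx = self.bottleneck.backward(dx)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pool), reversed(dskips)
        ):
            dx = blk.backward(pool.backward(dx) + dskip)

    def predict(self, crops: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Probability maps for ``(N, H, W)`` crops, batched inference."""
        crops = np.asarray(crops, dtype=np.float32)
        squeeze = crops.ndim == 2
        if squeeze:
            crops = crops[None]
        out = np.empty(crops.shape[:3], dtype=np.float32)
        for i in range(0, len(crops), batch_size):
            out[i : i + batch_size] = self.forward(crops[i : i + batch_size])
        return out[0] if squeeze else out

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state_dict(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data[...] = np.asarray(s, dtype=np.float32)
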