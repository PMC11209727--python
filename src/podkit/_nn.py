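"""Minimal numpy neural-network primitives for the desk-scale trainer.

Implements exactly what the toy pod detector needs — 2-D convolution
(arbitrary stride/dilation, NHWC layout) with hand-written backward passes,
ReLU, sigmoid, and Adam — using BLAS matmuls over kernel-offset slices, so a
small multi-branch detector trains in minutes on one CPU.  This is not a
general autograd: layers cache their inputs and are wired explicitly by the
model in :mod:`podkit.model`.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv2d:
    """NHWC convolution; weight layout (k, k, C_in, C_out)."""

    def __init__(
        self,
        k: int,
        c_in: int,
        c_out: int,
        stride: int = 1,
        pad: int = 0,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * c_in
        self.W = (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
                  .astype(DTYPE))
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.k, self.stride, self.pad, self.dilation = k, stride, pad, dilation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        span = self.dilation * (self.k - 1) + 1
        return (
            (h + 2 * self.pad - span) // self.stride + 1,
            (w + 2 * self.pad - span) // self.stride + 1,
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, _ = x.shape
        p, s, d = self.pad, self.stride, self.dilation
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        Ho, Wo = self.out_hw(H, W)
        out = np.tile(self.b, (B, Ho, Wo, 1)).astype(DTYPE)
        for ky in range(self.k):
            for kx in range(self.k):
                xs = xp[:, ky * d: ky * d + s * (Ho - 1) + 1: s,
                        kx * d: kx * d + s * (Wo - 1) + 1: s, :]
                out += xs @ self.W[ky, kx]
        self._xp = xp
        self._in_hw = (H, W)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "forward before backward"
        B, Ho, Wo, _ = dout.shape
        p, s, d = self.pad, self.stride, self.dilation
        dxp = np.zeros_like(xp)
        self.db[:] = dout.sum(axis=(0, 1, 2))
        flat_dout = dout.reshape(-1, dout.shape[-1])
        for ky in range(self.k):
            for kx in range(self.k):
                ysl = slice(ky * d, ky * d + s * (Ho - 1) + 1, s)
                xsl = slice(kx * d, kx * d + s * (Wo - 1) + 1, s)
                xs = xp[:, ysl, xsl, :]
                self.dW[ky, kx] = xs.reshape(-1, xs.shape[-1]).T @ flat_dout
                dxp[:, ysl, xsl, :] += dout @ self.W[ky, kx].T
        H, W = self._in_hw
        return dxp[:, p: p + H, p: p + W, :] if p else dxp

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 3e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
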