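"""Minimal numpy neural-network primitives for the feature extractor.

Convolutions are evaluated as a sum of nine offset GEMMs (one per 3x3 tap),
which keeps memory linear in the activation size and routes all heavy work
through BLAS.  Layers operate on single images laid out (H, W, C) in
float32, store what their backward pass needs, and expose ``params()`` /
``grads()`` for the Adam optimizer.  Everything is deterministic given the
seed used to initialize the weights and order the training data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv", "ReLU", "MaxPool2", "MaxPool2Same", "Adam"]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv(Layer):
    """k x k convolution, stride 1, same padding, He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, ksize: int = 3):
        self.cin, self.cout, self.ksize = cin, cout, ksize
        scale = np.sqrt(2.0 / (ksize * ksize * cin))
        self.W = (rng.standard_normal((ksize, ksize, cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w, _ = x.shape
        k = self.ksize
        if k == 1:
            xp = x
        else:
            p = k // 2
            xp = np.pad(x, ((p, p), (p, p), (0, 0)))
        self._xp = xp if train else None
        out = np.empty((h * w, self.cout), dtype=np.float32)
        out[:] = self.b
        for di in range(k):
            for dj in range(k):
                patch = xp[di : di + h, dj : dj + w].reshape(h * w, self.cin)
                out += patch @ self.W[di, dj]
        return out.reshape(h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called without a stored forward pass")
        h, w, _ = dout.shape
        k = self.ksize
        dflat = dout.reshape(h * w, self.cout)
        self.db[:] = dflat.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for di in range(k):
            for dj in range(k):
                patch = self._xp[di : di + h, dj : dj + w].reshape(h * w, self.cin)
                self.dW[di, dj] = patch.T @ dflat
                dxp[di : di + h, dj : dj + w] += (dflat @ self.W[di, dj].T).reshape(
                    h, w, self.cin
                )
        self._xp = None
        if k == 1:
            return dxp
        p = k // 2
        return dxp[p : h + p, p : w + p]

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a stored forward pass")
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (requires even spatial dims)."""

    stride = 2

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims {h}x{w} must be even for stride-2 pooling")
        xr = x.reshape(h // 2, 2, w // 2, 2, c).transpose(0, 2, 4, 1, 3).reshape(
            h // 2, w // 2, c, 4
        )
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._idx is None or self._shape is None:
            raise RuntimeError("backward called without a stored forward pass")
        h, w, c = self._shape
        dxr = np.zeros((h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=3)
        dx = dxr.reshape(h // 2, w // 2, c, 2, 2).transpose(0, 3, 1, 4, 2).reshape(h, w, c)
        self._idx = None
        return dx


class MaxPool2Same(Layer):
    """2x2 max pooling, stride 1, same padding (output size = input size)."""

    stride = 1

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @staticmethod
    def _candidates(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        xp = np.full((h + 1, w + 1, c), -np.inf, dtype=x.dtype)
        xp[:h, :w] = x
        return np.stack(
            [xp[:h, :w], xp[:h, 1 : w + 1], xp[1 : h + 1, :w], xp[1 : h + 1, 1 : w + 1]]
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cand = self._candidates(x)
        idx = cand.argmax(axis=0)
        out = np.take_along_axis(cand, idx[None], axis=0)[0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._idx is None or self._shape is None:
            raise RuntimeError("backward called without a stored forward pass")
        h, w, c = self._shape
        dxp = np.zeros((h + 1, w + 1, c), dtype=dout.dtype)
        offsets = ((0, 0), (0, 1), (1, 0), (1, 1))
        for k, (oy, ox) in enumerate(offsets):
            contrib = np.where(self._idx == k, dout, 0.0)
            dxp[oy : oy + h, ox : ox + w] += contrib
        self._idx = None
        return dxp[:h, :w]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        scale = np.float32(self.lr / bias1)
        vscale = np.float32(1.0 / np.sqrt(bias2))
        eps = np.float32(self.eps)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += np.float32(1 - b1) * g
            v *= b2
            v += np.float32(1 - b2) * np.square(g)
            denom = np.sqrt(v)
            denom *= vscale
            denom += eps
            update = m / denom
            update *= scale
            p -= update
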