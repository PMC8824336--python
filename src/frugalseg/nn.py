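"""Minimal NumPy building blocks for convolutional encoder-decoder networks.

Layers keep their forward caches on the instance, so a layer object belongs
to exactly one position in a network and one in-flight forward/backward pair.
All activations are float32 arrays of shape ``(N, H, W, C)`` (channels last).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Concat",
    "softmax",
    "softmax_backward",
    "Adam",
]


class Conv2D:
    """2-D convolution with 'same' zero padding and odd kernel size.

    He-normal initialisation; weights stored as ``(k, k, c_in, c_out)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, *,
                 rng: np.random.Generator) -> None:
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        scale = np.sqrt(2.0 / (kernel_size * kernel_size * c_in))
        self.W = rng.normal(0.0, scale,
                            size=(kernel_size, kernel_size, c_in, c_out)
                            ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = x.shape
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        else:
            xp = x
        self._xp = xp
        out = np.empty((n, h, w, self.W.shape[3]), dtype=np.float32)
        out[:] = self.b
        # one matmul per kernel offset: (N*H*W, Cin) @ (Cin, Cout)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + h, j:j + w, :]
                out += patch @ self.W[i, j]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        xp = self._xp
        n, hp, wp, _ = xp.shape
        h, w = dout.shape[1], dout.shape[2]
        self.db[:] = dout.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        flat_dout = dout.reshape(-1, dout.shape[3])
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + h, j:j + w, :]
                self.dW[i, j] = patch.reshape(-1, patch.shape[3]).T @ flat_dout
                dxp[:, i:i + h, j:j + w, :] += dout @ self.W[i, j].T
        p = k // 2
        self._xp = None
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class InstanceNorm:
    """Per-sample, per-channel normalisation over the spatial axes.

    Keeps feature magnitudes bounded through the depth of the network so
    the softmax head does not saturate (the overlap-based losses have
    vanishing gradients through a saturated softmax).  Unlike batch
    normalisation it is independent of the batch composition and behaves
    identically at train and inference time.  Learnable per-channel gain
    and bias.
    """

    EPS = 1e-5

    def __init__(self, channels: int) -> None:
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.EPS)
        self._xhat = (x - mu) * self._inv
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.dgamma[:] = (dout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[:] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        mean_d = dxhat.mean(axis=(1, 2), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return self._inv * (dxhat - mean_d - xhat * mean_dx)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0.0))


class MaxPool2:
    """2x2 max pooling with stride 2; ties propagate gradient to all maxima."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._x = x
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x.shape
        up = np.repeat(np.repeat(self._out, 2, axis=1), 2, axis=2)
        mask = self._x == up
        dup = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
        return np.where(mask, dup, np.float32(0.0))


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Concat:
    """Channel concatenation of (skip, up) used at decoder stages."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[3]
        return np.concatenate([a, b], axis=3)

    def backward(self, dout: np.ndarray):
        s = self._split
        return dout[..., :s], dout[..., s:]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Gradient through a per-pixel softmax given d(loss)/d(probs)."""
    dot = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - dot)


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
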