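"""Minimal convolutional-network building blocks in numpy.

Layers cache what backward needs during forward, so a model is used as
``forward -> loss -> backward -> optimiser step``.  Everything is plain
float32/float64 numpy, which makes training fully deterministic under a
fixed RNG seed (no threading-dependent reductions at these sizes) and lets
saliency computations reuse the exact analytic gradients of the model.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; empty for parameter-free layers."""
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 same-padding convolution via im2col, stride 1, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 ksize: int = 3):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        # He initialisation, suited to the ReLU nonlinearity that follows
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, ksize, ksize)).astype(np.float64)
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None
        self.activation: np.ndarray | None = None  # filled by forward

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(
            xp, (self.k, self.k), axis=(2, 3)
        )  # (n, c, h, w, k, k)
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        out = out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)
        self._cols, self._xshape = cols, x.shape
        self.activation = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dout2d = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dW[...] = (dout2d.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dout2d.sum(axis=0)
        dcols = dout2d @ self.W.reshape(self.out_ch, -1)  # (nhw, c*k*k)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; even spatial dims required."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        arg = flat.argmax(axis=-1)
        self._onehot = np.eye(4, dtype=bool)[arg]  # first max wins on ties
        self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dflat = dout[..., None] * self._onehot
        dblocks = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dblocks.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        return np.broadcast_to(dout[:, :, None, None], self._xshape) / (h * w)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(targets)
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimiser over the (value, grad) pairs exposed by layers."""

    def __init__(self, params: list[tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (_, value, grad) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
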