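"""Minimal NumPy building blocks for small 3-D convolutional autoencoders.

The models in this package are deliberately tiny (two strided conv layers
per encoder, two transposed-conv layers in the decoder), so a hand-written
forward/backward pass over float32 arrays is both exact and fast enough for
CPU training.  Convolutions use kernel 2 / stride 2, i.e. non-overlapping
patches: the patch extraction is a pure reshape, which keeps gradients
trivially correct and avoids any im2col bookkeeping.

All layers share the same protocol: ``forward(x) -> (y, cache)`` and
``backward(grad_y, cache) -> grad_x`` with parameter gradients accumulated
into ``layer.grads`` (same keys as ``layer.params``).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {"W": glorot(rng, n_in, n_out, (n_in, n_out)),
                       "b": np.zeros(n_out, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, g, cache):
        x = cache
        self.grads["W"] += x.T @ g
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"].T


def _to_patches(x):
    """(B, D, H, W, C) -> (B, D/2, H/2, W/2, 8*C) by non-overlapping 2**3 blocks."""
    b, d, h, w, c = x.shape
    y = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
    y = y.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return np.ascontiguousarray(y).reshape(b, d // 2, h // 2, w // 2, 8 * c)

def _from_patches(y, c):
    """Inverse of :func:`_to_patches`."""
    b, d, h, w, _ = y.shape
    x = y.reshape(b, d, h, w, 2, 2, 2, c)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return np.ascontiguousarray(x).reshape(b, 2 * d, 2 * h, 2 * w, c)


class Conv2x2(Layer):
    """3-D convolution with kernel 2, stride 2 (halves every spatial axis)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {"W": glorot(rng, 8 * c_in, c_out, (8 * c_in, c_out)),
                       "b": np.zeros(c_out, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x):
        p = _to_patches(x)
        shape = p.shape
        p2 = p.reshape(-1, shape[-1])              # single GEMM
        y = (p2 @ self.params["W"]).reshape(shape[:-1] + (self.c_out,))
        return y + self.params["b"], p2

    def backward(self, g, cache):
        p2 = cache
        g2 = g.reshape(-1, self.c_out)
        self.grads["W"] += p2.T @ g2
        self.grads["b"] += g2.sum(axis=0)
        gp = (g2 @ self.params["W"].T).reshape(g.shape[:-1] + (8 * self.c_in,))
        return _from_patches(gp, self.c_in)


class Deconv2x2(Layer):
    """Transposed 3-D convolution, kernel 2 / stride 2 (doubles spatial axes)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {"W": glorot(rng, c_in, 8 * c_out, (c_in, 8 * c_out)),
                       "b": np.zeros(c_out, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x):
        shape = x.shape
        x2 = x.reshape(-1, self.c_in)
        y = (x2 @ self.params["W"]).reshape(shape[:-1] + (8 * self.c_out,))
        out = _from_patches(y, self.c_out) + self.params["b"]
        return out, (x2, shape)

    def backward(self, g, cache):
        x2, shape = cache
        self.grads["b"] += g.sum(axis=(0, 1, 2, 3))
        gp = _to_patches(g)
        gp2 = gp.reshape(-1, 8 * self.c_out)
        self.grads["W"] += x2.T @ gp2
        return (gp2 @ self.params["W"].T).reshape(shape)


def relu(x):
    return np.maximum(x, 0.0)

def relu_grad(g, x):
    return g * (x > 0)

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Adam:
    """Standard Adam over a flat list of (layer, key) parameter slots."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)

    def zero_grad(self):
        for ly in self.layers:
            ly.zero_grad()
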