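"""A small, deterministic 3D convolutional network engine on numpy.

Implements exactly the layer set the node classifier needs — 3D convolution,
max pooling, batch normalisation, leaky ReLU, dropout, dense layers — with
explicit forward/backward passes and an Adam optimizer.  Tensors are laid out
``(N, C, X, Y, Z)``.  All randomness (initialisation, dropout, batch order)
flows through seeded ``numpy.random.Generator`` streams, so training histories
are bit-reproducible.

Weights are He-initialised (zero-mean normal with variance ``2 / fan_in``,
the appropriate scaling for rectifier networks); biases start at zero.  The
L2 penalty is ``l2_coeff * sum(w^2)`` over convolution and dense weights
(biases and batch-norm parameters excluded), added to the data loss.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Compute dtype for activations and parameters.  float32 is the working
#: default (CNN training is insensitive to the extra precision and ~2x
#: faster); tests that finite-difference gradients switch to float64.
DTYPE = np.float32

__all__ = [
    "Param",
    "Conv3D",
    "MaxPool3D",
    "BatchNorm",
    "LeakyReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


class Param:
    """A trainable tensor with its gradient; ``decay`` marks L2-regularised weights."""

    __slots__ = ("v", "g", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.v = np.asarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)
        self.decay = decay


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution, stride 1, 'same' zero padding.

    Weights are stored ``(cin, k, k, k, cout)``; forward and both backward
    contractions are einsums over sliding-window views, which avoids the
    large im2col copies.  The gradient w.r.t. the input is the full
    correlation of the (padded) output gradient with the flipped kernel.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, kernel
        fan_in = cin * kernel**3
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, kernel, kernel, kernel, cout)),
            decay=True,
        )
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        k, p = self.k, self.k // 2
        n, c = x.shape[:2]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp_shape = xp.shape
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        self._sp = win.shape[2:5]
        # im2col: (n * xyz, c * k^3) @ (c * k^3, f)
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(-1, c * k**3)
        self._cols = cols
        out = cols @ self.W.v.reshape(-1, self.cout) + self.b.v
        return out.reshape(n, *self._sp, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, grad):
        k, p = self.k, self.k // 2
        n = grad.shape[0]
        ox, oy, oz = self._sp
        g_flat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, self.cout)
        self.W.g += (self._cols.T @ g_flat).reshape(self.W.v.shape)
        self.b.g += g_flat.sum(axis=0)
        dcols = (g_flat @ self.W.v.reshape(-1, self.cout).T).reshape(
            n, ox, oy, oz, self.cin, k, k, k
        ).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        # col2im: scatter-add the k^3 shifted contributions
        dxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i : i + ox, j : j + oy, l : l + oz] += dcols[..., i, j, l]
        self._cols = None
        return dxp[:, :, p : -p or None, p : -p or None, p : -p or None]


class MaxPool3D(Layer):
    """Non-overlapping max pooling; odd remainders are trimmed (floor mode)."""

    def __init__(self, pool: tuple[int, int, int] = (2, 2, 2)):
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        p0, p1, p2 = self.pool
        self._full_shape = x.shape
        n, c, X, Y, Z = x.shape
        X, Y, Z = X - X % p0, Y - Y % p1, Z - Z % p2
        x = x[:, :, :X, :Y, :Z]
        r = x.reshape(n, c, X // p0, p0, Y // p1, p1, Z // p2, p2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, X // p0, Y // p1, Z // p2, p0 * p1 * p2
        )
        self._arg = r.argmax(axis=-1)
        self._in_shape = x.shape
        return r.max(axis=-1)

    def backward(self, grad):
        p0, p1, p2 = self.pool
        n, c, ox, oy, oz = grad.shape
        flat = np.zeros((n, c, ox, oy, oz, p0 * p1 * p2), dtype=grad.dtype)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, c, ox, oy, oz, p0, p1, p2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = flat.reshape(self._in_shape)
        if self._in_shape != self._full_shape:
            full = np.zeros(self._full_shape, dtype=grad.dtype)
            full[:, :, : self._in_shape[2], : self._in_shape[3], : self._in_shape[4]] = dx
            dx = full
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False, rng=None):
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(mu.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        shp = self._shape(x)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu.reshape(shp)) / self._std.reshape(shp)
        self._axes = axes
        self._m = x.size // x.shape[1]
        self._train = train
        return self.gamma.v.reshape(shp) * self._xhat + self.beta.v.reshape(shp)

    def backward(self, grad):
        shp = self._shape(grad)
        axes = self._axes
        self.gamma.g += (grad * self._xhat).sum(axis=axes)
        self.beta.g += grad.sum(axis=axes)
        g = grad * self.gamma.v.reshape(shp)
        if not self._train:
            return g / self._std.reshape(shp)
        m = self._m
        s1 = g.sum(axis=axes, keepdims=True)
        s2 = (g * self._xhat).sum(axis=axes, keepdims=True)
        return (g - s1 / m - self._xhat * s2 / m) / self._std.reshape(shp)


class LeakyReLU(Layer):
    """max(x, alpha * x); the negative half-plane is scaled by exactly alpha."""

    def __init__(self, alpha: float = 0.03):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.alpha * grad, grad)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)), decay=True)
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, grad):
        self.W.g += self._x.T @ grad
        self.b.g += grad.sum(axis=0)
        return grad @ self.W.v.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Multi-label binary cross-entropy (summed over endpoints, mean over batch).

    Returns ``(loss, dloss/dlogits)``.  Computed from logits for numerical
    stability: ``softplus(z) - y z`` per endpoint.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    softplus = np.logaddexp(0.0, z)
    loss = float((softplus - y * z).sum(axis=1).mean())
    grad = (sigmoid(z) - y) / z.shape[0]
    return loss, grad


class Adam:
    """Adam with externally controlled learning rate (for the decay schedule)."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.g
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.v -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0
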