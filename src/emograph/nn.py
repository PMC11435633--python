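"""Minimal feed-forward layers with manual backprop.

Every network in the package (the signal GAN, the 4-layer graph-convolutional
classifier, the plain-CNN baseline) is built from these layers.  Layers cache
what forward needs for backward; ``backward`` returns the gradient w.r.t. the
layer input and accumulates parameter gradients in ``grads``.

Shape conventions
-----------------
Dense           [B, F]            -> [B, F']
Conv1d          [B, C, L]         -> [B, C', L']
ChebGraphConv   [B, N, F]         -> [B, N, F']   (N graph nodes)
MaxPoolFeature  [B, N, F]         -> [B, N, F // size]
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "Conv1d", "ChebGraphConv", "MaxPoolFeature",
    "LeakyReLU", "Sigmoid", "Tanh", "Dropout", "Flatten", "Reshape",
    "Sequential", "softmax", "softmax_cross_entropy", "mse_loss",
    "bce_loss", "make_optimizer", "SGD", "Adam", "Adamax", "Adadelta",
]


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.W.T


class Conv1d(Layer):
    """1-D convolution via im2col; 'same' padding when stride == 1,
    'valid'-style floor((L + 2p - k)/s) + 1 otherwise."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = padding if padding is not None else (kernel // 2 if stride == 1 else kernel // 2)
        fan_in = c_in * kernel
        self.W = _glorot(rng, (c_in * kernel, c_out), fan_in, c_out)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        Lp = xp.shape[2]
        L_out = (Lp - self.k) // self.stride + 1
        idx = (np.arange(L_out)[:, None] * self.stride + np.arange(self.k)[None, :])
        cols = xp[:, :, idx]                       # [B, C, L_out, k]
        cols = cols.transpose(0, 2, 1, 3).reshape(B, L_out, C * self.k)
        return cols, L_out, Lp

    def forward(self, x, training=False):
        self._x_shape = x.shape
        cols, L_out, Lp = self._im2col(x)
        self._cols, self._L_out, self._Lp = cols, L_out, Lp
        y = cols @ self.W + self.b                 # [B, L_out, c_out]
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        B, _, L_out = grad.shape
        g = grad.transpose(0, 2, 1)                # [B, L_out, c_out]
        self.grads[0] += np.einsum("blf,blo->fo", self._cols, g)
        self.grads[1] += g.sum(axis=(0, 1))
        dcols = g @ self.W.T                       # [B, L_out, C*k]
        dcols = dcols.reshape(B, L_out, self.c_in, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, self.c_in, self._Lp))
        idx = (np.arange(L_out)[:, None] * self.stride + np.arange(self.k)[None, :])
        np.add.at(dxp, (slice(None), slice(None), idx), dcols)
        L = self._x_shape[2]
        return dxp[:, :, self.pad:self.pad + L]


class ChebGraphConv(Layer):
    """Spectral graph convolution with a degree-(K-1) Chebyshev filter.

    ``t_stack`` holds the Chebyshev matrices T_k(L~) of the rescaled Laplacian,
    shape [K, N, N], precomputed by the graph module.  Output mixes nodes via
    T_k and features via one [F_in, F_out] weight matrix per order.
    """

    def __init__(self, t_stack: np.ndarray, f_in: int, f_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.T = np.asarray(t_stack, dtype=float)
        K = self.T.shape[0]
        fan_in, fan_out = K * f_in, f_out
        self.W = _glorot(rng, (K, f_in, f_out), fan_in, fan_out)
        self.b = np.zeros(f_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        # xk[b,k,n,f] = (T_k x_b)[n,f]
        self._xk = np.einsum("knm,bmf->bknf", self.T, x)
        return np.einsum("bknf,kfo->bno", self._xk, self.W) + self.b

    def backward(self, grad):
        self.grads[0] += np.einsum("bknf,bno->kfo", self._xk, grad)
        self.grads[1] += grad.sum(axis=(0, 1))
        # dx[b,m,f] = sum_k T_k^T grad W_k^T
        gk = np.einsum("bno,kfo->bknf", grad, self.W)
        return np.einsum("knm,bknf->bmf", self.T, gk)


class MaxPoolFeature(Layer):
    """Max pooling along the trailing feature axis, floor division."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        B, N, F = x.shape
        Fo = F // self.size
        xr = x[:, :, :Fo * self.size].reshape(B, N, Fo, self.size)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        B, N, Fo = grad.shape
        dx = np.zeros(self._shape)
        b, n, f = np.meshgrid(np.arange(B), np.arange(N), np.arange(Fo),
                              indexing="ij")
        dx[b, n, f * self.size + self._arg] = grad
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x, training=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def all_params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def all_grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.all_params))

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params]

    def load_state(self, state):
        for p, s in zip(self.all_params, state):
            p[...] = s


# ---------------------------------------------------------------------------
# losses

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean CE over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def mse_loss(logits: np.ndarray, y: np.ndarray):
    """MSE against one-hot targets on softmax probabilities."""
    p = softmax(logits)
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), y] = 1.0
    diff = p - onehot
    loss = (diff ** 2).mean()
    dp = 2.0 * diff / diff.size
    # back through softmax
    dot = (dp * p).sum(axis=1, keepdims=True)
    return loss, p * (dp - dot)


def bce_loss(p: np.ndarray, target: float | np.ndarray, eps: float = 1e-7):
    """Binary cross-entropy on probabilities; returns (loss, dp)."""
    p = np.clip(p, eps, 1.0 - eps)
    t = np.broadcast_to(np.asarray(target, dtype=float), p.shape)
    loss = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
    dp = (p - t) / (p * (1 - p)) / p.size
    return loss, dp


# ---------------------------------------------------------------------------
# optimizers

class SGD:
    def __init__(self, params, grads, lr=0.01, weight_decay=0.0):
        self.params, self.grads = params, grads
        self.lr, self.wd = lr, weight_decay

    def step(self):
        for p, g in zip(self.params, self.grads):
            p -= self.lr * (g + self.wd * p)


class Adam:
    def __init__(self, params, grads, lr=0.001, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, *betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            g = g + self.wd * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax:
    def __init__(self, params, grads, lr=0.001, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, *betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, u in zip(self.params, self.grads, self.m, self.u):
            g = g + self.wd * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            u[...] = np.maximum(self.b2 * u, np.abs(g))
            p -= self.lr / (1 - self.b1 ** self.t) * m / (u + self.eps)


class Adadelta:
    def __init__(self, params, grads, lr=1.0, rho=0.95, eps=1e-6,
                 weight_decay=0.0):
        self.params, self.grads = params, grads
        self.lr, self.rho, self.eps, self.wd = lr, rho, eps, weight_decay
        self.Eg = [np.zeros_like(p) for p in params]
        self.Ed = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, Eg, Ed in zip(self.params, self.grads, self.Eg, self.Ed):
            g = g + self.wd * p
            Eg[...] = self.rho * Eg + (1 - self.rho) * g * g
            dx = -np.sqrt(Ed + self.eps) / np.sqrt(Eg + self.eps) * g
            Ed[...] = self.rho * Ed + (1 - self.rho) * dx * dx
            p += self.lr * dx


_OPTIMIZERS = {"sgd": SGD, "adam": Adam, "adamax": Adamax, "adadelta": Adadelta}


def make_optimizer(name: str, params, grads, lr: float, weight_decay: float = 0.0):
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}"
        ) from None
    return cls(params, grads, lr=lr, weight_decay=weight_decay)
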