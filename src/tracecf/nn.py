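"""Minimal feed-forward neural-network engine with manual backpropagation.

Provides the layers the package's models need (dense, strided convolution,
transposed convolution, common activations, inverted dropout), a ``Sequential``
container, and an Adam optimizer.  Everything is plain numpy; gradients are
hand-derived and are verified against finite differences in the test suite.

Conventions
-----------
* Images are NCHW float arrays; latent codes are (N, d).
* ``forward(x, train=...)`` caches what ``backward`` needs; ``backward(grad)``
  accumulates parameter gradients and returns the gradient w.r.t. the input,
  so objectives defined on network outputs can also be differentiated w.r.t.
  the input (used by the latent-space counterfactual optimizers).
* All randomness (init, dropout) flows through explicitly passed
  ``numpy.random.Generator`` instances; there is no global RNG state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "ELU",
    "Sigmoid",
    "Softplus",
    "Flatten",
    "Reshape",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "mlp",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


# ---------------------------------------------------------------------------
# dense
# ---------------------------------------------------------------------------


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: str = "glorot", dtype=np.float64):
        if scale == "he":
            std = np.sqrt(2.0 / n_in)
        else:
            std = np.sqrt(2.0 / (n_in + n_out))
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype), "W")
        self.b = Param(np.zeros(n_out, dtype=dtype), "b")
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# convolution via im2col / col2im
# ---------------------------------------------------------------------------


def _conv_out_hw(h: int, w: int, k: int, s: int, p: int) -> tuple[int, int]:
    return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _conv_out_hw(h, w, k, s, p)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    sn, sc, sh, sw = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, k, k),
        strides=(sn, sc, sh * s, sw * s, sh, sw),
        writeable=False,
    )
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to an image."""
    n, c, h, w = x_shape
    ho, wo = _conv_out_hw(h, w, k, s, p)
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + s * ho:s, j:j + s * wo:s] += cols6[:, :, i, j]
    return out[:, :, p:p + h, p:p + w]


class Conv2d(Layer):
    """Strided 2-D convolution (NCHW), kernel k, stride s, zero padding p."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1, dtype=np.float32):
        fan_in = c_in * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, fan_in)).astype(dtype), "W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")
        self.c_in, self.c_out, self.k, self.s, self.p = c_in, c_out, k, stride, pad
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        assert c == self.c_in, f"expected {self.c_in} channels, got {c}"
        ho, wo = _conv_out_hw(h, w, self.k, self.s, self.p)
        cols = im2col(x, self.k, self.s, self.p)
        self._cols, self._x_shape = cols, x.shape
        y = np.matmul(self.W.value, cols) + self.b.value[None, :, None]
        return y.reshape(n, self.c_out, ho, wo)

    def backward(self, grad):
        n, co, ho, wo = grad.shape
        g = grad.reshape(n, co, ho * wo)
        self.W.grad += np.einsum("ncl,nkl->ck", g, self._cols)
        self.b.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, g)
        return col2im(dcols, self._x_shape, self.k, self.s, self.p)

    def params(self):
        return [self.W, self.b]


class ConvTranspose2d(Layer):
    """Transposed convolution doubling spatial size (the adjoint of Conv2d).

    With k=3, stride=2, pad=1 this maps (N, c_in, H, W) -> (N, c_out, 2H, 2W),
    the exact adjoint of the encoder's stride-2 convolution geometry.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1, dtype=np.float32):
        fan_in = c_in * k * k
        # Stored as the weight of the adjoint conv: (c_in, c_out*k*k)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_in, c_out * k * k)).astype(dtype), "W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")
        self.c_in, self.c_out, self.k, self.s, self.p = c_in, c_out, k, stride, pad
        self._x_flat: np.ndarray | None = None
        self._out_shape: tuple | None = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        assert c == self.c_in
        ho, wo = self.s * h, self.s * w
        xf = x.reshape(n, c, h * w)
        self._x_flat = xf
        self._out_shape = (n, self.c_out, ho, wo)
        dcols = np.matmul(self.W.value.T, xf)  # (n, c_out*k*k, h*w)
        y = col2im(dcols, self._out_shape, self.k, self.s, self.p)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        cols = im2col(grad, self.k, self.s, self.p)  # (n, c_out*k*k, h*w)
        self.W.grad += np.einsum("ncl,nkl->ck", self._x_flat, cols)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = np.matmul(self.W.value, cols)
        n, c, hw = dx.shape
        h = self._out_shape[2] // self.s
        return dx.reshape(n, c, h, hw // h)

    def params(self):
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# activations and shape utilities
# ---------------------------------------------------------------------------


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._neg = x <= 0
        self._expm1 = np.expm1(np.minimum(x, 0.0))
        return np.where(self._neg, self.alpha * self._expm1, x)

    def backward(self, grad):
        return grad * np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Softplus(Layer):
    def forward(self, x, train=False):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, grad):
        return grad * sigmoid(self._x)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Dropout(Layer):
    """Inverted dropout.

    At train time a Bernoulli(1-p) mask scaled by 1/(1-p) is drawn from ``rng``
    (settable via :meth:`set_rng`).  ``mask_override`` lets callers freeze a
    specific mask, which is how fixed stochastic forward passes are realised
    for MC-dropout style uncertainty providers.
    """

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self.mask_override: np.ndarray | None = None

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def sample_mask(self, shape: tuple, rng: np.random.Generator) -> np.ndarray:
        return (rng.random(shape) >= self.p).astype(np.float64) / (1.0 - self.p)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if self.mask_override is not None:
            m = self.mask_override
            if m.shape != x.shape:  # broadcast a (1, d) mask over the batch
                m = np.broadcast_to(m, x.shape)
        else:
            if self.rng is None:
                raise RuntimeError("Dropout needs an rng at train time")
            m = self.sample_mask(x.shape, self.rng)
        self._mask = m
        return x * m

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def dropout_layers(self) -> list[Dropout]:
        return [l for l in self.layers if isinstance(l, Dropout)]

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for l in self.dropout_layers():
            l.set_rng(rng)

    # -- flat parameter (de)serialization -----------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        if len(arrays) != len(ps):
            raise ValueError(f"state has {len(arrays)} arrays, model has {len(ps)}")
        for p, a in zip(ps, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


# ---------------------------------------------------------------------------
# optimizer and helpers
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def mlp(sizes: list[int], rng: np.random.Generator, activation: str = "relu",
        out_layer: Layer | None = None, dropout: float = 0.0) -> Sequential:
    """Build a fully connected net: Dense+act per hidden size, linear head.

    ``sizes`` is [n_in, h1, ..., hk, n_out]; ``out_layer`` (e.g. Softplus) is
    appended after the final Dense when given.  ``dropout`` inserts a Dropout
    after every hidden activation.
    """
    acts = {"relu": ReLU, "elu": ELU}
    layers: list[Layer] = []
    for i in range(len(sizes) - 1):
        last = i == len(sizes) - 2
        layers.append(Dense(sizes[i], sizes[i + 1], rng,
                            scale="glorot" if last else "he"))
        if not last:
            layers.append(acts[activation]())
            if dropout > 0.0:
                layers.append(Dropout(dropout))
    if out_layer is not None:
        layers.append(out_layer)
    return Sequential(layers)
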