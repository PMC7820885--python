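"""Neural network layers built on the autograd engine.

Dense, convolution (via im2col), max-pooling, nearest-neighbour
upsampling, batch normalization, a trainable token embedding and an LSTM
cell -- the building blocks the five autoencoder families need.  Weight
initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so that models are bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Layer",
    "Dense",
    "BatchNorm",
    "Conv2D",
    "MaxPool2D",
    "Upsample2D",
    "Embedding",
    "LSTMCell",
    "ACTIVATIONS",
]


def _apply_activation(t: Tensor, name: str | None) -> Tensor:
    if name is None or name == "linear":
        return t
    if name == "relu":
        return t.relu()
    if name == "sigmoid":
        return t.sigmoid()
    if name == "tanh":
        return t.tanh()
    if name == "leaky_relu":
        return t.leaky_relu()
    raise ValueError(f"unknown activation: {name!r}")


ACTIVATIONS = ("linear", "relu", "sigmoid", "tanh", "leaky_relu")


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: a callable with trainable parameters."""

    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def train_mode(self) -> bool:
        return getattr(self, "_train", True)

    def set_train(self, flag: bool) -> None:
        self._train = flag


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, activation: str = "linear",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Tensor(glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.activation = activation

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return _apply_activation(x @ self.W + self.b, self.activation)


class BatchNorm(Layer):
    """Batch normalization over the sample axis (features last).

    Uses batch statistics in training mode and tracked running statistics
    in evaluation mode, so encoding is deterministic after training.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._train = True

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        if self._train:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data.ravel())
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data.ravel())
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Conv2D(Layer):
    """Same-padding stride-1 2-D convolution (channels-first NCHW).

    Implemented as an autograd primitive via im2col; the backward pass
    folds the column gradient back with per-offset accumulation.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 activation: str = "linear", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        fan_out = out_channels * kernel * kernel
        self.W = Tensor(
            glorot(rng, fan_in, fan_out, (out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)
        self.kernel = kernel
        self.activation = activation

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        pad = k // 2
        W, b = self.W, self.b
        n, c_in, h, w = x.data.shape
        c_out = W.data.shape[0]

        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # cols: (n, c_in, k, k, h, w)
        view = np.lib.stride_tricks.sliding_window_view(xp, (h, w), axis=(2, 3))
        # view shape: (n, c_in, k, k, h, w) given padded size h+2p etc.
        cols = view.reshape(n, c_in * k * k, h * w)
        Wm = W.data.reshape(c_out, c_in * k * k)
        out_data = (Wm @ cols).reshape(n, c_out, h, w) + b.data[None, :, None, None]

        def backward(out):
            g = out.grad  # (n, c_out, h, w)
            gm = g.reshape(n, c_out, h * w)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if W.requires_grad:
                dWm = np.einsum("nof,ncf->oc", gm, cols)
                W._accum(dWm.reshape(W.data.shape))
            if x.requires_grad:
                dcols = np.einsum("oc,nof->ncf", Wm, gm)
                dcols = dcols.reshape(n, c_in, k, k, h, w)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
                x._accum(dxp[:, :, pad:pad + h, pad:pad + w])

        out = Tensor._from_op(out_data, (x, W, b), backward)
        return _apply_activation(out, self.activation)


class MaxPool2D(Layer):
    """Non-overlapping max pooling (NCHW); spatial dims must divide the size."""

    def __init__(self, size: int = 2):
        self.size = size

    def __call__(self, x: Tensor) -> Tensor:
        s = self.size
        n, c, h, w = x.data.shape
        if h % s or w % s:
            raise ValueError("spatial dims must be divisible by pool size")
        blocks = x.data.reshape(n, c, h // s, s, w // s, s).swapaxes(3, 4)
        flat = blocks.reshape(n, c, h // s, w // s, s * s)
        out_data = flat.max(axis=-1)
        # route gradient to the first max per block (deterministic ties)
        onehot = np.zeros_like(flat)
        np.put_along_axis(onehot, flat.argmax(axis=-1)[..., None], 1.0, axis=-1)

        def backward(out):
            if x.requires_grad:
                g = (out.grad[..., None] * onehot).reshape(
                    n, c, h // s, w // s, s, s
                ).swapaxes(3, 4)
                x._accum(g.reshape(n, c, h, w))

        return Tensor._from_op(out_data, (x,), backward)


class Upsample2D(Layer):
    """Nearest-neighbour upsampling by an integer factor (NCHW)."""

    def __init__(self, size: int = 2):
        self.size = size

    def __call__(self, x: Tensor) -> Tensor:
        s = self.size
        out_data = x.data.repeat(s, axis=2).repeat(s, axis=3)

        def backward(out):
            if x.requires_grad:
                n, c, h, w = x.data.shape
                g = out.grad.reshape(n, c, h, s, w, s).sum(axis=(3, 5))
                x._accum(g)

        return Tensor._from_op(out_data, (x,), backward)


class Embedding(Layer):
    """Trainable token-id -> vector lookup table; id 0 is the pad token."""

    def __init__(self, vocab_size: int, dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        table = rng.normal(0.0, 0.1, size=(vocab_size, dim))
        table[0] = 0.0
        self.table = Tensor(table, requires_grad=True)
        self.vocab_size = vocab_size
        self.dim = dim

    def parameters(self) -> list[Tensor]:
        return [self.table]

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=int)
        if ids.size and (ids.min() < 0 or ids.max() >= self.vocab_size):
            raise ValueError("token id outside vocabulary")
        return self.table[ids]


class LSTMCell(Layer):
    """A single LSTM cell; gate order (i, f, g, o) on a fused weight matrix."""

    def __init__(self, input_dim: int, hidden_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        d = input_dim + hidden_dim
        self.W = Tensor(glorot(rng, d, 4 * hidden_dim, (d, 4 * hidden_dim)),
                        requires_grad=True)
        b = np.zeros(4 * hidden_dim)
        b[hidden_dim:2 * hidden_dim] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.hidden_dim = hidden_dim
        self.input_dim = input_dim

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_dim
        z = concat([x, h], axis=-1) @ self.W + self.b
        i = z[..., 0:H].sigmoid()
        f = z[..., H:2 * H].sigmoid()
        g = z[..., 2 * H:3 * H].tanh()
        o = z[..., 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new
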