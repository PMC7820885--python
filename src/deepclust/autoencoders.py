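"""Autoencoder backbones: the source of latent features Z = f_theta(X).

Five encoder families are provided -- plain dense, stacked denoising
(with greedy layer-wise pretraining), convolutional, variational and
recurrent (LSTM) -- all trained by minimizing a reconstruction
objective.  After training, only the encoder is kept and acts as the
feature extractor for clustering.

Loss conventions (documented because the mathematical definitions are
written as plain sums): squared-error losses sum over features and
average over the batch; the sequence loss sums over both sequences and
time steps.  Dropout-style corruption is pure masking -- surviving
coordinates are *not* rescaled -- matching the denoising-autoencoder
formulation rather than inverted-dropout inference.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ReconstructionReport, SequenceDataset, as_values
from .nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    LSTMCell,
    MaxPool2D,
    Tensor,
    Upsample2D,
    stack,
)

__all__ = [
    "BackboneSpec",
    "BackboneModel",
    "DenseAutoencoder",
    "StackedDenoisingAutoencoder",
    "ConvAutoencoder",
    "VariationalAutoencoder",
    "LSTMAutoencoder",
    "build_backbone",
    "preset_spec",
    "reconstruction_loss",
    "corrupt",
    "denoising_loss",
    "pretrain_greedy_layerwise",
    "vae_loss",
    "lstm_ae_loss",
    "encode",
    "train_reconstruction",
    "save_backbone",
    "load_backbone",
]

FAMILIES = ("dense", "stacked_denoising", "convolutional", "variational",
            "recurrent")


@dataclass
class BackboneSpec:
    """Architecture description for one backbone.

    ``layer_sizes`` holds hidden widths for dense/variational families,
    (channels, kernel, pool) triples for the convolutional family, and
    hidden-unit counts for the recurrent family.  ``latent_dim`` is the
    width of the embedded representation Z.
    """

    family: str
    layer_sizes: list = field(default_factory=list)
    latent_dim: int = 10
    activation: str = "relu"
    corruption_rate: float = 0.2
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0 <= self.corruption_rate < 1:
            raise ValueError("corruption_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "layer_sizes": [list(l) if isinstance(l, (tuple, list)) else l
                            for l in self.layer_sizes],
            "latent_dim": self.latent_dim,
            "activation": self.activation,
            "corruption_rate": self.corruption_rate,
            "batch_norm": self.batch_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneSpec":
        return cls(**d)


class BackboneModel:
    """Base class: an encoder/decoder pair over the autograd engine."""

    def __init__(self, spec: BackboneSpec, input_shape):
        self.spec = spec
        self.input_shape = tuple(np.atleast_1d(input_shape).tolist())

    # interface ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def encode_t(self, X) -> Tensor:
        """Differentiable encoder pass returning the latent Tensor."""
        raise NotImplementedError

    def forward_t(self, X, rng: np.random.Generator | None = None):
        """(latent Tensor, per-batch mean reconstruction-loss Tensor)."""
        raise NotImplementedError

    # conveniences ------------------------------------------------------
    def encode(self, X) -> np.ndarray:
        """Deterministic latent features (posterior mean for VAE)."""
        self.set_train(False)
        try:
            return self.encode_t(X).data.copy()
        finally:
            self.set_train(True)

    def set_train(self, flag: bool) -> None:
        for layer in getattr(self, "_layers", []):
            layer.set_train(flag)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.astype(np.float64).copy()

    def copy(self) -> "BackboneModel":
        return copy.deepcopy(self)


def _mse_per_sample(x: Tensor, xhat: Tensor) -> Tensor:
    """Sum of squared errors over all non-sample axes, per sample."""
    diff = x - xhat
    sq = diff * diff
    n = sq.data.shape[0]
    return sq.reshape(n, -1).sum(axis=1)


class DenseAutoencoder(BackboneModel):
    """Symmetric multilayer perceptron autoencoder.

    Encoder widths [D, h1, ..., latent]; nonlinear activations
    everywhere except the bottleneck output and the final reconstruction
    layer, which are linear (the convention that greedy layer-wise
    pretraining assumes).
    """

    def __init__(self, spec: BackboneSpec, input_shape, seed: int = 0):
        super().__init__(spec, input_shape)
        if len(self.input_shape) != 1:
            raise ValueError("dense family expects flat (D,) inputs")
        rng = np.random.default_rng(seed)
        D = self.input_shape[0]
        dims = [D] + [int(h) for h in spec.layer_sizes] + [spec.latent_dim]
        act = spec.activation
        self.encoder: list = []
        self.decoder: list = []
        self._layers: list = []
        for i in range(len(dims) - 1):
            a = "linear" if i == len(dims) - 2 else act
            layer = Dense(dims[i], dims[i + 1], activation=a, rng=rng)
            self.encoder.append(layer)
            self._layers.append(layer)
            if spec.batch_norm and i < len(dims) - 2:
                bn = BatchNorm(dims[i + 1])
                self.encoder.append(bn)
                self._layers.append(bn)
        rev = dims[::-1]
        for i in range(len(rev) - 1):
            a = "linear" if i == len(rev) - 2 else act
            layer = Dense(rev[i], rev[i + 1], activation=a, rng=rng)
            self.decoder.append(layer)
            self._layers.append(layer)

    def parameters(self) -> list[Tensor]:
        return [p for l in self._layers for p in l.parameters()]

    def encode_t(self, X) -> Tensor:
        t = X if isinstance(X, Tensor) else Tensor(as_values(X))
        for layer in self.encoder:
            t = layer(t)
        return t

    def decode_t(self, Z: Tensor) -> Tensor:
        t = Z
        for layer in self.decoder:
            t = layer(t)
        return t

    def forward_t(self, X, rng=None):
        x = X if isinstance(X, Tensor) else Tensor(as_values(X))
        z = self.encode_t(x)
        xhat = self.decode_t(z)
        loss = _mse_per_sample(x, xhat).mean()
        return z, loss


class StackedDenoisingAutoencoder(DenseAutoencoder):
    """Dense autoencoder initialized by greedy layer-wise denoising.

    Structurally identical to :class:`DenseAutoencoder`; the family tag
    enables :func:`pretrain_greedy_layerwise` and records the corruption
    rate used during pretraining.
    """


class ConvAutoencoder(BackboneModel):
    """Convolutional autoencoder for channels-last image stacks.

    Encoder: per stage Conv(ReLU) [+ BatchNorm spatial-flattened is
    omitted; normalization is per-channel dense on the bottleneck] and
    2x2 max-pooling; a dense layer maps the flattened maps to the
    latent code.  Decoder mirrors with nearest-neighbour upsampling and
    convolution, ending in a sigmoid conv so reconstructions stay in
    [0, 1].
    """

    def __init__(self, spec: BackboneSpec, input_shape, seed: int = 0):
        super().__init__(spec, input_shape)
        if len(self.input_shape) != 3:
            raise ValueError("convolutional family expects (H, W, C) inputs")
        h, w, c = self.input_shape
        rng = np.random.default_rng(seed)
        stages = [tuple(s) for s in spec.layer_sizes] or [(16, 3, 2), (8, 3, 2)]
        self.stages = stages
        self._layers = []
        self.enc_convs, self.enc_pools = [], []
        ch = c
        for (channels, kernel, pool) in stages:
            if h % pool or w % pool:
                raise ValueError("input size not divisible by pooling schedule")
            conv = Conv2D(ch, channels, kernel, activation=spec.activation, rng=rng)
            self.enc_convs.append(conv)
            self.enc_pools.append(MaxPool2D(pool))
            self._layers.append(conv)
            ch = channels
            h //= pool
            w //= pool
        self._bottleneck_shape = (ch, h, w)
        flat = ch * h * w
        self.to_latent = Dense(flat, spec.latent_dim, activation="linear", rng=rng)
        self.from_latent = Dense(spec.latent_dim, flat,
                                 activation=spec.activation, rng=rng)
        self._layers += [self.to_latent, self.from_latent]
        self.dec_ups, self.dec_convs = [], []
        rev = stages[::-1]
        for i, (channels, kernel, pool) in enumerate(rev):
            out_ch = rev[i + 1][0] if i + 1 < len(rev) else channels
            conv = Conv2D(channels, out_ch, kernel,
                          activation=spec.activation, rng=rng)
            self.dec_ups.append(Upsample2D(pool))
            self.dec_convs.append(conv)
            self._layers.append(conv)
        self.out_conv = Conv2D(rev[-1][0] if rev else c, c, 3,
                               activation="sigmoid", rng=rng)
        self._layers.append(self.out_conv)

    def parameters(self) -> list[Tensor]:
        return [p for l in self._layers for p in l.parameters()]

    @staticmethod
    def _to_nchw(X) -> np.ndarray:
        X = as_values(X)
        if X.ndim != 4:
            raise ValueError("expected (n, H, W, C) image stack")
        return np.transpose(X, (0, 3, 1, 2))

    def encode_t(self, X) -> Tensor:
        t = X if isinstance(X, Tensor) else Tensor(self._to_nchw(X))
        for conv, pool in zip(self.enc_convs, self.enc_pools):
            t = pool(conv(t))
        n = t.data.shape[0]
        return self.to_latent(t.reshape(n, -1))

    def decode_t(self, Z: Tensor) -> Tensor:
        n = Z.data.shape[0]
        t = self.from_latent(Z).reshape(n, *self._bottleneck_shape)
        for up, conv in zip(self.dec_ups, self.dec_convs):
            t = conv(up(t))
        return self.out_conv(t)

    def forward_t(self, X, rng=None):
        x = X if isinstance(X, Tensor) else Tensor(self._to_nchw(X))
        z = self.encode_t(x)
        xhat = self.decode_t(z)
        loss = _mse_per_sample(x, xhat).mean()
        return z, loss


class VariationalAutoencoder(BackboneModel):
    """Dense VAE with diagonal-Gaussian posterior and unit-normal prior.

    The encoder trunk feeds two linear heads producing the posterior
    mean and log-variance; training maximizes the evidence lower bound
    (squared-error reconstruction of a reparameterized sample plus the
    closed-form Gaussian KL).  ``encode`` returns the posterior mean so
    downstream clustering sees a deterministic embedding.
    """

    def __init__(self, spec: BackboneSpec, input_shape, seed: int = 0):
        super().__init__(spec, input_shape)
        if len(self.input_shape) != 1:
            raise ValueError("variational family expects flat (D,) inputs")
        rng = np.random.default_rng(seed)
        D = self.input_shape[0]
        dims = [D] + [int(h) for h in spec.layer_sizes]
        self.trunk = []
        self._layers = []
        for i in range(len(dims) - 1):
            layer = Dense(dims[i], dims[i + 1], activation=spec.activation, rng=rng)
            self.trunk.append(layer)
            self._layers.append(layer)
            if spec.batch_norm:
                bn = BatchNorm(dims[i + 1])
                self.trunk.append(bn)
                self._layers.append(bn)
        last = dims[-1]
        self.mu_head = Dense(last, spec.latent_dim, activation="linear", rng=rng)
        self.logvar_head = Dense(last, spec.latent_dim, activation="linear", rng=rng)
        self._layers += [self.mu_head, self.logvar_head]
        rev = dims[::-1]
        self.decoder = [Dense(spec.latent_dim, rev[0],
                              activation=spec.activation, rng=rng)]
        self._layers.append(self.decoder[0])
        for i in range(len(rev) - 1):
            a = "linear" if i == len(rev) - 2 else spec.activation
            layer = Dense(rev[i], rev[i + 1], activation=a, rng=rng)
            self.decoder.append(layer)
            self._layers.append(layer)

    def parameters(self) -> list[Tensor]:
        return [p for l in self._layers for p in l.parameters()]

    def posterior_t(self, X) -> tuple[Tensor, Tensor]:
        t = X if isinstance(X, Tensor) else Tensor(as_values(X))
        for layer in self.trunk:
            t = layer(t)
        return self.mu_head(t), self.logvar_head(t)

    def encode_t(self, X) -> Tensor:
        mu, _ = self.posterior_t(X)
        return mu

    def decode_t(self, Z: Tensor) -> Tensor:
        t = Z
        for layer in self.decoder:
            t = layer(t)
        return t

    def elbo_terms_t(self, X, rng: np.random.Generator | None = None):
        """(per-sample recon Tensor, per-sample KL Tensor).

        KL(q(z|x) || N(0, I)) = 0.5 * sum(mu^2 + var - 1 - log var).
        """
        x = X if isinstance(X, Tensor) else Tensor(as_values(X))
        mu, logvar = self.posterior_t(x)
        if rng is None:
            eps = np.zeros_like(mu.data)
        else:
            eps = rng.standard_normal(mu.data.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        xhat = self.decode_t(z)
        recon = _mse_per_sample(x, xhat)
        kl = ((mu * mu + logvar.exp() - 1.0 - logvar) * 0.5).sum(axis=1)
        return recon, kl

    def forward_t(self, X, rng=None):
        mu = self.encode_t(X)
        recon, kl = self.elbo_terms_t(X, rng)
        return mu, (recon + kl).mean()


class LSTMAutoencoder(BackboneModel):
    """Sequence-to-sequence autoencoder reconstructing in reverse order.

    The encoder LSTM consumes a variable-length sequence of real
    vectors; its final hidden state (projected to ``latent_dim``) is the
    fixed-length representation.  The decoder is seeded from the latent
    code and, with teacher forcing, predicts the input sequence in
    reverse order.
    """

    def __init__(self, spec: BackboneSpec, input_shape, seed: int = 0):
        super().__init__(spec, input_shape)
        if len(self.input_shape) != 1:
            raise ValueError("recurrent family expects (D,) per-step inputs")
        rng = np.random.default_rng(seed)
        D = self.input_shape[0]
        hidden = int(spec.layer_sizes[0]) if spec.layer_sizes else 64
        self.hidden = hidden
        self.enc_cell = LSTMCell(D, hidden, rng=rng)
        self.to_latent = Dense(hidden, spec.latent_dim, activation="linear", rng=rng)
        self.from_latent = Dense(spec.latent_dim, hidden, activation="tanh", rng=rng)
        self.dec_cell = LSTMCell(D, hidden, rng=rng)
        self.out_proj = Dense(hidden, D, activation="linear", rng=rng)
        self._layers = [self.enc_cell, self.to_latent, self.from_latent,
                        self.dec_cell, self.out_proj]

    def parameters(self) -> list[Tensor]:
        return [p for l in self._layers for p in l.parameters()]

    @staticmethod
    def _as_sequences(X) -> list[np.ndarray]:
        if isinstance(X, SequenceDataset):
            raise TypeError("embed token sequences first (vectorize_tokens)")
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        return [np.asarray(s, dtype=float) for s in X]

    def _encode_one(self, seq: np.ndarray) -> Tensor:
        if seq.ndim != 2 or seq.shape[0] == 0:
            raise ValueError("each sequence must be a non-empty (L, D) array")
        h = Tensor(np.zeros((1, self.hidden)))
        c = Tensor(np.zeros((1, self.hidden)))
        for t in range(seq.shape[0]):
            x_t = Tensor(seq[t:t + 1])
            h, c = self.enc_cell.step(x_t, h, c)
        return self.to_latent(h)

    def encode_t(self, X) -> Tensor:
        seqs = self._as_sequences(X)
        rows = [self._encode_one(s).reshape(-1) for s in seqs]
        return stack(rows, axis=0)

    def sequence_loss_t(self, X) -> tuple[Tensor, list[float]]:
        """Summed squared error against reverse-order targets, per Eq.-style
        convention (sum over sequences and time steps)."""
        seqs = self._as_sequences(X)
        per_seq: list[Tensor] = []
        for seq in seqs:
            L, D = seq.shape
            latent = self._encode_one(seq)
            h = self.from_latent(latent)
            c = Tensor(np.zeros((1, self.hidden)))
            targets = seq[::-1]  # reconstruct in reverse input order
            total = None
            prev = np.zeros((1, D))
            for t in range(L):
                h, c = self.dec_cell.step(Tensor(prev), h, c)
                pred = self.out_proj(h)
                target = Tensor(targets[t:t + 1])
                err = _mse_per_sample(target, pred).sum()
                total = err if total is None else total + err
                prev = targets[t:t + 1]  # teacher forcing
            per_seq.append(total)
        losses = [t.item() for t in per_seq]
        grand = per_seq[0]
        for t in per_seq[1:]:
            grand = grand + t
        return grand, losses

    def forward_t(self, X, rng=None):
        z = self.encode_t(X)
        loss, per = self.sequence_loss_t(X)
        n = len(per)
        return z, loss * (1.0 / n)


_FAMILY_CLASSES = {
    "dense": DenseAutoencoder,
    "stacked_denoising": StackedDenoisingAutoencoder,
    "convolutional": ConvAutoencoder,
    "variational": VariationalAutoencoder,
    "recurrent": LSTMAutoencoder,
}


def build_backbone(spec: BackboneSpec, input_shape, seed: int = 0) -> BackboneModel:
    """Construct a randomly initialized backbone for ``input_shape``.

    Initialization is a pure function of (spec, input_shape, seed).
    """
    cls = _FAMILY_CLASSES[spec.family]
    return cls(spec, input_shape, seed=seed)


def preset_spec(name: str, input_dim: int | None = None,
                scale: float = 1.0) -> BackboneSpec:
    """Named architecture presets mirroring the published layer schedules.

    ``scale`` shrinks channel/unit counts for desk-scale runs (1.0 keeps
    the printed sizes); ``input_dim`` parameterizes the input width of the
    gene-expression preset.
    """

    def s(x: int) -> int:
        return max(1, int(round(x * scale)))

    if name == "bach_cae_24layer":
        # four conv+BN+pool stages (127, 64, 32, 32 channels), mirrored
        # by four upsample+deconv stages
        return BackboneSpec(
            family="convolutional",
            layer_sizes=[(s(127), 3, 2), (s(64), 3, 2), (s(32), 3, 2),
                         (s(32), 3, 2)],
            latent_dim=max(2, s(32)),
            activation="relu",
            corruption_rate=0.2,
            batch_norm=True,
        )
    if name == "ge_vae_12layer":
        # dense 256 -> 32 trunk with BN + 20% dropout, 2-D latent code
        _ = input_dim  # input width is supplied at build time
        return BackboneSpec(
            family="variational",
            layer_sizes=[s(256), s(32)],
            latent_dim=2,
            activation="relu",
            corruption_rate=0.2,
            batch_norm=True,
        )
    if name == "review_lstm_ae":
        # 128-unit encoder LSTM over 300-dim token vectors, 20% dropout
        return BackboneSpec(
            family="recurrent",
            layer_sizes=[s(128)],
            latent_dim=max(2, s(128)),
            activation="tanh",
            corruption_rate=0.2,
        )
    raise ValueError(f"unknown preset {name!r}")


# -- objectives ---------------------------------------------------------


def reconstruction_loss(X, Xhat) -> ReconstructionReport:
    """Squared-error reconstruction loss sum_i ||x_i - xhat_i||^2.

    Per-sample terms sum over features; ``loss_value`` is their mean
    over the batch (reduction documented in the report).
    """
    X = as_values(X)
    Xhat = as_values(Xhat)
    if X.shape != Xhat.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    per = ((X - Xhat).reshape(X.shape[0], -1) ** 2).sum(axis=1)
    return ReconstructionReport(loss_value=float(per.mean()),
                                per_sample_losses=per,
                                loss_kind="squared_error", reduction="mean")


def corrupt(x: np.ndarray, rate: float, seed: int | np.random.Generator = 0
            ) -> np.ndarray:
    """Zero each coordinate independently with probability ``rate``.

    Surviving coordinates are left unscaled (pure masking).
    """
    if not 0 <= rate < 1:
        raise ValueError("corruption rate must be in [0, 1)")
    x = np.asarray(x, dtype=float)
    if rate == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(x.shape) >= rate
    return x * mask


def denoising_loss(x: np.ndarray, model: BackboneModel,
                   seed: int | np.random.Generator = 0,
                   rate: float | None = None) -> float:
    """Denoising objective: encode the corrupted input, score against the
    clean target with squared error (the standard convention; the
    absolute-difference form sometimes printed reduces to the same zero
    at a perfect reconstruction)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    rate = model.spec.corruption_rate if rate is None else rate
    x_tilde = corrupt(x, rate, seed)
    z = model.encode_t(x_tilde)
    xhat = model.decode_t(z)
    per = ((x - xhat.data).reshape(x.shape[0], -1) ** 2).sum(axis=1)
    return float(per.mean())


def vae_loss(x, model: VariationalAutoencoder,
             seed: int | np.random.Generator = 0) -> ReconstructionReport:
    """Negative ELBO = reconstruction term + KL(q(z|x) || N(0, I)).

    The KL term is reported separately and is always >= 0.
    """
    if not isinstance(model, VariationalAutoencoder):
        raise TypeError("vae_loss requires a variational backbone")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recon, kl = model.elbo_terms_t(np.atleast_2d(as_values(x)), rng)
    per = recon.data + kl.data
    return ReconstructionReport(
        loss_value=float(per.mean()),
        per_sample_losses=per,
        loss_kind="negative_elbo",
        reduction="mean",
        kl_term=float(kl.data.mean()),
    )


def lstm_ae_loss(batch, model: LSTMAutoencoder) -> ReconstructionReport:
    """Reverse-order sequence reconstruction loss (sum over sequences
    and time steps)."""
    if not isinstance(model, LSTMAutoencoder):
        raise TypeError("lstm_ae_loss requires a recurrent backbone")
    total, per = model.sequence_loss_t(batch)
    return ReconstructionReport(loss_value=float(total.item()),
                                per_sample_losses=np.array(per),
                                loss_kind="sequence_reverse", reduction="sum")


def encode(model: BackboneModel, X) -> np.ndarray:
    """Extract latent features Z (n rows, latent_dim columns)."""
    return model.encode(X)


# -- training -----------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_reconstruction(model: BackboneModel, X, epochs: int,
                         lr: float = 1e-3, batch_size: int = 32,
                         seed: int = 0) -> list[float]:
    """Minimize the family's reconstruction objective with Adam.

    Returns the per-epoch mean training loss.  For the variational
    family the objective is the negative ELBO with reparameterized
    sampling; for the recurrent family, the reverse-order sequence loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    history: list[float] = []
    if isinstance(model, LSTMAutoencoder):
        seqs = model._as_sequences(X)
        for _ in range(int(epochs)):
            epoch_losses = []
            for idx in _batches(len(seqs), batch_size, rng):
                batch = [seqs[i] for i in idx]
                opt.zero_grad()
                _, loss = model.forward_t(batch)
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            history.append(float(np.mean(epoch_losses)))
        return history

    values = as_values(X)
    for _ in range(int(epochs)):
        epoch_losses = []
        for idx in _batches(values.shape[0], batch_size, rng):
            opt.zero_grad()
            _, loss = model.forward_t(values[idx], rng)
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return history


def pretrain_greedy_layerwise(model: DenseAutoencoder, X, epochs_per_layer: int,
                              corruption_rate: float | None = None,
                              seed: int = 0, lr: float = 1e-3,
                              batch_size: int = 32,
                              fine_tune_epochs: int | None = None
                              ) -> DenseAutoencoder:
    """Greedy layer-wise denoising pretraining followed by fine-tuning.

    Each encoder/decoder pair is trained as a two-layer denoising
    autoencoder on the (clean) output of the previously trained encoder
    stack: the pair input is corrupted by dropout, passed through the
    pair, and scored with least squares against the clean input.  After
    all pairs are trained, the full deep autoencoder (encoder order then
    reversed decoder order) is fine-tuned end-to-end on clean inputs.
    ``epochs_per_layer == 0`` leaves every parameter untouched.

    Activation convention: ReLU within pairs except the outermost
    decoder output and the innermost encoder output, which are linear.
    """
    if not isinstance(model, DenseAutoencoder):
        raise TypeError("greedy layer-wise pretraining requires a dense or "
                        "stacked_denoising backbone")
    if epochs_per_layer < 0:
        raise ValueError("epochs_per_layer must be >= 0")
    if epochs_per_layer == 0:
        return model
    rate = model.spec.corruption_rate if corruption_rate is None else corruption_rate
    if not 0 <= rate < 1:
        raise ValueError("corruption rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    enc_layers = [l for l in model.encoder if isinstance(l, Dense)]
    dec_layers = [l for l in model.decoder if isinstance(l, Dense)]
    n_pairs = len(enc_layers)
    H = as_values(X)
    for i in range(n_pairs):
        enc = enc_layers[i]
        dec = dec_layers[n_pairs - 1 - i]  # its mirror in the decoder
        opt = Adam(enc.parameters() + dec.parameters(), lr=lr)
        for _ in range(int(epochs_per_layer)):
            for idx in _batches(H.shape[0], batch_size, rng):
                clean = H[idx]
                x_t = Tensor(corrupt(clean, rate, rng))
                opt.zero_grad()
                h = enc(x_t)
                if rate > 0:
                    # in-graph dropout mask (no rescaling): gradient flows
                    # through surviving coordinates only
                    h = h * Tensor(rng.random(h.data.shape) >= rate)
                y = dec(h)
                loss = _mse_per_sample(Tensor(clean), y).mean()
                loss.backward()
                opt.step()
        H = enc(Tensor(H)).data  # clean representation feeds the next pair
    fine = epochs_per_layer if fine_tune_epochs is None else fine_tune_epochs
    if fine > 0:
        train_reconstruction(model, X, epochs=fine, lr=lr,
                             batch_size=batch_size, seed=seed + 1)
    return model


# -- persistence --------------------------------------------------------


def save_backbone(model: BackboneModel, path: str) -> None:
    """Save parameters + spec JSON in a single .npz container."""
    meta = json.dumps({
        "spec": model.spec.to_dict(),
        "input_shape": list(model.input_shape),
    })
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_backbone(path: str, seed: int = 0) -> BackboneModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = [data[f"param_{i}"]
                  for i in range(sum(1 for k in data.files if k.startswith("param_")))]
    spec = BackboneSpec.from_dict(meta["spec"])
    model = build_backbone(spec, meta["input_shape"], seed=seed)
    model.load_state_arrays(arrays)
    return model
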