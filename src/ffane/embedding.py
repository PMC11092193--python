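"""Stacked-autoencoder node embedding of fused-similarity rows.

Each protein's raw feature vector is its row of the fused similarity matrix
(dimension n).  A stacked autoencoder — encoder widths ``[n, 1024, 512, 128]``
by default, mirrored untied decoder — is trained to minimise the mean squared
reconstruction error

    F_loss = (1/N) * sum_i || x_i - g(f(x_i)) ||^2

with Adam (learning rate 0.001), minibatches of 32, at most 100 epochs and
early stopping (patience 30) on a held-out validation split.  After training
the decoder is discarded and the encoder's bottleneck output (128-dimensional
by default) is the node embedding.

The implementation is plain numpy: forward/backward passes are written out
explicitly, which keeps training exactly reproducible per seed on one CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

#: Paper-scale default widths; hidden layers are capped so none is wider than
#: its predecessor when the input dimension is small.
DEFAULT_HIDDEN = (1024, 512, 128)

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class SAEConfig:
    """Training configuration for the stacked autoencoder.

    ``layer_sizes`` is the full encoder width sequence starting at the input
    dimension; ``None`` resolves to ``[n, 1024, 512, 128]`` with each hidden
    width capped at its predecessor.
    """

    layer_sizes: tuple[int, ...] | None = None
    activation: str = "sigmoid"  # "sigmoid" | "relu"
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.001
    patience: int = 30
    validation_fraction: float = 0.1
    seed: int = 0
    greedy: bool = False
    scale_minmax: bool = False

    def __post_init__(self) -> None:
        if self.activation not in ("sigmoid", "relu"):
            raise ValueError("activation must be 'sigmoid' or 'relu'")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.layer_sizes is not None:
            sizes = tuple(int(w) for w in self.layer_sizes)
            if any(w <= 0 for w in sizes) or len(sizes) < 2:
                raise ValueError("layer_sizes must be >=2 positive widths")
            if any(b > a for a, b in zip(sizes[1:], sizes[2:])):
                raise ValueError("widths must be weakly decreasing after the input")
            self.layer_sizes = sizes


def resolve_layer_sizes(input_dim: int, layer_sizes: tuple[int, ...] | None) -> tuple[int, ...]:
    """Concrete encoder widths for an input of dimension ``input_dim``.

    The default hidden widths presume a large protein set; for smaller inputs
    each width is capped at its predecessor so the autoencoder never widens.
    """
    if layer_sizes is None:
        sizes = [input_dim]
        for w in DEFAULT_HIDDEN:
            sizes.append(min(w, sizes[-1]))
        return tuple(sizes)
    sizes = tuple(int(w) for w in layer_sizes)
    if sizes[0] != input_dim:
        raise ValueError(
            f"layer_sizes[0]={sizes[0]} must equal the input dimension {input_dim}"
        )
    return sizes


@dataclass(frozen=True)
class Encoder:
    """Trained encoder: layered application of sigma(x W + b)."""

    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    activations: tuple[str, ...]  # per layer: "sigmoid" | "relu" | "linear"

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]


@dataclass
class TrainingHistory:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False
    epochs_run: int = 0
    initial_loss: float = float("nan")
    final_loss: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "train_losses": self.train_losses,
            "val_losses": self.val_losses,
            "best_epoch": self.best_epoch,
            "stopped_early": self.stopped_early,
            "epochs_run": self.epochs_run,
            "initial_loss": self.initial_loss,
            "final_loss": self.final_loss,
        }


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        out = np.empty_like(z)
        np.negative(z, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        return out
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "linear":
        return z
    raise ValueError(kind)


def _activation_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "relu":
        return (a > 0).astype(a.dtype)
    if kind == "linear":
        return np.ones_like(a)
    raise ValueError(kind)


def _layer_activations(n_layers: int, kind: str, final_linear: bool) -> list[str]:
    # sigmoid mode: sigmoid everywhere (inputs live in [0, 1]);
    # relu mode: relu hidden, linear output layer.
    acts = [kind] * n_layers
    if kind == "relu" and final_linear:
        acts[-1] = "linear"
    return acts


def _glorot_init(rng: np.random.Generator, sizes: list[int]) -> tuple[list, list]:
    ws, bs = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        ws.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32))
        bs.append(np.zeros(fan_out, dtype=np.float32))
    return ws, bs


def _forward(x: np.ndarray, ws: list, bs: list, acts: list[str]) -> list[np.ndarray]:
    """Returns per-layer post-activation outputs, input first."""
    outs = [x]
    for w, b, act in zip(ws, bs, acts):
        outs.append(_activate(outs[-1] @ w + b, act))
    return outs


def _reconstruction_loss(x, ws, bs, acts) -> float:
    xhat = _forward(x, ws, bs, acts)[-1]
    diff = xhat - x
    return float(np.mean(np.sum(diff * diff, axis=1)))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - _ADAM_B1**self.t
        b2t = 1.0 - _ADAM_B2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= _ADAM_B1
            m += (1.0 - _ADAM_B1) * g
            v *= _ADAM_B2
            v += (1.0 - _ADAM_B2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + _ADAM_EPS)


def _train_autoencoder(
    x: np.ndarray,
    ws: list,
    bs: list,
    acts: list[str],
    config: SAEConfig,
    rng: np.random.Generator,
) -> TrainingHistory:
    """In-place minibatch Adam training of one encoder+decoder stack."""
    n = x.shape[0]
    history = TrainingHistory()
    history.initial_loss = _reconstruction_loss(x, ws, bs, acts)

    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split left no training rows")
    x_train, x_val = x[train_idx], x[val_idx]

    params = ws + bs
    opt = _Adam(params, config.learning_rate)
    best = (np.inf, 0, None)  # monitored loss, epoch, params snapshot
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), config.batch_size):
            xb = x_train[order[start : start + config.batch_size]]
            outs = _forward(xb, ws, bs, acts)
            delta = (2.0 / xb.shape[0]) * (outs[-1] - xb)
            grads_w, grads_b = [], []
            for layer in range(len(ws) - 1, -1, -1):
                delta = delta * _activation_grad(outs[layer + 1], acts[layer])
                grads_w.append(outs[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer:
                    delta = delta @ ws[layer].T
            opt.step(params, grads_w[::-1] + grads_b[::-1])

        train_loss = _reconstruction_loss(x_train, ws, bs, acts)
        history.train_losses.append(train_loss)
        if n_val:
            monitored = _reconstruction_loss(x_val, ws, bs, acts)
            history.val_losses.append(monitored)
        else:
            monitored = train_loss
        history.epochs_run = epoch
        if monitored < best[0]:
            best = (monitored, epoch, (copy.deepcopy(ws), copy.deepcopy(bs)))
        elif epoch - best[1] >= config.patience:
            history.stopped_early = True
            break

    history.best_epoch = best[1]
    if best[2] is not None:
        for dst, src in zip(ws, best[2][0]):
            dst[...] = src
        for dst, src in zip(bs, best[2][1]):
            dst[...] = src
    history.final_loss = _reconstruction_loss(x, ws, bs, acts)
    return history


def train_sae(fused: SimilarityMatrix, config: SAEConfig | None = None) -> tuple[Encoder, TrainingHistory]:
    """Train the stacked autoencoder on fused-matrix rows; return the encoder.

    The decoder (an untied mirror of the encoder) exists only during training
    and is discarded.  With ``config.greedy`` the stack is built by classic
    layer-wise pre-training instead of end-to-end optimisation.
    """
    config = config or SAEConfig()
    x = np.asarray(fused.values, dtype=np.float32)
    if not np.isfinite(x).all():
        raise ValueError("fused matrix must be finite")
    if config.scale_minmax:
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        x = (x - lo) / span
    sizes = list(resolve_layer_sizes(x.shape[1], config.layer_sizes))
    rng = np.random.default_rng(config.seed)

    if config.greedy:
        return _train_greedy(x, sizes, config, rng)

    full_sizes = sizes + sizes[-2::-1]  # mirrored untied decoder
    acts = _layer_activations(len(full_sizes) - 1, config.activation, final_linear=True)
    ws, bs = _glorot_init(rng, full_sizes)
    history = _train_autoencoder(x, ws, bs, acts, config, rng)
    k = len(sizes) - 1  # encoder layer count
    enc_acts = list(acts[:k])
    if config.activation == "relu":
        enc_acts[-1] = "linear"  # bottleneck output kept linear in relu mode
    encoder = Encoder(
        weights=tuple(ws[:k]), biases=tuple(bs[:k]), activations=tuple(enc_acts)
    )
    return encoder, history


def _train_greedy(
    x: np.ndarray, sizes: list[int], config: SAEConfig, rng: np.random.Generator
) -> tuple[Encoder, TrainingHistory]:
    """Classic stacking: each layer trained as a one-hidden-layer autoencoder
    on the previous layer's codes."""
    enc_ws, enc_bs, enc_acts = [], [], []
    current = x
    history = TrainingHistory()
    history.initial_loss = float("nan")
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        stage_sizes = [fan_in, fan_out, fan_in]
        acts = _layer_activations(2, config.activation, final_linear=True)
        ws, bs = _glorot_init(rng, stage_sizes)
        stage = _train_autoencoder(current, ws, bs, acts, config, rng)
        if np.isnan(history.initial_loss):
            history.initial_loss = stage.initial_loss
        history.train_losses.extend(stage.train_losses)
        history.val_losses.extend(stage.val_losses)
        history.epochs_run += stage.epochs_run
        history.best_epoch = stage.best_epoch
        history.stopped_early = stage.stopped_early
        history.final_loss = stage.final_loss
        enc_ws.append(ws[0])
        enc_bs.append(bs[0])
        enc_acts.append(acts[0])
        current = _activate(current @ ws[0] + bs[0], acts[0])
    encoder = Encoder(
        weights=tuple(enc_ws), biases=tuple(enc_bs), activations=tuple(enc_acts)
    )
    return encoder, history


def encode(encoder: Encoder, matrix: np.ndarray) -> np.ndarray:
    """Embed rows of ``matrix`` through the trained encoder."""
    x = np.asarray(matrix, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != encoder.input_dim:
        raise ValueError(
            f"expected input of width {encoder.input_dim}, got shape {x.shape}"
        )
    out = _forward(x, list(encoder.weights), list(encoder.biases), list(encoder.activations))[-1]
    return out.astype(np.float64)
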