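"""Symmetric fully connected autoencoder for deep-code compression.

The default architecture is 2000-1000-400-1000-2000: a two-layer encoder maps a
2000-d deep code to a 400-d latent, z = g(W2 g(W1 x + b1) + b2) with ReLU g, and
a mirrored decoder reconstructs the input (linear output layer, since deep codes
are unbounded). Training minimizes mean squared reconstruction error by seeded
mini-batch SGD (lr 0.001, batch 32, 1000 epochs at full scale). One autoencoder
is fitted per modality, on training-fold data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AEConfig:
    layer_widths: tuple = (2000, 1000, 400, 1000, 2000)
    learning_rate: float = 0.001
    momentum: float = 0.9  # classical momentum; the conventional reading of "SGD"
    batch: int = 32
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        w = tuple(self.layer_widths)
        if w != w[::-1]:
            raise ValueError("layer widths must be symmetric")
        if len(w) % 2 == 0:
            raise ValueError("need an odd number of widths (middle = latent)")
        self.layer_widths = w

    @property
    def latent_dim(self) -> int:
        return self.layer_widths[len(self.layer_widths) // 2]


@dataclass
class AEWeights:
    Ws: list = field(default_factory=list)  # one matrix per transition
    bs: list = field(default_factory=list)
    widths: tuple = ()

    @property
    def n_encoder(self) -> int:
        return len(self.Ws) // 2


def init_weights(cfg: AEConfig) -> AEWeights:
    """Seeded uniform init scaled by fan-in."""
    rng = np.random.default_rng(cfg.seed)
    Ws, bs = [], []
    for d_in, d_out in zip(cfg.layer_widths[:-1], cfg.layer_widths[1:]):
        bound = np.sqrt(1.0 / d_in)
        Ws.append(rng.uniform(-bound, bound, size=(d_out, d_in)))
        bs.append(np.zeros(d_out))
    return AEWeights(Ws, bs, cfg.layer_widths)


def encode(x: np.ndarray, weights: AEWeights) -> np.ndarray:
    """Deep code -> latent. Accepts a single vector or a [n, d] batch."""
    h = np.asarray(x, dtype=float)
    for W, b in zip(weights.Ws[: weights.n_encoder], weights.bs[: weights.n_encoder]):
        h = np.maximum(h @ W.T + b, 0.0)
    return h


def decode(z: np.ndarray, weights: AEWeights) -> np.ndarray:
    """Latent -> reconstruction; hidden layers ReLU, output layer linear."""
    h = np.asarray(z, dtype=float)
    n = len(weights.Ws)
    for i in range(weights.n_encoder, n):
        h = h @ weights.Ws[i].T + weights.bs[i]
        if i < n - 1:
            h = np.maximum(h, 0.0)
    return h


def _forward_full(x: np.ndarray, weights: AEWeights):
    acts = [x]
    h = x
    n = len(weights.Ws)
    for i, (W, b) in enumerate(zip(weights.Ws, weights.bs)):
        h = h @ W.T + b
        if i < n - 1:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return h, acts


def reconstruction_mse(x: np.ndarray, weights: AEWeights) -> float:
    """Mean over samples and components of the squared reconstruction error."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return float(np.mean((decode(encode(x, weights), weights) - x) ** 2))


def train_autoencoder(
    codes: np.ndarray, cfg: AEConfig | None = None
) -> tuple[AEWeights, list[float]]:
    """Mini-batch SGD on the MSE reconstruction loss; seeded and deterministic.

    Returns the weights and the per-epoch mean loss trajectory. Raises if the
    loss becomes non-finite.
    """
    cfg = cfg or AEConfig()
    X = np.atleast_2d(np.asarray(codes, dtype=float))
    if X.shape[1] != cfg.layer_widths[0]:
        raise ValueError(
            f"input dim {X.shape[1]} != first layer width {cfg.layer_widths[0]}"
        )
    rng = np.random.default_rng(cfg.seed)
    weights = init_weights(cfg)
    n = len(X)
    losses: list[float] = []
    n_layers = len(weights.Ws)
    vWs = [np.zeros_like(W) for W in weights.Ws]
    vbs = [np.zeros_like(b) for b in weights.bs]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch):
            xb = X[order[lo : lo + cfg.batch]]
            xhat, acts = _forward_full(xb, weights)
            err = xhat - xb
            # loss = ||x - x'||^2 per sample, averaged over the batch
            loss = float(np.mean(np.sum(err**2, axis=1)))
            if not np.isfinite(loss):
                raise ValueError("diverged; lower learning rate")
            epoch_loss += loss
            n_batches += 1
            delta = 2.0 * err / len(xb)
            for i in range(n_layers - 1, -1, -1):
                if i < n_layers - 1:
                    delta = delta * (acts[i + 1] > 0)
                gW = delta.T @ acts[i]
                gb = delta.sum(axis=0)
                delta = delta @ weights.Ws[i]
                vWs[i] = cfg.momentum * vWs[i] - cfg.learning_rate * gW
                vbs[i] = cfg.momentum * vbs[i] - cfg.learning_rate * gb
                weights.Ws[i] += vWs[i]
                weights.bs[i] += vbs[i]
        losses.append(epoch_loss / max(n_batches, 1))
    return weights, losses
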