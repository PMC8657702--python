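"""PCM binding classifiers: the full network and the No-Interaction-Terms baseline.

The full model concatenates the compound and protein descriptor vectors and
passes them through three fully connected ReLU layers to a single sigmoid
output, so hidden units can form compound-protein interaction features. The
No-Interaction-Terms baseline keeps the two channels separate: one tower
sees only the compound vector, the other only the protein vector, each
ending in its own sigmoid, and the model prediction is the arithmetic mean
of the two tower probabilities. By construction the baseline can at best
recover per-compound and per-protein propensity ("bias") and is structurally
unable to express any interaction: its 2x2 prediction tables over any
compound pair x protein pair are exactly additive.

Training minimizes binary cross-entropy with Adam, halves the learning rate
when validation loss plateaus, stops early after a patience of epochs
without validation improvement, and restores the best-validation weights.
Everything is plain numpy and fully deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import ActivityTable, EmbeddingTable
from .splits import SplitAssignment

logger = logging.getLogger(__name__)

VARIANTS = ("full", "no_interaction")


@dataclass
class ModelConfig:
    variant: str = "full"
    hidden_sizes: tuple[int, int, int] = (2048, 1024, 512)
    dropout: float = 0.25
    learning_rate: float = 1e-3
    lr_halving_patience: int = 5
    early_stop_patience: int = 10
    min_delta: float = 1e-4  # plateau threshold on validation loss
    max_epochs: int = 300
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) != 3:
            raise ValueError("exactly 3 hidden layers required")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lr_halving_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")


class _FeedForward:
    """Three ReLU hidden layers + linear output unit, He-initialized."""

    def __init__(self, in_dim: int, hidden: Sequence[int], rng: np.random.Generator):
        sizes = [in_dim, *hidden, 1]
        self.weights = [
            rng.standard_normal((sizes[i], sizes[i + 1])) * math.sqrt(2.0 / sizes[i])
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, dropout: float = 0.0, rng=None):
        """Returns logits and the per-layer cache needed for backprop."""
        cache = []
        a = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if i < last:
                h = np.maximum(z, 0.0)
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                    h = h * mask
                else:
                    mask = None
                cache.append((a, z, mask))
                a = h
            else:
                cache.append((a, z, None))
        return z[:, 0], cache

    def backward(self, dlogit: np.ndarray, cache, dropout: float) -> list[np.ndarray]:
        """Gradient of the summed loss w.r.t. params(), given d loss / d logit."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = dlogit[:, None]
        for i in range(len(self.weights) - 1, -1, -1):
            a, z, mask = cache[i]
            grads_w[i] = a.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                _, z_prev, mask_prev = cache[i - 1]
                delta = delta * (z_prev > 0)
                if mask_prev is not None:
                    delta = delta * mask_prev
        return grads_w + grads_b


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class PCMModel:
    """A built (and possibly trained) PCM classifier."""

    config: ModelConfig
    compound_dim: int
    protein_dim: int
    networks: list[_FeedForward] = field(repr=False, default_factory=list)
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return sum(net.n_parameters() for net in self.networks)

    # --- forward passes -------------------------------------------------

    def _forward_probs(self, xc: np.ndarray, xp: np.ndarray):
        """Probabilities plus the caches/intermediates needed for backprop."""
        if self.config.variant == "full":
            logits, cache = self.networks[0].forward(np.hstack([xc, xp]))
            return _sigmoid(logits), (cache,)
        zc, cc = self.networks[0].forward(xc)
        zp, cp = self.networks[1].forward(xp)
        pc, pp = _sigmoid(zc), _sigmoid(zp)
        return 0.5 * (pc + pp), (cc, cp, pc, pp)

    def predict_matrix(self, xc: np.ndarray, xp: np.ndarray) -> np.ndarray:
        """Probabilities for row-aligned compound/protein feature matrices."""
        probs, _ = self._forward_probs(np.asarray(xc, float), np.asarray(xp, float))
        eps = np.finfo(float).tiny
        return np.clip(probs, eps, 1 - eps)

    def predict(
        self,
        pairs: Sequence[tuple[str, str]],
        compound_embeddings: EmbeddingTable,
        protein_embeddings: EmbeddingTable,
    ) -> np.ndarray:
        """Activity probabilities for (compound_id, protein_id) pairs, in order."""
        xc = compound_embeddings.matrix_for([c for c, _ in pairs])
        xp = protein_embeddings.matrix_for([p for _, p in pairs])
        return self.predict_matrix(xc, xp)

    # --- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for ni, net in enumerate(self.networks):
            for pi, w in enumerate(net.weights):
                arrays[f"net{ni}_w{pi}"] = w
            for pi, b in enumerate(net.biases):
                arrays[f"net{ni}_b{pi}"] = b
        meta = {
            "config": asdict(self.config),
            "compound_dim": self.compound_dim,
            "protein_dim": self.protein_dim,
            "training_log": self.training_log,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PCMModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig(**{**meta["config"], "hidden_sizes": tuple(meta["config"]["hidden_sizes"])})
        model = build(cfg, meta["compound_dim"], meta["protein_dim"])
        for ni, net in enumerate(model.networks):
            net.weights = [data[f"net{ni}_w{pi}"] for pi in range(len(net.weights))]
            net.biases = [data[f"net{ni}_b{pi}"] for pi in range(len(net.biases))]
        model.training_log = meta["training_log"]
        return model


def build(config: ModelConfig, compound_dim: int, protein_dim: int) -> PCMModel:
    """Construct an untrained model with seed-deterministic initial weights.

    The no-interaction towers mirror the full model's three layers at half
    width so the two variants have comparable capacity.
    """
    if compound_dim <= 0 or protein_dim <= 0:
        raise ValueError("descriptor dims must be positive")
    rng = np.random.default_rng(config.seed)
    if config.variant == "full":
        nets = [_FeedForward(compound_dim + protein_dim, config.hidden_sizes, rng)]
    else:
        tower = [max(1, h // 2) for h in config.hidden_sizes]
        nets = [
            _FeedForward(compound_dim, tower, rng),
            _FeedForward(protein_dim, tower, rng),
        ]
    return PCMModel(config=config, compound_dim=compound_dim, protein_dim=protein_dim, networks=nets)


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _features(
    table: ActivityTable,
    idx: np.ndarray,
    compound_embeddings: EmbeddingTable,
    protein_embeddings: EmbeddingTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    recs = [table[int(i)] for i in idx]
    try:
        xc = compound_embeddings.matrix_for([r.compound_id for r in recs])
        xp = protein_embeddings.matrix_for([r.protein_id for r in recs])
    except KeyError as exc:
        raise ValueError(f"missing embedding: {exc}") from None
    y = np.array([r.label for r in recs], dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("unlabeled records in split")
    return xc, xp, y


def train(
    model: PCMModel,
    split: SplitAssignment,
    compound_embeddings: EmbeddingTable,
    protein_embeddings: EmbeddingTable,
    table: ActivityTable,
) -> PCMModel:
    """Fit in place on the split's train partition; returns the model.

    Per epoch: shuffled mini-batches, Adam updates on the binary
    cross-entropy; validation loss afterwards (dropout off). The learning
    rate halves after ``lr_halving_patience`` epochs without a new best
    validation loss, training stops after ``early_stop_patience`` such
    epochs, and the best-validation weights are restored before returning.
    """
    cfg = model.config
    if len(split.train) == 0 or len(split.valid) == 0:
        raise ValueError("train and valid partitions must be non-empty")
    xc_tr, xp_tr, y_tr = _features(table, split.train, compound_embeddings, protein_embeddings)
    xc_va, xp_va, y_va = _features(table, split.valid, compound_embeddings, protein_embeddings)

    rng = np.random.default_rng(cfg.seed + 1)
    params = [p for net in model.networks for p in net.params()]
    opt = _Adam(params, cfg.learning_rate)
    best_val = math.inf  # strict best, for weight restoration
    plateau_ref = math.inf  # min_delta-gated best, for patience counters
    best_weights: list[np.ndarray] | None = None
    epochs_since_best = 0
    n = len(y_tr)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        train_loss_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            b = order[start : start + cfg.batch_size]
            xcb, xpb, yb = xc_tr[b], xp_tr[b], y_tr[b]
            if cfg.variant == "full":
                logits, cache = model.networks[0].forward(
                    np.hstack([xcb, xpb]), dropout=cfg.dropout, rng=rng
                )
                probs = _sigmoid(logits)
                dlogit = (probs - yb) / len(b)
                grads = model.networks[0].backward(dlogit, cache, cfg.dropout)
            else:
                # each tower is its own single-channel predictor trained on
                # the labels; only prediction averages them
                zc, cc = model.networks[0].forward(xcb, dropout=cfg.dropout, rng=rng)
                zp, cp = model.networks[1].forward(xpb, dropout=cfg.dropout, rng=rng)
                pc, pp = _sigmoid(zc), _sigmoid(zp)
                probs = 0.5 * (pc + pp)
                grads = model.networks[0].backward((pc - yb) / len(b), cc, cfg.dropout)
                grads += model.networks[1].backward((pp - yb) / len(b), cp, cfg.dropout)
            train_loss_sum += _bce(probs, yb) * len(b)
            opt.step(params, grads)

        val_probs = model.predict_matrix(xc_va, xp_va)
        val_loss = _bce(val_probs, y_va)
        model.training_log.append(
            {
                "epoch": epoch,
                "train_loss": train_loss_sum / n,
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = [p.copy() for p in params]
        if val_loss < plateau_ref - cfg.min_delta:
            plateau_ref = val_loss
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best % cfg.lr_halving_patience == 0:
                opt.lr *= 0.5
                logger.debug("epoch %d: halving learning rate to %g", epoch, opt.lr)
            if epochs_since_best >= cfg.early_stop_patience:
                logger.debug("early stop at epoch %d", epoch)
                break

    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p[...] = w
    return model
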