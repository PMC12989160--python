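"""Feed-forward binary classifier trained with SGD.

A compact, fully deterministic implementation of the sequential network used
to separate driver from passenger mutations: 1-5 ReLU hidden layers with
He-normal initialization, a single sigmoid output unit, binary cross-entropy
loss with L2 weight decay, stochastic gradient descent with momentum,
mini-batch shuffling, and early stopping on validation loss that restores
the best checkpointed weights.

A sigmoid output unit is mathematically equivalent to a two-way softmax
head; the single-unit form is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    hidden_units: one entry per hidden layer (1-5 layers).
    lr / momentum: SGD step size and momentum coefficient.
    l2: weight-decay coefficient (loss term l2 * sum W^2).
    patience: early-stopping patience in epochs on validation loss.
    val_fraction: fraction of the training set held out for early stopping.
    """

    hidden_units: tuple[int, ...] = (64, 32)
    lr: float = 0.01
    momentum: float = 0.9
    l2: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_units) <= 5:
            raise ValueError(
                f"need 1-5 hidden layers, got {len(self.hidden_units)}"
            )
        if self.lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {self.lr}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # log(1 + e^z) - y z, computed stably
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


class MLPClassifier:
    """He-initialized ReLU network with a sigmoid output unit."""

    def __init__(self, n_features: int, config: ModelConfig):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        sizes = [n_features, *config.hidden_units, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He-normal
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.stopped_epoch: int | None = None

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Hidden activations (post-ReLU) and output logits."""
        activations = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(0.0, h @ w + b)
            activations.append(h)
        logits = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return activations, logits

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Binary cross-entropy plus the L2 penalty."""
        _, logits = self._forward(x)
        penalty = self.config.l2 * sum(float(np.sum(w * w)) for w in self.weights)
        return _bce_from_logits(logits, y) + penalty

    def _step(self, x: np.ndarray, y: np.ndarray, velocity) -> None:
        cfg = self.config
        activations, logits = self._forward(x)
        n = len(y)
        delta = (_sigmoid(logits) - y)[:, None] / n  # dL/dlogits
        grads_w = []
        grads_b = []
        for layer in range(len(self.weights) - 1, -1, -1):
            a = activations[layer]
            grads_w.append(a.T @ delta + 2.0 * cfg.l2 * self.weights[layer])
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
        grads_w.reverse()
        grads_b.reverse()
        vw, vb = velocity
        for i in range(len(self.weights)):
            vw[i] = cfg.momentum * vw[i] - cfg.lr * grads_w[i]
            vb[i] = cfg.momentum * vb[i] - cfg.lr * grads_b[i]
            self.weights[i] += vw[i]
            self.biases[i] += vb[i]

    # -- training -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        """Train with mini-batch SGD; early stopping monitors the loss on an
        internal stratified validation split and restores the best weights."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {x.shape[1]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values; impute before training")

        # stratified validation split for early stopping
        idx_val: list[int] = []
        if cfg.val_fraction > 0:
            for cls in (0.0, 1.0):
                cls_idx = np.flatnonzero(y == cls)
                self._rng.shuffle(cls_idx)
                n_val = int(round(cfg.val_fraction * len(cls_idx)))
                idx_val.extend(cls_idx[:n_val])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[idx_val] = True
        x_tr, y_tr = x[~val_mask], y[~val_mask]
        x_val, y_val = x[val_mask], y[val_mask]
        monitor_val = len(y_val) > 0 and len(np.unique(y_val)) == 2

        velocity = (
            [np.zeros_like(w) for w in self.weights],
            [np.zeros_like(b) for b in self.biases],
        )
        best_loss = np.inf
        best_state = None
        wait = 0
        n = len(y_tr)
        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                self._step(x_tr[batch], y_tr[batch], velocity)
            train_loss = self.loss(x_tr, y_tr)
            if not np.isfinite(train_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check feature scaling"
                )
            monitored = self.loss(x_val, y_val) if monitor_val else train_loss
            self.history["train_loss"].append(train_loss)
            self.history["val_loss"].append(monitored)
            if monitored < best_loss - 1e-9:
                best_loss = monitored
                best_state = (
                    [w.copy() for w in self.weights],
                    [b.copy() for b in self.biases],
                )
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    self.stopped_epoch = epoch
                    break
        if best_state is not None:  # restore best checkpoint
            self.weights = [w.copy() for w in best_state[0]]
            self.biases = [b.copy() for b in best_state[1]]
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        _, logits = self._forward(x)
        return _sigmoid(logits)

    def predict(self, x: np.ndarray, threshold: float | None = None) -> np.ndarray:
        if threshold is None:
            threshold = self.config.threshold
        return (self.predict_proba(x) >= threshold).astype(int)
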