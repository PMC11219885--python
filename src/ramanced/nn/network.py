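"""Network container, Adam optimizer and the seeded training loop."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError
from .blocks import Sequential
from .layers import BatchNorm1d, BatchNormFlat, Dropout, Layer

__all__ = ["Adam", "TrainSettings", "Network", "softmax", "cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(
        self,
        root: Layer,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.slots = [
            (lyr, name) for lyr in root.walk() for name in lyr.params
        ]
        self.m = [np.zeros_like(lyr.params[n]) for lyr, n in self.slots]
        self.v = [np.zeros_like(lyr.params[n]) for lyr, n in self.slots]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (lyr, name) in enumerate(self.slots):
            g = lyr.grads.get(name)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            lyr.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass(frozen=True)
class TrainSettings:
    """Optimization settings shared by all deep families."""

    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 20
    min_delta: float = 1e-4
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if not 0 <= self.validation_fraction < 1:
            raise ConfigurationError("validation_fraction must lie in [0, 1)")


class Network:
    """A Sequential graph with a 2-unit softmax head and a fit/predict API."""

    def __init__(self, graph: Sequential, rng: np.random.Generator) -> None:
        self.graph = graph
        self.rng = rng
        self.history: dict[str, list[float]] = {
            "train_loss": [],
            "train_acc": [],
            "val_loss": [],
            "val_acc": [],
        }

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.graph.forward(x, training)

    def recalibrate_batchnorm(self, x: np.ndarray) -> None:
        """Reset batch-norm running statistics from one dropout-free pass.

        Dropout inflates activation variance during training, so running
        statistics collected there overestimate the inference-time variance
        and systematically shift eval-mode logits. One full pass with
        dropout off and momentum 0 replaces them with clean statistics.
        """
        bns = [
            lyr
            for lyr in self.graph.walk()
            if isinstance(lyr, (BatchNorm1d, BatchNormFlat))
        ]
        if not bns:
            return
        drops = [lyr for lyr in self.graph.walk() if isinstance(lyr, Dropout)]
        saved = [(d, d.rate) for d in drops] + [(b, b.momentum) for b in bns]
        for d in drops:
            d.rate = 0.0
        for b in bns:
            b.momentum = 0.0
        try:
            self.graph.forward(x, training=True)
        finally:
            for obj, val in saved:
                if isinstance(obj, Dropout):
                    obj.rate = val
                else:
                    obj.momentum = val

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self._forward(x, training=False))

    def _evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        logits = self._forward(x, training=False)
        loss, _ = cross_entropy(logits, y)
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc

    def get_weights(self) -> list[np.ndarray]:
        return [lyr.params[n].copy() for lyr in self.graph.walk() for n in sorted(lyr.params)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        slots = [(lyr, n) for lyr in self.graph.walk() for n in sorted(lyr.params)]
        for (lyr, n), w in zip(slots, weights):
            lyr.params[n] = w.copy()

    def fit(self, x: np.ndarray, y: np.ndarray, settings: TrainSettings) -> "Network":
        """Minimize cross-entropy with Adam; early-stop on validation loss.

        A validation split is carved from the end of a seeded shuffle of the
        training rows; with ``validation_fraction = 0`` training runs for
        the full epoch budget and early stopping is disabled. The best
        validation-loss weights are restored at the end.
        """
        if x.shape[0] != y.shape[0]:
            raise ConfigurationError("x and y disagree on sample count")
        n_val = int(round(settings.validation_fraction * x.shape[0]))
        if n_val >= 2:
            # stratified carve-out: proportional share of each class
            val_idx: list[int] = []
            for cls in np.unique(y):
                members = np.flatnonzero(y == cls)
                members = members[self.rng.permutation(members.size)]
                take = max(1, int(round(settings.validation_fraction * members.size)))
                val_idx.extend(members[:take].tolist())
            val_mask = np.zeros(x.shape[0], dtype=bool)
            val_mask[val_idx] = True
            x_tr, y_tr = x[~val_mask], y[~val_mask]
            x_val, y_val = x[val_mask], y[val_mask]
        else:
            x_tr, y_tr = x, y
            x_val = y_val = None

        optimizer = Adam(self.graph, settings.learning_rate)
        best_loss = np.inf
        best_weights = self.get_weights()
        wait = 0
        n = x_tr.shape[0]
        for _ in range(settings.epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, settings.batch_size):
                idx = order[start : start + settings.batch_size]
                logits = self._forward(x_tr[idx], training=True)
                loss, dlogits = cross_entropy(logits, y_tr[idx])
                if not np.isfinite(loss) or not np.isfinite(logits).all():
                    raise FloatingPointError(
                        f"non-finite training loss/logits at step {optimizer.t + 1} "
                        f"(lr={settings.learning_rate}, batch={settings.batch_size})"
                    )
                self.graph.backward(dlogits)
                optimizer.step()
                epoch_loss += loss * idx.size
                correct += int((logits.argmax(axis=1) == y_tr[idx]).sum())
            self.history["train_loss"].append(epoch_loss / n)
            self.history["train_acc"].append(correct / n)
            if x_val is not None:
                self.recalibrate_batchnorm(x_tr)
                val_loss, val_acc = self._evaluate(x_val, y_val)
                self.history["val_loss"].append(val_loss)
                self.history["val_acc"].append(val_acc)
                if val_loss < best_loss - settings.min_delta:
                    best_loss = val_loss
                    best_weights = self.get_weights()
                    wait = 0
                else:
                    wait += 1
                    if wait >= settings.patience:
                        break
        if x_val is not None:
            self.set_weights(best_weights)
        self.recalibrate_batchnorm(x_tr)
        return self
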