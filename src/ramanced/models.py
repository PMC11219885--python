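"""The six classifier families over preprocessed spectra.

Four 1-D deep architectures — plain CNN, multi-scale CNN (MCNN), residual
network (ResNet) and deep residual shrinkage network (DRSN) — plus SVM and
KNN baselines, all behind one fit/predict_proba contract. The DRSN is the
ResNet topology with a learned channel-wise soft-thresholding gate inside
each residual unit, so the DRSN-vs-ResNet comparison isolates the
shrinkage mechanism.

Architectural facts fixed by the study design: the CNN stacks four conv
layers with 32/64/64/32 filters and a 2-unit head with dropout after each
dense layer; the MCNN runs three parallel branches with 16/32/64 filters
and kernel sizes 4/8/16, stride 1, 'same' padding and leaky rectifiers.
Unstated details (kernel 9 and pool strides for CNN/ResNet, three residual
units, dense head width 64, dropout 0.5, Adam at 1e-3 with batch 8 and
early stopping) are package choices documented in the methods note.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError
from .nn import (
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool1d,
    LeakyReLU,
    MaxPool1d,
    Network,
    ParallelConcat,
    ReLU,
    ResidualUnit,
    Sequential,
    TrainSettings,
)
from .nn.layers import ShrinkageGate, soft_threshold  # re-exported

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict_proba",
    "soft_threshold",
    "ShrinkageGate",
    "FAMILIES",
]

FAMILIES = ("cnn", "mcnn", "resnet", "drsn", "svm", "knn")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture family plus hyperparameters for one classifier."""

    family: Literal["cnn", "mcnn", "resnet", "drsn", "svm", "knn"] = "drsn"
    conv_filters: tuple[int, ...] = ()
    kernel_sizes: tuple[int, ...] = ()
    dropout_rate: float = 0.5
    n_classes: int = 2
    residual_units: int = 3
    shrinkage_reduction: int = 4
    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    training: TrainSettings = field(default_factory=TrainSettings)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.n_classes != 2:
            raise ConfigurationError("only binary classification is supported")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if not self.conv_filters:
            defaults = {
                "cnn": (32, 64, 64, 32),
                "mcnn": (16, 32, 64),
                "resnet": (32, 64, 64),
                "drsn": (32, 64, 64),
            }
            object.__setattr__(self, "conv_filters", defaults.get(self.family, ()))
        if not self.kernel_sizes:
            defaults = {"cnn": (9,), "mcnn": (4, 8, 16), "resnet": (9,), "drsn": (9,)}
            object.__setattr__(self, "kernel_sizes", defaults.get(self.family, ()))

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, training=replace(self.training, seed=seed))

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "family": self.family,
                "conv_filters": list(self.conv_filters),
                "kernel_sizes": list(self.kernel_sizes),
                "dropout_rate": self.dropout_rate,
                "residual_units": self.residual_units,
                "shrinkage_reduction": self.shrinkage_reduction,
                "knn_k": self.knn_k,
                "svm_kernel": self.svm_kernel,
                "svm_c": self.svm_c,
                "training": vars(self.training) | {},
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """A fitted classifier plus its provenance."""

    family: str
    classifier: object
    history: dict
    config_hash: str
    seed: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return predict_proba(self, x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


class DeepClassifier:
    """Numpy network wrapper implementing the shared contract."""

    def __init__(self, config: ModelConfig, input_length: int) -> None:
        self.config = config
        self.input_length = input_length
        rng = np.random.default_rng(config.training.seed)
        builder = {
            "cnn": _build_cnn,
            "mcnn": _build_mcnn,
            "resnet": lambda c, L, r: _build_resnet(c, L, r, shrinkage=False),
            "drsn": lambda c, L, r: _build_resnet(c, L, r, shrinkage=True),
        }[config.family]
        self.net = Network(builder(config, input_length, rng), rng)

    def n_parameters(self) -> int:
        return self.net.graph.n_parameters()

    def _as_3d(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != self.input_length:
                raise ConfigurationError(
                    f"{self.config.family}: input length {x.shape[1]} != "
                    f"expected {self.input_length}"
                )
            x = x[:, None, :]
        return x

    def fit(self, x: np.ndarray, y: np.ndarray) -> "DeepClassifier":
        self.net.fit(self._as_3d(x), np.asarray(y, dtype=int), self.config.training)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._as_3d(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    @property
    def history(self) -> dict:
        return self.net.history


class ClassicalClassifier:
    """SVM / KNN baseline behind the same contract (scikit-learn inside)."""

    def __init__(self, config: ModelConfig, input_length: int) -> None:
        self.config = config
        self.input_length = input_length
        if config.family == "svm":
            self.est = SVC(
                kernel=config.svm_kernel,
                C=config.svm_c,
                random_state=config.training.seed,
            )
        else:
            self.est = KNeighborsClassifier(n_neighbors=config.knn_k)
        self.history: dict = {}

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ClassicalClassifier":
        self.est.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.input_length:
            raise ConfigurationError(
                f"{self.config.family}: input length {x.shape[1]} != "
                f"expected {self.input_length}"
            )
        if self.config.family == "svm":
            # Monotone sigmoid of the margin rather than Platt scaling,
            # which is unreliable (and can invert rankings) at this n.
            margin = self.est.decision_function(x)
            if self.est.classes_[1] != 1:
                margin = -margin
            p1 = 1.0 / (1.0 + np.exp(-margin))
            return np.column_stack([1.0 - p1, p1])
        proba = self.est.predict_proba(x)
        # column order: class 0 (control), class 1 (CeD)
        order = np.argsort(self.est.classes_)
        return proba[:, order]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def _pooled_length(length: int, pools: list[int]) -> int:
    for p in pools:
        length //= p
    return length


def _build_cnn(cfg: ModelConfig, L: int, rng: np.random.Generator) -> Sequential:
    k = cfg.kernel_sizes[0]
    filters = cfg.conv_filters
    layers: list = []
    c_in = 1
    for f in filters:
        layers += [Conv1d(c_in, f, k, 1, "same", rng), ReLU(), MaxPool1d(2)]
        c_in = f
    flat = filters[-1] * _pooled_length(L, [2] * len(filters))
    layers += [
        Flatten(),
        Dense(flat, 64, rng),
        ReLU(),
        Dropout(cfg.dropout_rate, rng),
        Dense(64, cfg.n_classes, rng),
    ]
    return Sequential(*layers)


def _build_mcnn(cfg: ModelConfig, L: int, rng: np.random.Generator) -> Sequential:
    branches = [
        Sequential(Conv1d(1, f, k, 1, "same", rng), LeakyReLU(), MaxPool1d(4))
        for f, k in zip(cfg.conv_filters, cfg.kernel_sizes)
    ]
    total = sum(cfg.conv_filters)
    flat = 32 * _pooled_length(L, [4, 4])
    return Sequential(
        ParallelConcat(*branches),
        Conv1d(total, 32, 9, 1, "same", rng),
        LeakyReLU(),
        MaxPool1d(4),
        Flatten(),
        Dense(flat, 64, rng),
        LeakyReLU(),
        Dropout(cfg.dropout_rate, rng),
        Dense(64, cfg.n_classes, rng),
    )


def _build_resnet(
    cfg: ModelConfig, L: int, rng: np.random.Generator, shrinkage: bool
) -> Sequential:
    f0 = cfg.conv_filters[0]
    k = cfg.kernel_sizes[0]
    layers: list = [
        Conv1d(1, f0, k, 1, "same", rng),
        BatchNorm1d(f0),
        ReLU(),
        MaxPool1d(4),
    ]
    c_in = f0
    for i, f in enumerate(cfg.conv_filters[: cfg.residual_units]):
        stride = 1 if i == 0 else 2
        layers += [
            ResidualUnit(c_in, f, k, stride, shrinkage=shrinkage, rng=rng),
            Dropout(cfg.dropout_rate, rng),
        ]
        c_in = f
    layers += [GlobalAvgPool1d(), Dense(c_in, cfg.n_classes, rng)]
    return Sequential(*layers)


def build_model(config: ModelConfig, input_length: int):
    """Instantiate an untrained classifier of the configured family."""
    min_len = 16 * 4  # deepest pooling chain must leave >= 1 sample
    if config.family in ("cnn", "mcnn", "resnet", "drsn"):
        if input_length < min_len:
            raise ConfigurationError(
                f"input_length {input_length} too short for the conv stack "
                f"(needs >= {min_len})"
            )
        return DeepClassifier(config, input_length)
    return ClassicalClassifier(config, input_length)


def train(model, x: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit a classifier and wrap it with its provenance."""
    model.fit(x, y)
    cfg: ModelConfig = model.config
    return TrainedModel(
        family=cfg.family,
        classifier=model,
        history=dict(model.history),
        config_hash=cfg.config_hash(),
        seed=cfg.training.seed,
    )


def predict_proba(model, x: np.ndarray) -> np.ndarray:
    """Class probabilities (column 1 = CeD) from a fitted or trained model."""
    target = model.classifier if isinstance(model, TrainedModel) else model
    proba = target.predict_proba(np.asarray(x, dtype=float))
    if proba.ndim != 2 or proba.shape[1] != 2:
        raise ConfigurationError("predict_proba must return (n, 2) probabilities")
    return proba
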