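"""FOG detectors: deep networks and shallow baselines.

Seven detector kinds share one contract — ``fit_detector`` returns a
:class:`TrainedDetector` whose ``score`` method maps feature rows to a
scalar where **higher means more FOG-like** — so the evaluation harness is
model-agnostic.

Novelty detectors (``mlp_autoencoder``, ``ocsvm``) are fitted on non-FOG
rows only and flag FOG as deviation from normal movement: the autoencoder
scores by reconstruction RMSE, the one-class SVM by distance outside the
learned region. Supervised detectors (``svm``, ``adaboost``,
``random_forest``, ``cnn``, ``cnn_lstm``) use the binary window labels.

Deep models train with binary cross-entropy, gradient clipping at 1,
learning rate 1e-4 and early stopping after 20 stagnant epochs; the
autoencoder uses RMSprop, the convolutional models Adam. Features feeding
any deep model are scaled to [0, 1] by the training-set maximum; the same
scale is stored on the detector and reused at scoring time, never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC, OneClassSVM

from . import nn
from .errors import ContractError, StateError

DEEP_KINDS = ("mlp_autoencoder", "cnn", "cnn_lstm")
SHALLOW_KINDS = ("ocsvm", "svm", "adaboost", "random_forest")
NOVELTY_KINDS = ("ocsvm", "mlp_autoencoder")
ALL_KINDS = DEEP_KINDS + SHALLOW_KINDS

AUTOENCODER_INPUT_DIM = 192  # 64-bin spectrum x 3 axes, flattened
SPECTRUM_SHAPE = (64, 3)


@dataclass
class TrainConfig:
    """Training hyper-parameters for the deep detectors."""

    epochs: int = 150
    batch_size: int = 512
    learning_rate: float = 1e-4
    clip_value: float = 1.0
    early_stop_patience: int = 20
    noise_factor: float = 0.2  # denoising autoencoder only
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ContractError("epochs, batch_size and learning_rate must be positive")


def default_config(kind: str, seed: int = 0) -> TrainConfig:
    """Published training regime per model kind."""
    if kind == "mlp_autoencoder":
        return TrainConfig(epochs=250, batch_size=512, seed=seed)
    if kind == "cnn":
        return TrainConfig(epochs=150, batch_size=512, seed=seed)
    if kind == "cnn_lstm":
        return TrainConfig(epochs=150, batch_size=1024, seed=seed)
    return TrainConfig(seed=seed)


@dataclass
class TrainedDetector:
    """A fitted detector plus the state needed to score new windows."""

    kind: str
    model: object
    norm_max: float | None = None  # training-set max for 0-1 scaling
    context_depth: int = 0
    config: Optional[TrainConfig] = None
    meta: dict = field(default_factory=dict)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        if self.norm_max is None:
            return x
        return np.asarray(x, dtype=float) / self.norm_max

    def score(self, features: np.ndarray) -> np.ndarray:
        """Per-row scalar score, higher = more FOG-like."""
        if self.model is None:
            raise StateError("detector has not been trained")
        x = self._normalize(features)
        if self.kind == "mlp_autoencoder":
            return reconstruction_rmse(self.model, x.reshape(x.shape[0], -1))
        if self.kind == "cnn":
            return self.model.predict(x.reshape(x.shape[0], *SPECTRUM_SHAPE)).ravel()
        if self.kind == "cnn_lstm":
            x = x.reshape(x.shape[0], self.context_depth + 1, *SPECTRUM_SHAPE)
            return self.model.predict(x).ravel()
        flat = x.reshape(x.shape[0], -1)
        if self.kind == "ocsvm":
            return -self.model.decision_function(flat)  # outside margin = novel
        if self.kind == "random_forest":
            return self.model.predict_proba(flat)[:, 1]
        return self.model.decision_function(flat)  # svm, adaboost

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return self.score(features)


# ---------------------------------------------------------------------------
# deep architectures


def build_autoencoder(seed: int = 0, output_activation: str = "sigmoid",
                      dtype=nn.core.DTYPE) -> nn.Sequential:
    """Seven-layer dense denoising autoencoder for 192-bin spectra.

    Encoder 192 -> 192 -> 80 -> 40 (tanh), bottleneck 20 (ReLU), decoder
    40 -> 80 -> 192. The output layer defaults to sigmoid so that binary
    cross-entropy on [0, 1]-scaled spectra is well defined; with ``tanh``
    the loss falls back to mean squared error.
    """
    rng = np.random.default_rng(seed)
    layers = [
        nn.Dense(192, 192, "tanh", rng, dtype),
        nn.Dense(192, 80, "tanh", rng, dtype),
        nn.Dense(80, 40, "tanh", rng, dtype),
        nn.Dense(40, 20, "relu", rng, dtype),
        nn.Dense(20, 40, "tanh", rng, dtype),
        nn.Dense(40, 80, "tanh", rng, dtype),
        nn.Dense(80, 192, output_activation, rng, dtype),
    ]
    loss = "bce" if output_activation == "sigmoid" else "mse"
    model = nn.Sequential(layers, loss=loss)
    _assert_output_shape(model, (2, 192), (2, 192))
    return model


def build_cnn(seed: int = 0, dtype=nn.core.DTYPE) -> nn.Sequential:
    """1-D convolutional classifier over a single (64, 3) spectrum.

    Two conv layers (32 filters, kernel 8, ReLU) each followed by pool-2,
    then dense 128 (dropout 0.5), dense 32 (dropout 0.3), sigmoid output.
    """
    rng = np.random.default_rng(seed)
    # 64 -(conv8)-> 57 -(pool)-> 28 -(conv8)-> 21 -(pool)-> 10 x 32 = 320
    layers = [
        nn.Conv1D(3, 32, 8, "relu", rng, dtype),
        nn.MaxPool1D(2),
        nn.Conv1D(32, 32, 8, "relu", rng, dtype),
        nn.MaxPool1D(2),
        nn.Flatten(),
        nn.Dense(320, 128, "relu", rng, dtype),
        nn.Dropout(0.5),
        nn.Dense(128, 32, "relu", rng, dtype),
        nn.Dropout(0.3),
        nn.Dense(32, 1, "sigmoid", rng, dtype),
    ]
    model = nn.Sequential(layers, loss="bce")
    _assert_output_shape(model, (2,) + SPECTRUM_SHAPE, (2, 1))
    return model


def build_cnn_lstm(k: int = 3, seed: int = 0, dtype=nn.core.DTYPE) -> nn.Sequential:
    """Time-distributed CNN feeding an LSTM, for (k+1, 64, 3) stacked spectra.

    The same conv stack (128 then 64 filters, kernel 4, pool 2 each) is
    applied to every time step; an LSTM with 64 cells summarises the
    sequence; dense 80 and 40 (ReLU) lead to a sigmoid output.
    """
    if k < 0:
        raise ContractError(f"context depth must be >= 0, got {k}")
    rng = np.random.default_rng(seed)
    # per step: 64 -(conv4)-> 61 -(pool)-> 30 -(conv4)-> 27 -(pool)-> 13 x 64 = 832
    conv_stack = [
        nn.Conv1D(3, 128, 4, "relu", rng, dtype),
        nn.MaxPool1D(2),
        nn.Conv1D(128, 64, 4, "relu", rng, dtype),
        nn.MaxPool1D(2),
        nn.Flatten(),
    ]
    layers = [
        nn.TimeDistributed(conv_stack),
        nn.LSTM(832, 64, rng, dtype),
        nn.Dense(64, 80, "relu", rng, dtype),
        nn.Dense(80, 40, "relu", rng, dtype),
        nn.Dense(40, 1, "sigmoid", rng, dtype),
    ]
    model = nn.Sequential(layers, loss="bce")
    _assert_output_shape(model, (2, k + 1) + SPECTRUM_SHAPE, (2, 1))
    return model


def _assert_output_shape(model: nn.Sequential, in_shape, out_shape) -> None:
    out = model.forward(np.zeros(in_shape, dtype=np.float32))
    if out.shape != out_shape:
        raise ContractError(
            f"architecture wiring error: {in_shape} -> {out.shape}, "
            f"expected {out_shape}"
        )


def _make_optimizer(kind: str, cfg: TrainConfig) -> nn.Optimizer:
    if kind == "mlp_autoencoder":
        return nn.RMSprop(lr=cfg.learning_rate, clipvalue=cfg.clip_value)
    return nn.Adam(lr=cfg.learning_rate, clipvalue=cfg.clip_value)


# ---------------------------------------------------------------------------
# training entry points


def reconstruction_rmse(model: nn.Sequential, x: np.ndarray) -> np.ndarray:
    """Per-row root-mean-square reconstruction error (the novelty score)."""
    x = np.asarray(x, dtype=float)
    recon = model.predict(x)
    return np.sqrt(((x - recon) ** 2).mean(axis=1))


def train_novelty(model: nn.Sequential, train_features: np.ndarray,
                  cfg: TrainConfig, labels: np.ndarray | None = None) -> TrainedDetector:
    """Fit the denoising autoencoder on non-FOG spectra only.

    ``train_features`` must already exclude FOG rows; passing the matching
    ``labels`` lets the function assert that (any FOG row is a leakage bug).
    Features are scaled to [0, 1] by their maximum, Gaussian noise of sd
    ``cfg.noise_factor`` corrupts each batch, and the clean input is the
    reconstruction target.
    """
    if labels is not None and np.any(np.asarray(labels) == 1):
        raise ContractError("novelty training set contains FOG-labelled rows")
    x = np.asarray(train_features, dtype=float).reshape(len(train_features), -1)
    if x.shape[1] != AUTOENCODER_INPUT_DIM:
        raise ContractError(
            f"autoencoder expects {AUTOENCODER_INPUT_DIM}-dim rows, got {x.shape[1]}"
        )
    norm = float(np.abs(x).max()) or 1.0
    xs = (x / norm).astype(np.float32)
    rng = np.random.default_rng(cfg.seed)
    model.fit(
        xs, xs, _make_optimizer("mlp_autoencoder", cfg),
        epochs=cfg.epochs, batch_size=cfg.batch_size, rng=rng,
        patience=cfg.early_stop_patience, noise_sd=cfg.noise_factor,
    )
    return TrainedDetector("mlp_autoencoder", model, norm_max=norm, config=cfg)


def novelty_score(det: TrainedDetector, features: np.ndarray) -> np.ndarray:
    """Reconstruction RMSE per row; higher = more novel = more FOG-like."""
    if det.kind != "mlp_autoencoder":
        raise ContractError(f"novelty_score expects an autoencoder, got {det.kind}")
    return det.score(features)


def train_supervised_deep(model: nn.Sequential, kind: str, features: np.ndarray,
                          labels: np.ndarray, cfg: TrainConfig,
                          context_depth: int = 0) -> TrainedDetector:
    """Fit the CNN or CNN-LSTM on labelled, max-normalised spectra."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    if len(np.unique(y)) < 2:
        raise ContractError("supervised training needs both classes present")
    norm = float(np.abs(x).max()) or 1.0
    xs = (x / norm).astype(np.float32)
    rng = np.random.default_rng(cfg.seed)
    model.fit(
        xs, y.astype(np.float32), _make_optimizer(kind, cfg),
        epochs=cfg.epochs, batch_size=cfg.batch_size, rng=rng,
        patience=cfg.early_stop_patience,
    )
    return TrainedDetector(kind, model, norm_max=norm,
                           context_depth=context_depth, config=cfg)


def fit_shallow(kind: str, features: np.ndarray,
                labels: np.ndarray | None = None,
                seed: int = 0, **params) -> TrainedDetector:
    """Fit one of the shallow baselines with the published defaults.

    random_forest and adaboost: 100 estimators; svm: RBF kernel, gamma 0.3,
    C 1; ocsvm: linear kernel, trained on non-FOG rows only (labels, when
    given, select them).
    """
    if kind not in SHALLOW_KINDS:
        raise ContractError(f"unknown shallow kind {kind!r}")
    x = np.asarray(features, dtype=float).reshape(len(features), -1)
    if kind == "ocsvm":
        if labels is not None:
            labels = np.asarray(labels)
            x = x[labels == 0]
        model = OneClassSVM(kernel=params.pop("kernel", "linear"), **params)
        model.fit(x)
        return TrainedDetector(kind, model)
    if labels is None:
        raise ContractError(f"{kind} is supervised and needs labels")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ContractError("supervised training needs both classes present")
    if kind == "svm":
        model = SVC(kernel="rbf", gamma=params.pop("gamma", 0.3),
                    C=params.pop("C", 1.0), random_state=seed, **params)
    elif kind == "adaboost":
        model = AdaBoostClassifier(n_estimators=params.pop("n_estimators", 100),
                                   random_state=seed, **params)
    else:
        model = RandomForestClassifier(n_estimators=params.pop("n_estimators", 100),
                                       random_state=seed, n_jobs=1, **params)
    model.fit(x, y)
    return TrainedDetector(kind, model)


def fit_detector(kind: str, features: np.ndarray, labels: np.ndarray,
                 cfg: TrainConfig | None = None, context_depth: int = 0,
                 seed: int = 0) -> TrainedDetector:
    """Uniform training entry point used by the evaluation harness.

    ``features`` are the training-fold rows for the requested kind:
    flattened 192-dim spectra for the autoencoder and shallow models,
    (N, 64, 3) for the CNN, (N, k+1, 64, 3) for the CNN-LSTM.
    Novelty kinds see only the non-FOG rows.
    """
    if kind not in ALL_KINDS:
        raise ContractError(f"unknown detector kind {kind!r}")
    labels = np.asarray(labels)
    if cfg is None:
        cfg = default_config(kind, seed=seed)
    if kind == "mlp_autoencoder":
        x = np.asarray(features).reshape(len(features), -1)
        return train_novelty(build_autoencoder(cfg.seed), x[labels == 0], cfg)
    if kind == "cnn":
        x = np.asarray(features).reshape(len(features), *SPECTRUM_SHAPE)
        return train_supervised_deep(build_cnn(cfg.seed), kind, x, labels, cfg)
    if kind == "cnn_lstm":
        x = np.asarray(features).reshape(
            len(features), context_depth + 1, *SPECTRUM_SHAPE
        )
        return train_supervised_deep(build_cnn_lstm(context_depth, cfg.seed),
                                     kind, x, labels, cfg, context_depth)
    return fit_shallow(kind, features, labels, seed=seed)
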