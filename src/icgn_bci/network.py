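"""Sequence classifiers built on the recurrent cells.

Architecture (shared by all three cell kinds for comparability):

    recurrent layer (uni- or bidirectional, final hidden state)
      -> dropout -> dense ReLU -> dense output (softmax or sigmoid)

Training is plain mini-batch gradient descent through time with an
adaptive-moment (Adam) optimizer by default; everything (initialisation,
shuffling, dropout masks) is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .cells import (
    CellParameters,
    _bptt_batch,
    _unroll_batch,
    init_cell_parameters,
)

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "TrainingHistory",
    "SequenceClassifier",
    "build_classifier",
    "train",
    "predict",
    "hyperparameter_sweep",
]


@dataclass
class NetworkConfig:
    cell_kind: str = "icgn"  # "lstm" | "icgn" | "bilstm"
    recurrent_units: int = 64  # per direction for bilstm
    dropout_rate: float = 0.2
    dense_units: int = 64
    n_classes: int = 2
    output_activation: str = "softmax"  # or "sigmoid"
    window_length: int = 20

    def __post_init__(self) -> None:
        if self.cell_kind not in ("lstm", "icgn", "bilstm"):
            raise ValueError(f"unknown cell_kind {self.cell_kind!r}")
        if self.recurrent_units < 1 or self.dense_units < 1 or self.window_length < 1:
            raise ValueError("units and window_length must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.output_activation not in ("softmax", "sigmoid"):
            raise ValueError("output_activation must be softmax or sigmoid")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    loss: str = "categorical_crossentropy"  # or "mean_squared_error"
    optimizer: str = "adam"  # or "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.loss not in ("categorical_crossentropy", "mean_squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.loss) + 1),
                "loss": self.loss,
                "acc": self.accuracy,
                "val_loss": self.val_loss,
                "val_acc": self.val_accuracy,
            }
        )


class SequenceClassifier:
    """Recurrent feature extractor plus a two-layer dense classification head."""

    def __init__(self, config: NetworkConfig, input_dim: int, seed: int = 0):
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(seed)
        H = config.recurrent_units
        kind = "lstm" if config.cell_kind == "bilstm" else config.cell_kind
        self.cells: list[CellParameters] = [
            init_cell_parameters(kind, input_dim, H, "uniform_scaled", rng)
        ]
        if config.cell_kind == "bilstm":
            self.cells.append(init_cell_parameters(kind, input_dim, H, "uniform_scaled", rng))
        feat = H * len(self.cells)

        def glorot(n_out, n_in):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_out, n_in))

        self.w1 = glorot(config.dense_units, feat)
        self.b1 = np.zeros(config.dense_units)
        self.w2 = glorot(config.n_classes, config.dense_units)
        self.b2 = np.zeros(config.n_classes)

    # -- parameter bookkeeping -------------------------------------------
    def named_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for ci, cell in enumerate(self.cells):
            for name, arr in cell.named_arrays().items():
                out[f"cell{ci}.{name}"] = arr
        out.update({"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2})
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.named_arrays().values()))

    @property
    def feature_dim(self) -> int:
        return self.config.recurrent_units * len(self.cells)

    # -- forward ----------------------------------------------------------
    def _recurrent_features(self, X: np.ndarray, keep_cache: bool = False):
        caches = []
        feats = []
        H_seq, h, _, cache = _unroll_batch(self.cells[0], X, keep_cache=keep_cache)
        feats.append(h)
        caches.append(cache)
        if len(self.cells) == 2:
            Xr = X[:, ::-1, :]
            _, hb, _, cache_b = _unroll_batch(self.cells[1], Xr, keep_cache=keep_cache)
            feats.append(hb)
            caches.append(cache_b)
        return np.concatenate(feats, axis=1), caches

    def _head(self, phi: np.ndarray):
        z1 = phi @ self.w1.T + self.b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.w2.T + self.b2
        if self.config.output_activation == "softmax":
            z = z2 - z2.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
        else:
            p = 1.0 / (1.0 + np.exp(-z2))
        return z1, a1, z2, p

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        phi, _ = self._recurrent_features(X)
        return self._head(phi)[3]

    # -- loss and gradients ----------------------------------------------
    def _loss_and_dz2(self, p: np.ndarray, z2: np.ndarray, y_onehot: np.ndarray, loss: str):
        N = p.shape[0]
        eps = 1e-12
        if loss == "categorical_crossentropy":
            if self.config.output_activation == "softmax":
                value = -np.sum(y_onehot * np.log(p + eps)) / N
                dz2 = (p - y_onehot) / N
            else:  # elementwise binary cross-entropy on sigmoid units
                value = -np.sum(
                    y_onehot * np.log(p + eps) + (1 - y_onehot) * np.log(1 - p + eps)
                ) / N
                dz2 = (p - y_onehot) / N
        else:  # mean squared error on output activations
            value = np.sum((p - y_onehot) ** 2) / N
            dp = 2.0 * (p - y_onehot) / N
            if self.config.output_activation == "softmax":
                s = np.sum(dp * p, axis=1, keepdims=True)
                dz2 = p * (dp - s)
            else:
                dz2 = dp * p * (1.0 - p)
        return float(value), dz2

    def _backward(self, X, caches, phi, mask, z1, a1, dz2):
        grads: dict[str, np.ndarray] = {}
        grads["w2"] = dz2.T @ a1
        grads["b2"] = dz2.sum(0)
        da1 = dz2 @ self.w2
        dz1 = da1 * (z1 > 0)
        grads["w1"] = dz1.T @ (phi * mask if mask is not None else phi)
        grads["b1"] = dz1.sum(0)
        dphi = dz1 @ self.w1
        if mask is not None:
            dphi = dphi * mask
        H = self.config.recurrent_units
        N, T, _ = X.shape
        for ci, cell in enumerate(self.cells):
            dh_final = dphi[:, ci * H : (ci + 1) * H]
            d_hseq = np.zeros((N, T, H))
            cg, _ = _bptt_batch(cell, caches[ci], d_hseq, d_h_final=dh_final)
            for name, g in cg.items():
                grads[f"cell{ci}.{name}"] = g
        return grads

    def loss_and_gradients(
        self,
        X: np.ndarray,
        y: np.ndarray,
        loss: str = "categorical_crossentropy",
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[float, float, dict[str, np.ndarray]]:
        """Mini-batch loss, accuracy and gradients (training mode if rng given)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        k = self.config.n_classes
        if y.min() < 0 or y.max() >= k:
            raise ValueError(f"labels must lie in [0, {k})")
        y_onehot = np.eye(k)[y]
        phi, caches_raw = self._recurrent_features(X, keep_cache=True)
        mask = None
        rate = self.config.dropout_rate
        if dropout_rng is not None and rate > 0:
            mask = (dropout_rng.random(phi.shape) >= rate) / (1.0 - rate)
        phi_d = phi * mask if mask is not None else phi
        z1, a1, z2, p = self._head(phi_d)
        value, dz2 = self._loss_and_dz2(p, z2, y_onehot, loss)
        acc = float(np.mean(p.argmax(axis=1) == y)) * 100.0
        grads = self._backward(X, caches_raw, phi, mask, z1, a1, dz2)
        return value, acc, grads


def build_classifier(config: NetworkConfig, input_dim: int, seed: int = 0) -> SequenceClassifier:
    """Deterministically initialised classifier for ``input_dim`` input channels."""
    if input_dim < 1:
        raise ValueError("input_dim must be positive")
    return SequenceClassifier(config, input_dim, seed)


def _evaluate(model: SequenceClassifier, X, y, loss: str, batch: int = 512) -> tuple[float, float]:
    total, correct, n = 0.0, 0, len(y)
    k = model.config.n_classes
    for s in range(0, n, batch):
        xb, yb = X[s : s + batch], y[s : s + batch]
        phi, _ = model._recurrent_features(np.asarray(xb, dtype=float))
        z1, a1, z2, p = model._head(phi)
        v, _ = model._loss_and_dz2(p, z2, np.eye(k)[yb], loss)
        total += v * len(yb)
        correct += int(np.sum(p.argmax(axis=1) == yb))
    return total / n, 100.0 * correct / n


def train(
    model: SequenceClassifier,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    training_config: TrainingConfig,
) -> tuple[SequenceClassifier, TrainingHistory]:
    """Seeded mini-batch training; records per-epoch loss/accuracy on both sets."""
    X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() >= model.config.n_classes:
        raise ValueError("label outside configured class range")
    cfg = training_config
    rng = np.random.default_rng(cfg.seed)
    params = model.named_arrays()
    if cfg.optimizer == "adam":
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v2 = {k: np.zeros_like(v) for k, v in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
    history = TrainingHistory()
    n = len(X)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_acc, nb = 0.0, 0.0, 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            value, acc, grads = model.loss_and_gradients(
                X[idx], y[idx], loss=cfg.loss, dropout_rng=rng
            )
            if cfg.optimizer == "adam":
                step += 1
                for k_, g in grads.items():
                    m[k_] = b1 * m[k_] + (1 - b1) * g
                    v2[k_] = b2 * v2[k_] + (1 - b2) * g * g
                    mh = m[k_] / (1 - b1**step)
                    vh = v2[k_] / (1 - b2**step)
                    params[k_] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            else:
                for k_, g in grads.items():
                    params[k_] -= cfg.learning_rate * g
            ep_loss += value
            ep_acc += acc
            nb += 1
        history.loss.append(ep_loss / nb)
        history.accuracy.append(ep_acc / nb)
        if val_set is not None and len(val_set[0]) > 0:
            vl, va = _evaluate(model, val_set[0], np.asarray(val_set[1], dtype=int), cfg.loss)
        else:
            vl, va = np.nan, np.nan
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
    return model, history


def predict(model: SequenceClassifier, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels; dropout is never applied at inference."""
    p = model.predict_proba(samples)
    return p, p.argmax(axis=1)


def hyperparameter_sweep(
    grid_spec: dict[str, list],
    dataset: tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    cell_kind: str = "icgn",
    epochs: int = 100,
    n_seeds: int = 1,
    dense_units: int = 64,
    n_classes: int = 2,
) -> pd.DataFrame:
    """Grid search over {units, dropout, lr, loss, batch}; one row per unique combination.

    Returns mean final validation accuracy across ``n_seeds`` repetitions.
    """
    defaults = {
        "units": [64],
        "dropout": [0.2],
        "lr": [0.001],
        "loss": ["categorical_crossentropy"],
        "batch": [32],
    }
    unknown = set(grid_spec) - set(defaults)
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    grid = {k: list(dict.fromkeys(grid_spec.get(k, v))) for k, v in defaults.items()}
    combos = list(product(*grid.values()))
    if not combos:
        raise ValueError("empty grid")
    (Xtr, ytr), (Xva, yva) = dataset
    rows = []
    for units, dropout, lr, loss, batch in combos:
        accs = []
        for rep in range(n_seeds):
            net_cfg = NetworkConfig(
                cell_kind=cell_kind,
                recurrent_units=units,
                dropout_rate=dropout,
                dense_units=dense_units,
                n_classes=n_classes,
            )
            model = build_classifier(net_cfg, Xtr.shape[2], seed=seed + rep)
            tr_cfg = TrainingConfig(
                learning_rate=lr, epochs=epochs, batch_size=batch, loss=loss, seed=seed + rep
            )
            _, hist = train(model, (Xtr, ytr), (Xva, yva), tr_cfg)
            accs.append(hist.val_accuracy[-1])
        rows.append(
            {
                "units": units,
                "dropout": dropout,
                "lr": lr,
                "loss": loss,
                "batch": batch,
                "val_accuracy": float(np.mean(accs)),
            }
        )
    return pd.DataFrame(rows)
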