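"""Feed-forward BMD regressor with a bounded output activation.

A fully connected network (23 inputs, three ReLU hidden layers, one output
unit) maps the regional grayscale features plus weight and area to BMD.
The output activation

    f(x) = 0.55 · tanh(x) + 0.85

compresses the prediction into the open interval (0.3, 1.4) g/cm² — a
biologically plausible BMD range — so the model cannot produce outlandish
densities regardless of its training state. Inputs are z-scored with
statistics computed on the training split only; training is plain
mini-batch SGD on the MSE with early stopping on the validation loss,
restoring the parameters of the best-validation epoch.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from spinebmd.softnet import TrainingError

ACTIVATION_GAIN = 0.55
ACTIVATION_OFFSET = 0.85


@dataclasses.dataclass(frozen=True)
class AnnSpec:
    input_dim: int = 23
    hidden_layers: tuple[int, int, int] = (32, 16, 8)
    learning_rate: float = 0.05
    max_epochs: int = 3000
    patience: int = 50
    min_improvement: float = 1e-5
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) != 3:
            raise ValueError("exactly three hidden layers are required")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclasses.dataclass(frozen=True)
class SplitIndex:
    """Disjoint train/validation id sets at a 4:1 (80/20) ratio."""

    train_ids: tuple
    val_ids: tuple


def relu(x):
    """max(0, x), element-wise."""
    return np.maximum(0.0, x)


def output_activation(x):
    """0.55·tanh(x) + 0.85 — strictly increasing, range (0.3, 1.4)."""
    return ACTIVATION_GAIN * np.tanh(x) + ACTIVATION_OFFSET


def _inverse_output_activation(y):
    return np.arctanh((y - ACTIVATION_OFFSET) / ACTIVATION_GAIN)


def split_dataset(ids, seed: int) -> SplitIndex:
    """Seeded shuffle; first 80% train, remainder validation.

    Rounding ties go to the training set (the train share is ceil(0.8·n)).
    """
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError(f"need at least 5 ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.ceil(0.8 * len(ids)))
    train = tuple(ids[i] for i in order[:n_train])
    val = tuple(ids[i] for i in order[n_train:])
    return SplitIndex(train_ids=train, val_ids=val)


class AnnModel:
    """MLP with ReLU hidden layers and the bounded tanh output head."""

    def __init__(self, spec: AnnSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        dims = (spec.input_dim, *spec.hidden_layers, 1)
        self.weights = []
        self.biases = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            std = np.sqrt(2.0 / d_in)
            self.weights.append(std * rng.standard_normal((d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        # output layer initialized small so initial predictions sit mid-range
        self.weights[-1] *= 0.1
        self.feat_mean = np.zeros(spec.input_dim)
        self.feat_std = np.ones(spec.input_dim)

    def set_standardization(self, mean: np.ndarray, std: np.ndarray) -> None:
        std = np.where(std > 0, std, 1.0)
        self.feat_mean = np.asarray(mean, dtype=np.float64)
        self.feat_std = np.asarray(std, dtype=np.float64)

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        acts = [x]
        h = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = relu(h @ W + b)
            acts.append(h)
        z = h @ self.weights[-1] + self.biases[-1]
        y = output_activation(z)
        if want_cache:
            return y, z, acts
        return y

    def predict(self, features: np.ndarray) -> np.ndarray:
        """BMD predictions, g/cm², for raw (unstandardized) feature rows."""
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} features, got {features.shape[1]}"
            )
        x = (features - self.feat_mean) / self.feat_std
        return self._forward(x)[:, 0]

    def parameters(self):
        return list(self.weights) + list(self.biases)

    def _gradients(self, x, target):
        """Backprop of the batch MSE through the bounded head and ReLU stack."""
        y, z, acts = self._forward(x, want_cache=True)
        n = x.shape[0]
        dz = (2.0 / (n)) * (y - target) * ACTIVATION_GAIN * (1.0 - np.tanh(z) ** 2)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        d = dz
        for layer in reversed(range(len(self.weights))):
            grads_w[layer] = acts[layer].T @ d
            grads_b[layer] = d.sum(axis=0)
            if layer > 0:
                d = (d @ self.weights[layer].T) * (acts[layer] > 0)
        loss = float(np.mean((y - target) ** 2))
        return loss, grads_w, grads_b


def predict_bmd(model: AnnModel, features: np.ndarray):
    """Scalar BMD for one 23-element vector, or a vector for a feature matrix."""
    features = np.asarray(features, dtype=np.float64)
    single = features.ndim == 1
    out = model.predict(features)
    return float(out[0]) if single else out


def train_ann(
    features: np.ndarray,
    targets: np.ndarray,
    spec: AnnSpec,
    split: SplitIndex,
) -> tuple[AnnModel, list[tuple[float, float]]]:
    """Fit the regressor with early stopping on the validation loss.

    ``features`` rows are indexed by the positions in ``split``; they are
    z-scored internally using training-split statistics only. Training
    halts when the best validation MSE has not improved by more than
    ``spec.min_improvement`` for ``spec.patience`` consecutive epochs, and
    the parameters from the best-validation epoch are restored.

    Returns the model and the per-epoch (train_mse, val_mse) history.
    """
    features = np.asarray(features, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    lo = ACTIVATION_OFFSET - ACTIVATION_GAIN
    hi = ACTIVATION_OFFSET + ACTIVATION_GAIN
    if np.any(targets <= lo) or np.any(targets >= hi):
        raise ValueError(
            f"targets must lie strictly inside the activation range ({lo}, {hi})"
        )
    train_idx = np.asarray(split.train_ids, dtype=int)
    val_idx = np.asarray(split.val_ids, dtype=int)

    model = AnnModel(spec)
    model.set_standardization(
        features[train_idx].mean(axis=0), features[train_idx].std(axis=0)
    )
    x_train = (features[train_idx] - model.feat_mean) / model.feat_std
    y_train = targets[train_idx][:, None]
    x_val = (features[val_idx] - model.feat_mean) / model.feat_std
    y_val = targets[val_idx][:, None]

    rng = np.random.default_rng(spec.seed + 1)
    history: list[tuple[float, float]] = []
    best_val = np.inf
    best_params = None
    stale = 0
    for _epoch in range(spec.max_epochs):
        order = rng.permutation(len(x_train))
        train_loss = 0.0
        for start in range(0, len(x_train), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            loss, gw, gb = model._gradients(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged: loss={loss}")
            train_loss += loss * len(idx)
            for layer in range(len(model.weights)):
                model.weights[layer] -= spec.learning_rate * gw[layer]
                model.biases[layer] -= spec.learning_rate * gb[layer]
        train_mse = train_loss / len(x_train)
        val_pred = model._forward(x_val)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        history.append((train_mse, val_mse))
        if val_mse < best_val - spec.min_improvement:
            best_val = val_mse
            best_params = (
                [w.copy() for w in model.weights],
                [b.copy() for b in model.biases],
            )
            stale = 0
        else:
            stale += 1
            if stale >= spec.patience:
                break
    if best_params is not None:
        model.weights, model.biases = best_params
    return model, history


def save_checkpoint(model: AnnModel, path: str | Path) -> None:
    """Archive of parameters, spec and training-set standardization stats."""
    meta = json.dumps(dataclasses.asdict(model.spec))
    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    arrays["feat_mean"] = model.feat_mean
    arrays["feat_std"] = model.feat_std
    np.savez(path, __spec__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> AnnModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__spec__"]).decode())
        meta["hidden_layers"] = tuple(meta["hidden_layers"])
        model = AnnModel(AnnSpec(**meta))
        n_layers = len(model.weights)
        model.weights = [archive[f"W{i}"] for i in range(n_layers)]
        model.biases = [archive[f"b{i}"] for i in range(n_layers)]
        model.feat_mean = archive["feat_mean"]
        model.feat_std = archive["feat_std"]
    return model
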