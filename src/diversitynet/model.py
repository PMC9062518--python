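"""Fully connected regression networks for diversity estimation.

One small multilayer perceptron is trained per diversity metric: ReLU hidden
layers with optional dropout, a single softplus output unit (diversity is
strictly positive but unbounded above), mean-absolute-error loss on rescaled
labels, minibatch Adam. Model selection runs a fixed grid of
{feature set} × {architecture} × {dropout} combinations, scores each on
test-set MAPE, and the winning configuration is retrained on all data as an
ensemble of independently seeded networks whose spread gives per-prediction
uncertainty.

The implementation is plain numpy with hand-written backpropagation: the
networks are tiny (tens of nodes), so a deep-learning framework would buy
nothing but a heavyweight dependency, while explicit code keeps bit-level
reproducibility under a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Hidden-layer architectures explored in model selection.
ARCHITECTURES: tuple[tuple[int, ...], ...] = ((30,), (30, 5), (30, 15, 5), (30, 20, 10, 5))
#: Dropout fractions explored in model selection.
DROPOUT_RATES: tuple[float, ...] = (0.0, 0.1, 0.3)
#: Named feature sets explored in model selection.
FEATURE_SET_NAMES: tuple[str, ...] = ("full27", "subset8", "subset6")

#: Label rescaling applied before training so targets fall roughly in [0, 1]:
#: alpha richness divided by 100, gamma richness by 800, beta already in [0, 1].
LABEL_SCALES: dict[str, float] = {"alpha": 1 / 100, "beta": 1.0, "gamma": 1 / 800}

DEFAULT_BATCH_SIZE = 40


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + training hyperparameters of one network."""

    metric: str
    feature_set: str
    hidden_layers: tuple[int, ...]
    dropout: float = 0.0
    label_scale: float | None = None
    batch_size: int = DEFAULT_BATCH_SIZE
    max_epochs: int = 2000
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.metric not in LABEL_SCALES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")
        if self.label_scale is None:
            object.__setattr__(self, "label_scale", LABEL_SCALES[self.metric])
        if self.label_scale <= 0:
            raise ValueError("label_scale must be positive")
        object.__setattr__(self, "hidden_layers", tuple(int(w) for w in self.hidden_layers))


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test row indices (60 / 20 / 20)."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


@dataclass
class TrainingHistory:
    """Per-epoch MAE on scaled labels for the training and validation sets."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    chosen_epoch: int | None = None

    def __len__(self) -> int:
        return len(self.train_loss)


def split_data(n: int, seed: int) -> DataSplit:
    """Random 60/20/20 split: test and validation each get ``floor(0.2 n)``.

    For the 7,896-plot training corpus this yields 1,579 test, 1,579
    validation and 4,738 training instances.
    """
    if n < 5:
        raise ValueError("need at least 5 instances for a 60/20/20 split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = int(math.floor(0.2 * n))
    if n_hold == 0:
        raise ValueError("n too small for non-empty partitions")
    return DataSplit(
        test=np.sort(perm[:n_hold]),
        validation=np.sort(perm[n_hold:2 * n_hold]),
        train=np.sort(perm[2 * n_hold:]),
    )


def scale_labels(values, label_scale: float):
    """Multiply diversity labels by the metric's scaling factor."""
    if label_scale <= 0:
        raise ValueError("label_scale must be positive")
    return np.asarray(values, dtype=float) * label_scale


def unscale_labels(values, label_scale: float):
    """Inverse of :func:`scale_labels` (divide by the factor)."""
    if label_scale <= 0:
        raise ValueError("label_scale must be positive")
    return np.asarray(values, dtype=float) / label_scale


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPRegressor:
    """Fully connected net: ReLU hidden layers + dropout, softplus output.

    Weights use seeded He-uniform (fan-in) initialization; optimization is
    Adam on the mean absolute error of the (scaled) labels. All randomness —
    initialization, minibatch shuffling, dropout masks — flows from the
    config seed, so two networks built from identical configs are
    bit-identical.
    """

    def __init__(self, layer_sizes: Sequence[int], dropout: float = 0.0,
                 seed: int = 0, learning_rate: float = 1e-3):
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.dropout = float(dropout)
        self.seed = int(seed)
        self.learning_rate = float(learning_rate)
        self.rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            limit = math.sqrt(6.0 / fan_in)
            self.weights.append(self.rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, X: np.ndarray, training: bool = False):
        """Forward pass; returns (output, cache-for-backprop)."""
        a = np.asarray(X, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        cache = {"a": [a], "z": [], "masks": []}
        n_layers = len(self.weights)
        for ell in range(n_layers):
            z = a @ self.weights[ell] + self.biases[ell]
            cache["z"].append(z)
            if ell < n_layers - 1:
                a = np.maximum(z, 0.0)
                if training and self.dropout > 0.0:
                    keep = 1.0 - self.dropout
                    mask = (self.rng.random(a.shape) < keep) / keep
                    a = a * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                a = _softplus(z)
            cache["a"].append(a)
        return a[:, 0], cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluation-mode predictions (dropout disabled); strictly positive."""
        out, _ = self.forward(X, training=False)
        return out

    def _backward(self, cache, y: np.ndarray):
        """Gradients of mean |softplus(z) − y| w.r.t. all weights and biases."""
        n = len(y)
        y_hat = cache["a"][-1][:, 0]
        z_out = cache["z"][-1]
        # d MAE / d y_hat = sign(residual) / n ; d softplus / d z = sigmoid(z)
        delta = (np.sign(y_hat - y)[:, None] / n) * _sigmoid(z_out)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        for ell in range(len(self.weights) - 1, -1, -1):
            a_prev = cache["a"][ell]
            grads_w[ell] = a_prev.T @ delta
            grads_b[ell] = delta.sum(axis=0)
            if ell > 0:
                delta = delta @ self.weights[ell].T
                mask = cache["masks"][ell - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (cache["z"][ell - 1] > 0)
        return grads_w, grads_b

    def _adam_step(self, grads_w, grads_b, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self.weights + self.biases
        grads = grads_w + grads_b
        lr_t = self.learning_rate * math.sqrt(1 - beta2 ** self._adam_t) / (
            1 - beta1 ** self._adam_t)
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + eps)

    def train_epoch(self, X: np.ndarray, y: np.ndarray, batch_size: int) -> float:
        """One pass of minibatch Adam; returns the mean minibatch MAE."""
        n = len(y)
        order = self.rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            out, cache = self.forward(X[idx], training=True)
            loss = float(np.mean(np.abs(out - y[idx])))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at Adam step {self._adam_t}")
            losses.append(loss)
            grads_w, grads_b = self._backward(cache, y[idx])
            self._adam_step(grads_w, grads_b)
        return float(np.mean(losses))

    # --- serialization -------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "dropout": self.dropout,
            "seed": self.seed,
            "learning_rate": self.learning_rate,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLPRegressor":
        net = cls(state["layer_sizes"], state["dropout"], state["seed"],
                  state["learning_rate"])
        net.weights = [np.array(w, dtype=float) for w in state["weights"]]
        net.biases = [np.array(b, dtype=float) for b in state["biases"]]
        return net


def build_network(config: ModelConfig, n_features: int) -> MLPRegressor:
    """Instantiate the network for a config; layer sizes are
    input → hidden layers → 1 softplus output."""
    from .features import FEATURE_SETS

    expected = len(FEATURE_SETS.get(config.feature_set, ()))
    if expected and n_features != expected:
        raise ValueError(
            f"feature set {config.feature_set!r} has {expected} features, "
            f"got {n_features}")
    sizes = (n_features,) + config.hidden_layers + (1,)
    return MLPRegressor(sizes, dropout=config.dropout, seed=config.seed,
                        learning_rate=config.learning_rate)


def train_model(network: MLPRegressor, X_train, y_train, X_val, y_val,
                config: ModelConfig, n_epochs: int | None = None) -> TrainingHistory:
    """Train for ``n_epochs`` (default ``config.max_epochs``) recording per-epoch
    training and validation MAE on scaled labels.

    Labels are passed on the original diversity scale and rescaled internally
    by ``config.label_scale``. Validation loss is evaluated with dropout
    disabled. Fully reproducible given the network's seed.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    yt = scale_labels(y_train, config.label_scale)
    yv = scale_labels(y_val, config.label_scale)
    if len(yt) == 0 or len(yv) == 0:
        raise ValueError("train and validation sets must be non-empty")
    history = TrainingHistory()
    epochs = config.max_epochs if n_epochs is None else n_epochs
    for _ in range(epochs):
        train_loss = network.train_epoch(X_train, yt, config.batch_size)
        val_pred = network.predict(X_val)
        val_loss = float(np.mean(np.abs(val_pred - yv)))
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
    return history


def select_epoch(history: TrainingHistory) -> int:
    """Best-validation epoch rounded to the nearest multiple of 50 (min 50).

    Epochs are 1-based; ties in validation loss break toward the earlier
    epoch, and rounding uses the round-half-up convention.
    """
    if len(history) == 0:
        raise ValueError("empty training history")
    best = int(np.argmin(history.val_loss)) + 1
    rounded = int(math.floor(best / 50.0 + 0.5)) * 50
    return max(50, rounded)


def mape(predictions, truth, return_n_excluded: bool = False):
    """Mean absolute percentage error, ``100 · mean(|pred − truth| / truth)``.

    Instances with zero truth (where the quantity is undefined) are excluded;
    pass ``return_n_excluded=True`` to also get their count.
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truth, dtype=float)
    keep = true != 0
    n_excluded = int((~keep).sum())
    if not np.any(keep):
        raise ValueError("all truth values are zero; MAPE undefined")
    value = float(100.0 * np.mean(np.abs(pred[keep] - true[keep]) / true[keep]))
    return (value, n_excluded) if return_n_excluded else value


def grid_configs(metric: str,
                 feature_sets: Sequence[str] = FEATURE_SET_NAMES,
                 architectures: Sequence[tuple[int, ...]] = ARCHITECTURES,
                 dropout_rates: Sequence[float] = DROPOUT_RATES,
                 n_epochs: int = 500,
                 base_seed: int = 0,
                 batch_size: int = DEFAULT_BATCH_SIZE) -> list[ModelConfig]:
    """Enumerate the model-selection grid (default 3 × 4 × 3 = 36 configs)."""
    configs = []
    idx = 0
    for fs in feature_sets:
        for arch in architectures:
            for p in dropout_rates:
                configs.append(ModelConfig(
                    metric=metric, feature_set=fs, hidden_layers=tuple(arch),
                    dropout=float(p), max_epochs=n_epochs, seed=base_seed + idx,
                    batch_size=batch_size))
                idx += 1
    return configs


def grid_search(metric: str,
                feature_tables: dict[str, np.ndarray],
                labels: np.ndarray,
                split: DataSplit,
                feature_sets: Sequence[str] = FEATURE_SET_NAMES,
                architectures: Sequence[tuple[int, ...]] = ARCHITECTURES,
                dropout_rates: Sequence[float] = DROPOUT_RATES,
                n_epochs: int = 500,
                base_seed: int = 0,
                batch_size: int = DEFAULT_BATCH_SIZE) -> pd.DataFrame:
    """Train every (feature set × architecture × dropout) combination and rank
    by test-set MAPE (ascending).

    ``feature_tables`` maps feature-set name to the full scaled feature matrix
    (all rows; the split selects train/validation/test rows). The default grid
    is 3 × 4 × 3 = 36 configurations. Returns a DataFrame with columns
    Features, Nodes, Dropout, MAPE, chosen_epoch, val_loss.
    """
    labels = np.asarray(labels, dtype=float)
    for fs in feature_sets:
        if fs not in feature_tables:
            raise ValueError(f"feature table missing for set {fs!r}")
    rows = []
    for config in grid_configs(metric, feature_sets, architectures, dropout_rates,
                               n_epochs, base_seed, batch_size):
        X = np.asarray(feature_tables[config.feature_set], dtype=float)
        net = build_network(config, X.shape[1])
        history = train_model(
            net, X[split.train], labels[split.train],
            X[split.validation], labels[split.validation], config)
        chosen = select_epoch(history)
        pred = unscale_labels(net.predict(X[split.test]), config.label_scale)
        rows.append({
            "Features": X.shape[1],
            "FeatureSet": config.feature_set,
            "Nodes": ", ".join(str(w) for w in config.hidden_layers),
            "Dropout": config.dropout,
            "MAPE": mape(pred, labels[split.test]),
            "chosen_epoch": chosen,
            "val_loss": float(np.min(history.val_loss)),
            "seed": config.seed,
        })
    table = pd.DataFrame(rows).sort_values("MAPE", kind="stable").reset_index(drop=True)
    return table


@dataclass
class Ensemble:
    """A bag of independently seeded networks trained with one configuration."""

    config: ModelConfig
    chosen_epoch: int
    members: list[MLPRegressor]
    feature_scaler: dict[str, tuple[float, float]] | None = None

    def predict_members(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_rows) member predictions on the diversity scale."""
        X = np.asarray(X, dtype=float)
        preds = np.stack([m.predict(X) for m in self.members])
        return unscale_labels(preds, self.config.label_scale)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "chosen_epoch": self.chosen_epoch,
            "n_members": len(self.members),
            "feature_scaler": self.feature_scaler,
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
        for i, member in enumerate(self.members):
            (directory / f"member_{i:03d}.json").write_text(
                json.dumps(member.state_dict()))
        return directory

    @classmethod
    def load(cls, directory) -> "Ensemble":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        cfg = meta["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        config = ModelConfig(**cfg)
        members = [
            MLPRegressor.from_state_dict(
                json.loads((directory / f"member_{i:03d}.json").read_text()))
            for i in range(meta["n_members"])
        ]
        scaler = meta.get("feature_scaler")
        if scaler is not None:
            scaler = {k: tuple(v) for k, v in scaler.items()}
        return cls(config=config, chosen_epoch=meta["chosen_epoch"],
                   members=members, feature_scaler=scaler)


def train_production_ensemble(config: ModelConfig, chosen_epoch: int,
                              X_all, y_all, n_members: int = 50,
                              base_seed: int | None = None,
                              feature_scaler=None) -> Ensemble:
    """Retrain the winning configuration on *all* data as an ensemble.

    Each member gets seed ``base_seed + index`` and trains for exactly
    ``chosen_epoch`` epochs (the early-stopping point found during model
    selection); no validation split is held out.
    """
    if chosen_epoch <= 0:
        raise ValueError("chosen_epoch must be positive")
    X_all = np.asarray(X_all, dtype=float)
    y_scaled = scale_labels(y_all, config.label_scale)
    if base_seed is None:
        base_seed = config.seed
    members = []
    for i in range(n_members):
        member_cfg = ModelConfig(
            metric=config.metric, feature_set=config.feature_set,
            hidden_layers=config.hidden_layers, dropout=config.dropout,
            label_scale=config.label_scale, batch_size=config.batch_size,
            max_epochs=chosen_epoch, seed=base_seed + i,
            learning_rate=config.learning_rate,
        )
        net = build_network(member_cfg, X_all.shape[1])
        for _ in range(chosen_epoch):
            net.train_epoch(X_all, y_scaled, member_cfg.batch_size)
        members.append(net)
    return Ensemble(config=config, chosen_epoch=chosen_epoch, members=members,
                    feature_scaler=feature_scaler)
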