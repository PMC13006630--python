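"""Fully connected regression network and its training protocol.

The model maps a 91-dimensional standardized input (88 daily gait
measures + age, sex, BMI) to a single sigmoid output, the MDS-UPDRS III
score scaled to [0, 1]. The default architecture is

    input(91) -> GaussianNoise(sd 0.6)
              -> Dense(272, ReLU) -> Dropout(0.5)
              -> Dense(152, ReLU) -> Dropout(0.5)
              -> Dense(70,  ReLU) -> Dropout(0.5)
              -> Dense(1, sigmoid)

for exactly 77,301 trainable parameters. Training uses Adam on a mean
squared error loss (optionally per-sample weighted), with early stopping:
the monitored set's MAE is evaluated after every epoch (and at epoch 0,
before any update) with the stochastic layers disabled, training stops
after `patience` epochs without improvement or at `max_epochs`, and the
weights of the best monitored epoch are returned (rollback). Input noise
and dropout are active only during weight updates, never at evaluation,
so prediction is a pure function of (weights, X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "Dense",
    "Dropout",
    "GaussianNoise",
    "NetworkSpec",
    "ModelWeights",
    "TrainingConfig",
    "default_network_spec",
    "count_trainable",
    "init_weights",
    "train",
    "predict",
]


@dataclass(frozen=True)
class Dense:
    units: int
    activation: str = "relu"  # "relu" | "sigmoid" | "linear"


@dataclass(frozen=True)
class Dropout:
    rate: float = 0.5


@dataclass(frozen=True)
class GaussianNoise:
    sd: float = 0.6


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer description; only Dense layers carry parameters."""

    input_width: int = 91
    layers: tuple = (
        GaussianNoise(0.6),
        Dense(272), Dropout(0.5),
        Dense(152), Dropout(0.5),
        Dense(70), Dropout(0.5),
        Dense(1, "sigmoid"),
    )

    def dense_shapes(self) -> list[tuple[int, int]]:
        shapes, fan_in = [], self.input_width
        for layer in self.layers:
            if isinstance(layer, Dense):
                shapes.append((fan_in, layer.units))
                fan_in = layer.units
        return shapes


def default_network_spec() -> NetworkSpec:
    return NetworkSpec()


def count_trainable(spec: NetworkSpec) -> int:
    """Total trainable parameters: sum of (fan_in + 1) * fan_out over Dense."""
    return sum((fi + 1) * fo for fi, fo in spec.dense_shapes())


@dataclass
class ModelWeights:
    """Per-layer weight matrices and bias vectors, flattenable for exchange.

    The flat vector (concatenation of W1, b1, W2, b2, ...) is the object a
    federated client transmits; the shape manifest ties it back to a spec.
    """

    arrays: list[np.ndarray]

    @property
    def shapes(self) -> list[tuple[int, ...]]:
        return [a.shape for a in self.arrays]

    def to_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.arrays])

    @classmethod
    def from_flat(cls, flat: np.ndarray, shapes) -> "ModelWeights":
        arrays, i = [], 0
        for shape in shapes:
            size = int(np.prod(shape))
            arrays.append(np.asarray(flat[i : i + size], dtype=float).reshape(shape))
            i += size
        if i != len(flat):
            raise ValueError("flat vector length does not match shape manifest")
        return cls(arrays)

    def copy(self) -> "ModelWeights":
        return ModelWeights([a.copy() for a in self.arrays])

    def save(self, path) -> None:
        np.savez(path, **{f"arr{i}": a for i, a in enumerate(self.arrays)})

    @classmethod
    def load(cls, path) -> "ModelWeights":
        with np.load(path) as data:
            return cls([data[f"arr{i}"] for i in range(len(data.files))])


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 150
    patience: int = 20
    batch_size: int = 32
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate < 0 or self.max_epochs < 0 or self.patience < 0:
            raise ValueError("negative training hyperparameter")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def init_weights(spec: NetworkSpec, seed: int) -> ModelWeights:
    """Glorot-uniform kernels with zero biases (the framework default for
    dense layers, and deliberately small so the sigmoid output starts well
    away from saturation)."""
    rng = np.random.default_rng(seed)
    arrays = []
    for fan_in, fan_out in spec.dense_shapes():
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        arrays.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        arrays.append(np.zeros(fan_out))
    return ModelWeights(arrays)


def _forward(spec, weights, X, training, rng):
    """Forward pass; returns output and, in training mode, layer caches."""
    a = np.asarray(X)
    caches = []
    dense_i = 0
    for layer in spec.layers:
        if isinstance(layer, GaussianNoise):
            if training and layer.sd > 0:
                if a.dtype == np.float32:
                    a = a + layer.sd * rng.standard_normal(a.shape, dtype=np.float32)
                else:
                    a = a + rng.normal(0.0, layer.sd, size=a.shape)
        elif isinstance(layer, Dropout):
            if training and layer.rate > 0:
                keep = rng.random(a.shape) >= layer.rate
                a = a * keep / (1.0 - layer.rate)
                caches.append(("dropout", keep, layer.rate))
            elif training:
                caches.append(("dropout", None, 0.0))
        else:  # Dense
            W = weights.arrays[2 * dense_i]
            b = weights.arrays[2 * dense_i + 1]
            z = a @ W + b
            if layer.activation == "relu":
                out = np.maximum(z, 0.0)
            elif layer.activation == "sigmoid":
                out = expit(z)
            else:
                out = z
            if training:
                caches.append(("dense", a, out, layer.activation, dense_i))
            a = out
            dense_i += 1
    return (a, caches) if training else a


def _backward(spec, weights, caches, grad_out, grads):
    """Backprop through cached layers, writing into per-array ``grads``."""
    g = grad_out
    for cache in reversed(caches):
        if cache[0] == "dropout":
            _, keep, rate = cache
            if keep is not None:
                g = g * keep / (1.0 - rate)
        else:
            _, a_in, out, activation, di = cache
            if activation == "relu":
                g = g * (out > 0)
            elif activation == "sigmoid":
                g = g * out * (1.0 - out)
            W = weights.arrays[2 * di]
            np.matmul(a_in.T, g, out=grads[2 * di])
            np.sum(g, axis=0, out=grads[2 * di + 1])
            g = g @ W.T
    return grads


def train(
    weights: ModelWeights,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    spec: NetworkSpec | None = None,
    monitor: tuple[np.ndarray, np.ndarray] | None = None,
    sample_weight: np.ndarray | None = None,
):
    """Train a copy of ``weights``; return (best weights, history frame).

    ``monitor`` is the (X, y) pair whose MAE drives early stopping and
    rollback; when omitted the training set itself is monitored (the
    federated local-training protocol). ``sample_weight`` multiplies each
    sample's squared-error contribution (the 4:1 own-vs-shared weighting
    during client-side personalisation). Targets must already be on the
    [0, 1] scale. Epoch 0 (the incoming weights, untouched) is always a
    rollback candidate, so training can never worsen the monitored MAE.
    """
    spec = spec or default_network_spec()
    # single-precision internals: the training loop is matmul-bound and
    # float32 gradients are ample for this loss surface
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32).reshape(-1)
    if len(X) == 0:
        raise ValueError("empty training set")
    if X.shape[1] != spec.input_width:
        raise ValueError(
            f"feature count {X.shape[1]} != spec input width {spec.input_width}"
        )
    if sample_weight is not None:
        sample_weight = np.asarray(sample_weight, dtype=np.float32).reshape(-1)
        if (sample_weight <= 0).any():
            raise ValueError("sample weights must be positive")

    mon_X, mon_y = (X, y) if monitor is None else monitor
    mon_X = np.asarray(mon_X, dtype=np.float32)
    mon_y = np.asarray(mon_y, dtype=np.float32).reshape(-1)

    rng = np.random.default_rng(config.seed)
    # all parameters live in one flat float32 vector; the layer arrays are
    # views into it, so the Adam update is a handful of vectorized ops
    shapes = [a.shape for a in weights.arrays]
    theta = np.concatenate(
        [a.ravel() for a in weights.arrays]
    ).astype(np.float32)
    views, grad_flat = [], np.zeros_like(theta)
    grad_views, i0 = [], 0
    for shape in shapes:
        size = int(np.prod(shape))
        views.append(theta[i0 : i0 + size].reshape(shape))
        grad_views.append(grad_flat[i0 : i0 + size].reshape(shape))
        i0 += size
    w = ModelWeights(views)
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    t = 0
    beta1, beta2 = np.float32(config.beta1), np.float32(config.beta2)

    def monitored_mae():
        pred = _forward(spec, w, mon_X, training=False, rng=None).reshape(-1)
        return float(np.mean(np.abs(pred - mon_y)))

    best_mae = monitored_mae()
    best_theta = theta.copy()
    best_epoch = 0
    history = [{"epoch": 0, "train_mse": np.nan, "monitor_mae": best_mae}]
    since_best = 0

    n = len(X)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_sse, epoch_wsum = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            wb = sample_weight[idx] if sample_weight is not None else None
            out, caches = _forward(spec, w, xb, training=True, rng=rng)
            resid = out.reshape(-1) - yb
            if wb is None:
                wsum = float(len(idx))
                grad_out = (2.0 * resid / wsum).reshape(-1, 1)
                epoch_sse += float(np.sum(resid**2))
            else:
                wsum = float(wb.sum())
                grad_out = (2.0 * wb * resid / wsum).reshape(-1, 1)
                epoch_sse += float(np.sum(wb * resid**2))
            epoch_wsum += wsum
            _backward(spec, w, caches, grad_out, grad_views)
            t += 1
            lr_t = np.float32(
                config.learning_rate
                * np.sqrt(1.0 - config.beta2**t)
                / (1.0 - config.beta1**t)
            )
            m += (1.0 - beta1) * (grad_flat - m)
            v += (1.0 - beta2) * (grad_flat * grad_flat - v)
            theta -= lr_t * m / (np.sqrt(v) + np.float32(config.eps))
        mae = monitored_mae()
        history.append(
            {"epoch": epoch, "train_mse": epoch_sse / epoch_wsum, "monitor_mae": mae}
        )
        if mae < best_mae:
            best_mae, best_epoch = mae, epoch
            np.copyto(best_theta, theta)
            since_best = 0
        else:
            since_best += 1
            if since_best >= max(config.patience, 1):
                break
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    best_w = ModelWeights.from_flat(best_theta.astype(float), shapes)
    return best_w, hist


def predict(weights: ModelWeights, X: np.ndarray, spec: NetworkSpec | None = None):
    """Deterministic evaluation-mode prediction; outputs in (0, 1)."""
    spec = spec or default_network_spec()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.input_width:
        raise ValueError(
            f"expected 2-D input with {spec.input_width} features, got {X.shape}"
        )
    return _forward(spec, weights, X, training=False, rng=None).reshape(-1)
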