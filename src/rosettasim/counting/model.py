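"""Leaf-count regression networks and their training loop.

Two architectures are provided.  The *small* network stacks three 5x5
convolutions (stride 1), each followed by 3x3 max pooling with stride 2,
and regresses the count directly from the flattened features.  The *large*
network uses four convolution + pooling stages and a 1024-unit fully
connected layer before the scalar output.  tanh follows every convolution
and the fully connected layer.  Training minimizes mean squared count
error plus an L2 weight penalty (default λ = 1e-4) at a static learning
rate of 1e-3, with mini-batch Adam by default.

Filter counts per stage are not architectural constants of the problem and
are configurable; defaults are (32, 64, 64) and (32, 64, 64, 128).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ..dataset import DatasetManifest, load_arrays
from .augment import augment_batch
from .metrics import EvalMetrics, compute_metrics
from .nn import SGD, Adam, Conv2D, Dense, Flatten, MaxPool2D, Sequential, Tanh

__all__ = ["CounterConfig", "LeafCounter", "build_counter", "train", "predict", "evaluate"]

_DEFAULT_FILTERS = {"small": (32, 64, 64), "large": (32, 64, 64, 128)}


@dataclass(frozen=True)
class CounterConfig:
    architecture: str = "small"
    input_size: int = 256  # 128 is a fast mode; inputs are resized on load
    filters: Optional[tuple] = None  # per-conv-layer counts; None = architecture default
    fc_units: int = 1024  # large architecture only
    weight_decay: float = 1e-4
    learning_rate: float = 1e-3  # static
    batch_size: int = 32
    epochs: int = 100
    patience: int = 20  # early stopping on held-out loss; <=0 disables
    split_fraction: float = 0.8
    augment: bool = True
    flips: bool = True
    crop_fraction: float = 0.10
    brightness: bool = True
    contrast: bool = True
    optimizer: str = "adam"  # or "sgd"
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in _DEFAULT_FILTERS:
            raise ValueError(f"unknown architecture {self.architecture!r}; use 'small' or 'large'")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not (0 < self.crop_fraction < 1):
            raise ValueError("crop_fraction must be in (0, 1)")

    @property
    def filter_counts(self) -> tuple:
        return self.filters if self.filters is not None else _DEFAULT_FILTERS[self.architecture]


@dataclass
class LeafCounter:
    config: CounterConfig
    net: Sequential

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.net.forward(x[i:i + batch_size].astype(np.float32))[:, 0])
        return np.concatenate(out)

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_counter(cfg: CounterConfig) -> LeafCounter:
    """Construct a freshly initialized counter (weights seeded by cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    shape = (cfg.input_size, cfg.input_size, 3)
    c_in = 3
    for c_out in cfg.filter_counts:
        conv = Conv2D(c_in, c_out, 5, rng)
        pool = MaxPool2D(3, 2)
        layers += [conv, Tanh(), pool]
        shape = pool.out_shape(conv.out_shape(shape))
        c_in = c_out
    flat = Flatten()
    layers.append(flat)
    (dim,) = flat.out_shape(shape)
    if cfg.architecture == "large":
        layers += [Dense(dim, cfg.fc_units, rng), Tanh(), Dense(cfg.fc_units, 1, rng)]
    else:
        layers.append(Dense(dim, 1, rng))
    return LeafCounter(cfg, Sequential(layers))


DataLike = Union[DatasetManifest, tuple]


def _as_arrays(data: DataLike, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, DatasetManifest):
        return load_arrays(data, image_size=input_size)
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    if x.shape[1] != input_size:
        raise ValueError(f"images are {x.shape[1]}px but the model expects {input_size}px")
    return x, np.asarray(y, dtype=np.float32)


def train(
    model: LeafCounter,
    train_data: DataLike,
    cfg: Optional[CounterConfig] = None,
    val_data: Optional[DataLike] = None,
) -> dict:
    """Train in place; returns a history dict with per-epoch losses.

    ``train_data`` is a dataset manifest or an ``(images, labels)`` pair.
    Held-out loss is tracked on ``val_data`` when given (otherwise on the
    training data) and drives early stopping when ``cfg.patience > 0``.
    """
    cfg = cfg or model.config
    x, y = _as_arrays(train_data, cfg.input_size)
    if len(x) == 0:
        raise ValueError("training data is empty")
    xv, yv = _as_arrays(val_data, cfg.input_size) if val_data is not None else (x, y)

    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.optimizer == "adam":
        opt = Adam(model.net, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    elif cfg.optimizer == "sgd":
        opt = SGD(model.net, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    since_best = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = x[idx]
            if cfg.augment:
                xb = augment_batch(xb, rng, flips=cfg.flips, crop_fraction=cfg.crop_fraction,
                                   brightness=cfg.brightness, contrast=cfg.contrast)
            yb = y[idx]
            pred = model.net.forward(xb, train=True)[:, 0]
            err = pred - yb
            loss = float((err ** 2).mean()) + cfg.weight_decay * model.net.l2_penalty()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss} "
                    f"(pred range {np.nanmin(pred)}..{np.nanmax(pred)})")
            model.net.backward((2.0 * err / len(idx))[:, None].astype(np.float32))
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        val_pred = model.predict(xv)
        val_loss = float(((val_pred - yv) ** 2).mean())
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if cfg.patience > 0:
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = model.net.state()
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if cfg.patience > 0 and best_state is not None:
        model.net.load_state(best_state)
    return history


def predict(model: LeafCounter, data: DataLike) -> np.ndarray:
    x, _ = _as_arrays(data, model.config.input_size)
    return model.predict(x)


def evaluate(model: LeafCounter, test_data: DataLike, integerize: bool = True) -> EvalMetrics:
    """Evaluate on a test set; metrics integerize predictions by default."""
    x, y = _as_arrays(test_data, model.config.input_size)
    if len(x) == 0:
        raise ValueError("test data is empty")
    return compute_metrics(y, model.predict(x), integerize=integerize)
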