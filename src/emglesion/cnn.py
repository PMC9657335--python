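"""1-D convolutional neural network for binary EMG segment classification.

Architecture: four convolution blocks (conv1d + ReLU + ceil-mode max-pool,
with 0.1 dropout after blocks 3 and 4), global average pooling, a dense
ReLU layer of 100 units, and a single sigmoid output unit.  A 1000-sample
segment therefore flows 1000 -> 500 -> 250 -> 125 -> 63 -> 63 -> 32 -> 32
-> 16 in the temporal dimension; "same" padding with ceil-mode pooling is
the one convention that produces this shape sequence.

Training minimizes binary cross-entropy with the Adam optimizer.  The
network, its backward pass and the optimizer are implemented directly in
NumPy; convolutions are expressed as im2col matrix products.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .preprocessing import SegmentDataset

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainingConfig",
    "TrainingHistory",
    "default_architecture",
    "derive_shapes",
    "count_parameters",
    "bc_loss",
    "CNNModel",
    "train",
    "predict",
]

#: Probabilities are clipped to [EPS, 1 - EPS] inside the loss.
EPS = 1e-7


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network; only the kind-appropriate fields are used."""

    kind: str  # conv1d | relu | maxpool1d | dropout | gap | dense | sigmoid
    filters: int = 0
    kernel: int = 0
    stride: int = 1
    rate: float = 0.0
    units: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0 <= self.rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer sequence with a fixed input length."""

    layers: tuple
    input_length: int = 1000
    padding_mode: str = "same_ceil"


def default_architecture(input_length: int = 1000) -> ArchitectureSpec:
    """The optimized architecture: 4 conv blocks, GAP, FC-100, sigmoid."""
    layers = (
        LayerSpec("conv1d", filters=32, kernel=5, stride=2),
        LayerSpec("relu"),
        LayerSpec("maxpool1d", kernel=2, stride=2),
        LayerSpec("conv1d", filters=32, kernel=5, stride=2),
        LayerSpec("relu"),
        LayerSpec("maxpool1d", kernel=2, stride=2),
        LayerSpec("conv1d", filters=64, kernel=3, stride=1),
        LayerSpec("relu"),
        LayerSpec("maxpool1d", kernel=2, stride=2),
        LayerSpec("dropout", rate=0.1),
        LayerSpec("conv1d", filters=128, kernel=3, stride=1),
        LayerSpec("relu"),
        LayerSpec("maxpool1d", kernel=2, stride=2),
        LayerSpec("dropout", rate=0.1),
        LayerSpec("gap"),
        LayerSpec("dense", units=100),
        LayerSpec("relu"),
        LayerSpec("dense", units=1),
        LayerSpec("sigmoid"),
    )
    return ArchitectureSpec(layers=layers, input_length=input_length)


def derive_shapes(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """(temporal length, channels) after each layer.

    Convolution and pooling with "same" padding and ceil mode give
    ``length_out = ceil(length_in / stride)``; GAP collapses the temporal
    axis, so its shape (and every dense layer's) is reported as
    ``(1, width)``.
    """
    length, channels = spec.input_length, 1
    flat: Optional[int] = None  # width once the temporal axis is gone
    shapes = []
    for layer in spec.layers:
        if layer.kind == "conv1d":
            length = math.ceil(length / layer.stride)
            channels = layer.filters
        elif layer.kind == "maxpool1d":
            length = math.ceil(length / layer.stride)
        elif layer.kind == "gap":
            flat = channels
        elif layer.kind == "dense":
            if flat is None:
                raise ValueError("dense layer before GAP/flatten")
            flat = layer.units
        elif layer.kind not in ("relu", "dropout", "sigmoid"):
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        if flat is None:
            if length <= 0:
                raise ValueError("non-positive intermediate temporal length")
            shapes.append((length, channels))
        else:
            shapes.append((1, flat))
    return shapes


def count_parameters(spec: ArchitectureSpec) -> tuple[list[int], int]:
    """Trainable parameters per layer (weights + biases) and the total."""
    channels = 1
    flat: Optional[int] = None
    counts = []
    for layer in spec.layers:
        n = 0
        if layer.kind == "conv1d":
            n = layer.filters * layer.kernel * channels + layer.filters
            channels = layer.filters
        elif layer.kind == "gap":
            flat = channels
        elif layer.kind == "dense":
            n = layer.units * flat + layer.units
            flat = layer.units
        counts.append(n)
    return counts, sum(counts)


def bc_loss(y_pred, y_true, eps: float = EPS) -> float:
    """Binary cross-entropy, natural log, mean over instances.

    ``-(1/n) sum_i [x_i log(y_i) + (1 - x_i) log(1 - y_i)]`` with the
    predicted probabilities clipped to ``[eps, 1 - eps]``.
    """
    y = np.asarray(y_pred, dtype=float)
    x = np.asarray(y_true, dtype=float)
    if y.shape != x.shape:
        raise ValueError("predicted and actual sequences must have equal length")
    if y.size == 0:
        raise ValueError("empty loss inputs")
    y = np.clip(y, eps, 1.0 - eps)
    return float(-np.mean(x * np.log(y) + (1.0 - x) * np.log(1.0 - y)))


# --------------------------------------------------------------------------
# layers


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = math.ceil(length / stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return out, left, total - left


class _Conv1D:
    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        limit = math.sqrt(6.0 / (in_ch * kernel))  # uniform fan-in init
        self.W = rng.uniform(-limit, limit, size=(filters, in_ch, kernel))
        self.b = np.zeros(filters)
        self.stride = stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        n, c, length = x.shape
        f, _, k = self.W.shape
        out, pl, pr = _same_pad(length, k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        idx = self.stride * np.arange(out)[:, None] + np.arange(k)[None, :]
        cols = xp[:, :, idx]  # (n, c, out, k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n, out, c * k)
        self._cache = (cols, x.shape, pl, xp.shape[2], out)
        y = cols @ self.W.reshape(f, c * k).T + self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (n, f, out)

    def backward(self, g):
        cols, xshape, pl, lp, out = self._cache
        n, c, length = xshape
        f, _, k = self.W.shape
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (n, out, f)
        self.dW[...] = (
            gt.reshape(-1, f).T @ cols.reshape(-1, c * k)
        ).reshape(self.W.shape)
        self.db[...] = gt.sum(axis=(0, 1))
        dcols = (gt @ self.W.reshape(f, c * k)).reshape(n, out, c, k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (n, c, out, k)
        dxp = np.zeros((n, c, lp))
        base = self.stride * np.arange(out)
        for j in range(k):  # positions unique per tap: fancy += is safe
            dxp[:, :, base + j] += dcols[:, :, :, j]
        return dxp[:, :, pl:pl + length]


class _MaxPool1D:
    def __init__(self, kernel: int, stride: int):
        self.kernel = kernel
        self.stride = stride
        self.params = []
        self.grads = []

    def forward(self, x, training, rng):
        n, c, length = x.shape
        k = self.kernel
        out, pl, pr = _same_pad(length, k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf)
        idx = self.stride * np.arange(out)[:, None] + np.arange(k)[None, :]
        windows = xp[:, :, idx]  # (n, c, out, k)
        arg = windows.argmax(axis=3)
        self._cache = (arg, x.shape, pl, xp.shape[2], out)
        return np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]

    def backward(self, g):
        arg, xshape, pl, lp, out = self._cache
        n, c, length = xshape
        dxp = np.zeros((n, c, lp))
        base = self.stride * np.arange(out)
        for j in range(self.kernel):
            mask = arg == j
            dxp[:, :, base + j] += g * mask
        return dxp[:, :, pl:pl + length]


class _ReLU:
    params = []
    grads = []

    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _Dropout:
    params = []
    grads = []

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class _GlobalAvgPool:
    params = []
    grads = []

    def forward(self, x, training, rng):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._length, axis=2) / self._length


class _Dense:
    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / in_dim)
        self.W = rng.uniform(-limit, limit, size=(in_dim, units))
        self.b = np.zeros(units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


# --------------------------------------------------------------------------
# model


class CNNModel:
    """A network instance built from an :class:`ArchitectureSpec`.

    The final sigmoid is applied outside the layer stack so training can
    back-propagate through the numerically stable logit formulation.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = []
        channels = 1
        flat: Optional[int] = None
        for ls in spec.layers:
            if ls.kind == "conv1d":
                layers.append(_Conv1D(channels, ls.filters, ls.kernel, ls.stride, rng))
                channels = ls.filters
            elif ls.kind == "relu":
                layers.append(_ReLU())
            elif ls.kind == "maxpool1d":
                layers.append(_MaxPool1D(ls.kernel, ls.stride))
            elif ls.kind == "dropout":
                layers.append(_Dropout(ls.rate))
            elif ls.kind == "gap":
                layers.append(_GlobalAvgPool())
                flat = channels
            elif ls.kind == "dense":
                layers.append(_Dense(flat, ls.units, rng))
                flat = ls.units
            elif ls.kind == "sigmoid":
                pass  # applied on top of the logits
            else:
                raise ValueError(f"unknown layer kind {ls.kind!r}")
        self.layers = layers

    def forward_logits(self, segments: np.ndarray, training: bool = False,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
        x = np.asarray(segments, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.spec.input_length:
            raise ValueError(
                f"segments must be (n, {self.spec.input_length}); got {x.shape}"
            )
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, training, rng)
        return h[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def predict_proba(self, segments: np.ndarray, batch: int = 512) -> np.ndarray:
        segments = np.asarray(segments, dtype=float)
        out = np.empty(len(segments))
        for i in range(0, len(segments), batch):
            out[i:i + batch] = expit(self.forward_logits(segments[i:i + batch]))
        return out

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, spec=json.dumps([asdict(ls) for ls in self.spec.layers]),
                 input_length=self.spec.input_length, **arrays)

    @classmethod
    def load(cls, path) -> "CNNModel":
        with np.load(path, allow_pickle=False) as z:
            layers = tuple(LayerSpec(**d) for d in json.loads(str(z["spec"])))
            spec = ArchitectureSpec(layers=layers, input_length=int(z["input_length"]))
            model = cls(spec, seed=0)
            for i, p in enumerate(model.params):
                p[...] = z[f"p{i}"]
        return model


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer hyperparameters: Adam at 0.001, batch 128, BC loss.

    The reference configuration trains for 500 epochs; the desk default is
    30, which suffices on clearly separable synthetic data.
    """

    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch curves (loss and accuracy on the train and test sets)."""

    train_loss: list = field(default_factory=list)
    test_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    test_acc: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
                "train_acc": self.train_acc,
                "test_acc": self.test_acc,
            }
        )


def _validate_dataset(ds: SegmentDataset, name: str) -> None:
    if len(ds) == 0:
        raise ValueError(f"{name} dataset is empty")
    if not np.isin(ds.labels, (0, 1)).all():
        raise ValueError(f"{name} labels must be binary 0/1")


def train(
    spec: ArchitectureSpec,
    train_set: SegmentDataset,
    test_set: SegmentDataset,
    cfg: TrainingConfig = TrainingConfig(),
) -> tuple[CNNModel, TrainingHistory]:
    """Mini-batch Adam optimization of the binary cross-entropy loss.

    Weight initialization, batch shuffling and dropout are all driven by
    generators derived from ``cfg.seed``, so runs are reproducible on one
    machine.  The history records full train/test loss and accuracy after
    every epoch (dropout disabled for evaluation).
    """
    _validate_dataset(train_set, "train")
    _validate_dataset(test_set, "test")
    init_ss, shuffle_ss, dropout_ss = np.random.SeedSequence(cfg.seed).spawn(3)
    model = CNNModel(spec, seed=init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)

    x = train_set.segments
    t = train_set.labels.astype(float)
    m = [np.zeros_like(p) for p in model.params]
    v = [np.zeros_like(p) for p in model.params]
    step = 0
    history = TrainingHistory()

    for _epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(len(x))
        for start in range(0, len(x), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            z = model.forward_logits(x[idx], training=True, rng=dropout_rng)
            p = expit(z)
            model.backward((p - t[idx]) / len(idx))
            step += 1
            bc1 = 1.0 - cfg.beta1**step
            bc2 = 1.0 - cfg.beta2**step
            for pi, gi, mi, vi in zip(model.params, model.grads, m, v):
                mi *= cfg.beta1
                mi += (1 - cfg.beta1) * gi
                vi *= cfg.beta2
                vi += (1 - cfg.beta2) * gi * gi
                pi -= cfg.learning_rate * (mi / bc1) / (np.sqrt(vi / bc2) + cfg.adam_eps)

        p_train = model.predict_proba(train_set.segments)
        p_test = model.predict_proba(test_set.segments)
        history.train_loss.append(bc_loss(p_train, t))
        history.test_loss.append(bc_loss(p_test, test_set.labels.astype(float)))
        history.train_acc.append(float(np.mean((p_train > 0.5) == train_set.labels)))
        history.test_acc.append(float(np.mean((p_test > 0.5) == test_set.labels)))

    return model, history


def predict(model: CNNModel, segments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (probability > 0.5 -> post-lesion = 1).

    A probability of exactly 0.5 resolves to class 0 (strict inequality for
    the positive class).
    """
    probs = model.predict_proba(np.atleast_2d(np.asarray(segments, dtype=float)))
    return probs, (probs > 0.5).astype(int)
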