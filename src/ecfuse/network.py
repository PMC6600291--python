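"""Small convolutional network trained with mini-batch SGD, in pure NumPy.

Layer stack (valid padding throughout, stride 1):

    conv 5x5 -> batch-norm -> ReLU -> max-pool 2x2
    -> conv 5x5 -> batch-norm -> ReLU
    -> conv 2x2 -> batch-norm -> ReLU
    -> dropout -> fully-connected(l) -> softmax

A 19x19 input traces 19 -> 15 -> 7 -> 3 -> 2 spatially (conv5, pool,
conv5, conv2); a second pooling stage would shrink 19x19 inputs below the
last conv's receptive field, so pooling follows the first block only.

All randomness (weight init, shuffling, dropout masks) is driven by a
single seed, so training is bit-reproducible in single-threaded runs.
Feature maps enter in channels-last layout (N, H, W, C).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class CNNShapeError(ValueError):
    """Input too small for the layer stack; names the failing layer."""


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the three-stage convolutional stack."""

    kernel_sizes: tuple[int, int, int] = (5, 5, 2)
    filters: tuple[int, int, int] = (20, 50, 500)
    stride: int = 1
    learning_rate: float = 0.001
    momentum: float = 0.0
    batch_size: int = 1000
    epochs: int = 300
    dropout_rate: float = 0.5
    n_classes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != 3 or len(self.filters) != 3:
            raise ValueError("exactly three conv stages are required")
        if any(k < 1 for k in self.kernel_sizes) or any(f < 1 for f in self.filters):
            raise ValueError("kernel sizes and filter counts must be positive")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def architecture1(cls, **kw) -> "CNNConfig":
        """Whole-map fusion profile: batch 1000, 300 epochs."""
        return cls(batch_size=1000, epochs=300, **kw)

    @classmethod
    def architecture2(cls, **kw) -> "CNNConfig":
        """Per-channel fusion profile: batch 100, 150 epochs."""
        return cls(batch_size=100, epochs=150, **kw)

    @classmethod
    def scaled_down(cls, **kw) -> "CNNConfig":
        """Desk-scale profile for tests and small synthetic datasets."""
        defaults = dict(
            filters=(8, 16, 64),
            epochs=20,
            batch_size=16,
            learning_rate=0.05,
            momentum=0.9,
            dropout_rate=0.1,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TrainingHistory:
    """Per-epoch accuracy/loss curves for train and (optionally) test data."""

    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def validate_cnn_shapes(
    input_shape: tuple[int, int, int], config: CNNConfig
) -> list[tuple[int, int]]:
    """Trace spatial (H, W) through the stack; raise if any dim drops below 1.

    Returns the spatial size after each of the four shape-changing layers
    (conv1, pool1, conv2, conv3).
    """
    h, w = input_shape[0], input_shape[1]
    trace: list[tuple[int, int]] = []
    k1, k2, k3 = config.kernel_sizes
    steps = [("conv1", "conv", k1), ("pool1", "pool", 2),
             ("conv2", "conv", k2), ("conv3", "conv", k3)]
    for name, kind, k in steps:
        if kind == "conv":
            h, w = h - k + 1, w - k + 1
        else:
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise CNNShapeError(
                f"input {input_shape[:2]} too small: spatial size drops to "
                f"({h}, {w}) at layer {name}"
            )
        trace.append((h, w))
    return trace


# ---------------------------------------------------------------------------
# layers (channels-first internally)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = xshape
    oh, ow = h - kh + 1, w - kw + 1
    dx = np.zeros(xshape)
    d = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + oh, j:j + ow] += d[:, :, i, j]
    return dx


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * k * k
        self.k = k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.k)
        n, _, h, w = x.shape
        oh, ow = h - self.k + 1, w - self.k + 1
        w2 = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(w2, self._cols) + self.b[:, None]
        return out.reshape(n, -1, oh, ow)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n = g.shape[0]
        g2 = g.reshape(n, g.shape[1], -1)
        self.grads[0][...] = np.einsum("nfp,nkp->fk", g2, self._cols).reshape(
            self.W.shape
        )
        self.grads[1][...] = g2.sum(axis=(0, 2))
        w2 = self.W.reshape(self.W.shape[0], -1)
        dcols = np.matmul(w2.T, g2)
        return _col2im(dcols, self._xshape, self.k, self.k)


class BatchNorm2D(_Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[
            None, :, None, None
        ]

    def backward(self, g: np.ndarray) -> np.ndarray:
        m = g.shape[0] * g.shape[2] * g.shape[3]
        self.grads[0][...] = (g * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = g.sum(axis=(0, 2, 3))
        gxhat = g * self.gamma[None, :, None, None]
        term = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (gxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term / self._std[None, :, None, None]


class ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2(_Layer):
    """2x2 max pooling, stride 2, floor division (trailing row/col dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._xshape = x.shape
        xc = x[:, :, : 2 * h2, : 2 * w2]
        r = xc.reshape(n, c, h2, 2, w2, 2)
        out = r.max(axis=(3, 5))
        self._r, self._out = r, out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        mask = self._r == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dr = mask * (g[:, :, :, None, :, None] / counts)
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._xshape)
        dx[:, :, : 2 * h2, : 2 * w2] = dr.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Flatten(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._xshape)


class Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CNNModel:
    """The built layer stack plus its config and input shape."""

    def __init__(
        self, input_shape: tuple[int, int, int], config: CNNConfig,
        layers: list[_Layer]
    ):
        self.input_shape = input_shape
        self.config = config
        self.layers = layers

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (N, H, W, C) channels-last batch."""
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"{self.input_shape}"
            )
        out = np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2)))
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        """Class probabilities (each row on the simplex) in eval mode."""
        x = np.asarray(x, dtype=float)
        chunks = [
            softmax(self.forward(x[i:i + batch], train=False))
            for i in range(0, len(x), batch)
        ]
        return np.vstack(chunks)

    # -- parameter access --------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus batch-norm running statistics, in layer order."""
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.params)
            out.extend(layer.buffers())
        return out

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state array count mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError("state array shape mismatch")
            dst[...] = src


def build_cnn(input_shape: tuple[int, int, int], config: CNNConfig) -> CNNModel:
    """Construct the layer stack for a channels-last input shape (H, W, C).

    Shapes are validated analytically first; an input too small for the
    stack raises :class:`CNNShapeError` naming the failing layer.
    """
    trace = validate_cnn_shapes(input_shape, config)
    h, w, c = input_shape
    k1, k2, k3 = config.kernel_sizes
    f1, f2, f3 = config.filters
    rng = np.random.default_rng(config.seed)
    layers: list[_Layer] = [
        Conv2D(c, f1, k1, rng), BatchNorm2D(f1), ReLU(), MaxPool2(),
        Conv2D(f1, f2, k2, rng), BatchNorm2D(f2), ReLU(),
        Conv2D(f2, f3, k3, rng), BatchNorm2D(f3), ReLU(),
        Flatten(),
        Dropout(config.dropout_rate, rng),
        Dense(trace[-1][0] * trace[-1][1] * f3, config.n_classes, rng),
    ]
    return CNNModel(input_shape, config, layers)


def _loss_and_acc(model: CNNModel, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    p = model.predict_proba(x)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(len(y)), y] + eps)))
    acc = float(np.mean(np.argmax(p, axis=1) == y))
    return loss, acc


def train_cnn(
    model: CNNModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: CNNConfig | None = None,
    x_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> TrainingHistory:
    """Mini-batch SGD on softmax cross-entropy; records per-epoch history.

    Labels are 0-based class indices.  The test set, when given, is used for
    monitoring only.  Raises on an empty class or a NaN loss.
    """
    if config is None:
        config = model.config
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    counts = np.bincount(y_train, minlength=config.n_classes)
    if np.any(counts == 0):
        missing = np.where(counts == 0)[0].tolist()
        raise ValueError(f"training data has no samples for classes {missing}")

    n = len(x_train)
    bs = min(config.batch_size, n)
    rng = np.random.default_rng(config.seed + 1)
    params = model.parameters()
    grads = model.gradients()
    velocity = [np.zeros_like(p) for p in params]
    history = TrainingHistory()

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            p = softmax(logits)
            loss = -np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {_epoch}; reduce the learning rate"
                )
            g = (p - np.eye(config.n_classes)[yb]) / len(yb)
            for layer in reversed(model.layers):
                g = layer.backward(g)
            for v, prm, grd in zip(velocity, params, grads):
                v *= config.momentum
                v -= config.learning_rate * grd
                prm += v

        tr_loss, tr_acc = _loss_and_acc(model, x_train, y_train)
        history.train_loss.append(tr_loss)
        history.train_accuracy.append(tr_acc)
        if x_test is not None and y_test is not None:
            te_loss, te_acc = _loss_and_acc(model, x_test, np.asarray(y_test, int))
            history.test_loss.append(te_loss)
            history.test_accuracy.append(te_acc)
    return history


def predict_proba(model: CNNModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`CNNModel.predict_proba`."""
    return model.predict_proba(np.asarray(x, dtype=float))
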