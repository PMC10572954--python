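"""Minimal CNN training backend in numpy.

Instantiates an :class:`~osteovote.architecture.ArchitectureSpec` as real
weight tensors and trains it with Adam on sparse categorical
cross-entropy — the optimizer, loss, learning rate (0.001) and batch size
(16) of the study's training setup. The backend exists for desk-scale
work: verifying parameter accounting against actually-instantiated
tensors, and training reduced-width stacks on small synthetic images. It
is deliberately plain NHWC numpy (shift-and-matmul convolutions, reshape
max-pooling) with no GPU path.

Anything exposing ``predict_proba`` through :class:`BaseLearner` — a
frozen or fine-tuned pretrained backbone included — can join the voting
ensemble; this module only provides the from-scratch learner.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec
from .ensemble import ProbabilityMatrix
from .pipeline import AugmentConfig, augment_pixels

LEARNER_MODES = ("complete_training", "frozen", "fine_tuned")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule settings (defaults follow the study setup)."""

    optimizer_name: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 200
    loss_name: str = "sparse categorical cross-entropy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("learning_rate and batch_size must be positive, epochs >= 0")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


class BaseLearner(abc.ABC):
    """Interface every ensemble member implements."""

    def __init__(self, learner_id: str, mode: str = "complete_training") -> None:
        if mode not in LEARNER_MODES:
            raise ValueError(f"mode must be one of {LEARNER_MODES}, got {mode!r}")
        self.learner_id = learner_id
        self.mode = mode

    @abc.abstractmethod
    def predict_proba(self, X: np.ndarray) -> ProbabilityMatrix:
        """Per-sample class probabilities; rows sum to 1."""


class MatrixLearner(BaseLearner):
    """A learner backed by precomputed probabilities (e.g. read from CSV)."""

    def __init__(self, learner_id: str, values: np.ndarray, mode: str = "fine_tuned") -> None:
        super().__init__(learner_id, mode)
        self._matrix = ProbabilityMatrix(learner_id=learner_id, values=values)

    def predict_proba(self, X=None) -> ProbabilityMatrix:
        return self._matrix


# ---------------------------------------------------------------------------
# Layers. Each holds its parameters as a list of (tensor, gradient) pairs.

class _Layer:
    params: list[list[np.ndarray]]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def weight_tensors(self) -> list[np.ndarray]:
        """All per-layer tensors, including non-trainable statistics."""
        return [p[0] for p in self.params]


class _BatchNorm(_Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.moving_mean = np.zeros(channels)
        self.moving_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.params = [[self.gamma, np.zeros_like(self.gamma)],
                       [self.beta, np.zeros_like(self.beta)]]

    def weight_tensors(self) -> list[np.ndarray]:
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean *= self.momentum
            self.moving_mean += (1 - self.momentum) * mean
            self.moving_var *= self.momentum
            self.moving_var += (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.params[0][1][...] = (grad * self._xhat).sum(axis=axes)
        self.params[1][1][...] = grad.sum(axis=axes)
        m = self._m
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class _Conv2D(_Layer):
    """3x3-style same-padding convolution via shift-and-matmul."""

    def __init__(self, f: int, c_in: int, c_out: int, relu: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if f % 2 != 1:
            raise ValueError("same-padding convolution needs an odd filter size")
        self.f, self.relu = f, relu
        scale = np.sqrt(2.0 / (f * f * c_in))  # He initialization
        self.w = rng.normal(0.0, scale, size=(f, f, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [[self.w, np.zeros_like(self.w)], [self.b, np.zeros_like(self.b)]]

    def forward(self, x, train, rng):
        f = self.f
        p = f // 2
        n, h, w_, c = x.shape
        self._xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w_, self.w.shape[3])).copy()
        for i in range(f):
            for j in range(f):
                patch = self._xp[:, i:i + h, j:j + w_, :]
                out += np.tensordot(patch, self.w[i, j], axes=([3], [0]))
        self._pre = out
        return np.maximum(out, 0.0) if self.relu else out

    def backward(self, grad):
        if self.relu:
            grad = grad * (self._pre > 0)
        f = self.f
        n, h, w_, _ = grad.shape
        dxp = np.zeros_like(self._xp)
        dw, db = self.params[0][1], self.params[1][1]
        db[...] = grad.sum(axis=(0, 1, 2))
        for i in range(f):
            for j in range(f):
                patch = self._xp[:, i:i + h, j:j + w_, :]
                dw[i, j] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j:j + w_, :] += np.tensordot(grad, self.w[i, j],
                                                             axes=([3], [1]))
        p = f // 2
        return dxp[:, p:p + h, p:p + w_, :] if p else dxp


class _MaxPool(_Layer):
    def __init__(self, f: int) -> None:
        super().__init__()
        self.f = f

    def forward(self, x, train, rng):
        f = self.f
        n, h, w, c = x.shape
        h2, w2 = h // f, w // f
        self._in_shape = x.shape
        windows = (x[:, :h2 * f, :w2 * f, :]
                   .reshape(n, h2, f, w2, f, c)
                   .transpose(0, 1, 3, 5, 2, 4)
                   .reshape(n, h2, w2, c, f * f))
        self._arg = windows.argmax(axis=-1)
        return np.take_along_axis(windows, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        f = self.f
        n, h, w, c = self._in_shape
        h2, w2 = h // f, w // f
        dwin = np.zeros((n, h2, w2, c, f * f))
        np.put_along_axis(dwin, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :h2 * f, :w2 * f, :] = (dwin
                                      .reshape(n, h2, w2, c, f, f)
                                      .transpose(0, 1, 4, 2, 5, 3)
                                      .reshape(n, h2 * f, w2 * f, c))
        return dx


class _Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, activation: str,
                 rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [[self.w, np.zeros_like(self.w)], [self.b, np.zeros_like(self.b)]]

    def forward(self, x, train, rng):
        self._x = x
        out = x @ self.w + self.b
        if self.activation == "relu":
            self._pre = out
            return np.maximum(out, 0.0)
        return out  # softmax is fused with the loss

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._pre > 0)
        self.params[0][1][...] = self._x.T @ grad
        self.params[1][1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class _Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params: list[list[np.ndarray]]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for pid, (w, g) in enumerate(params):
            if pid not in self.state:
                self.state[pid] = (np.zeros_like(w), np.zeros_like(w))
            m, v = self.state[pid]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class NumpyCNN(BaseLearner):
    """A trainable CNN instantiated from an architecture specification."""

    def __init__(self, spec: ArchitectureSpec, learner_id: str = "cnn",
                 mode: str = "complete_training", seed: int = 0) -> None:
        super().__init__(learner_id, mode)
        self.spec = spec
        self.history: list[dict] = []
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(rng.integers(2**31))
        self.layers: list[_Layer] = []
        prev = tuple(spec.input_shape)
        for layer, out_shape in zip(spec.layers, spec.output_shapes):
            if layer.kind == "batch_norm":
                self.layers.append(_BatchNorm(prev[-1]))
            elif layer.kind == "conv2d":
                self.layers.append(_Conv2D(layer.filter_size, prev[2],
                                           layer.depth_or_units,
                                           layer.activation == "relu", rng))
            elif layer.kind == "max_pool":
                self.layers.append(_MaxPool(layer.filter_size))
            elif layer.kind == "flatten":
                self.layers.append(_Flatten())
            elif layer.kind == "dense":
                self.layers.append(_Dense(prev[0], layer.depth_or_units,
                                          layer.activation, rng))
            elif layer.kind == "dropout":
                self.layers.append(_Dropout(layer.dropout_rate))
            prev = out_shape
        self.n_classes = prev[0]

    # -- introspection ------------------------------------------------------
    def weight_tensors(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.weight_tensors())
        return out

    def n_parameters(self) -> int:
        return sum(t.size for t in self.weight_tensors())

    # -- inference ----------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        self._check_input(X)
        out = X
        for layer in self.layers:
            out = layer.forward(out, train, self._rng)
        return out

    def _check_input(self, X: np.ndarray) -> None:
        if tuple(X.shape[1:]) != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {X.shape[1:]} does not match spec {self.spec.input_shape}")

    def predict_proba(self, X: np.ndarray) -> ProbabilityMatrix:
        probs = _softmax(self._forward(np.asarray(X, dtype=np.float64), train=False))
        probs = probs / probs.sum(axis=1, keepdims=True)
        return ProbabilityMatrix(learner_id=self.learner_id, values=probs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax_labels()

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainingConfig,
            validation: tuple[np.ndarray, np.ndarray] | None = None,
            augment: AugmentConfig | None = None) -> list[dict]:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self._check_input(X)
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(f"labels must lie in [0, {self.n_classes})")
        if self.mode == "frozen":
            raise ValueError("a frozen learner cannot be trained")
        opt = _Adam(config.learning_rate)
        n = X.shape[0]
        aug_rng = np.random.default_rng(self._rng.integers(2**31))
        for epoch in range(config.epochs):
            order = self._rng.permutation(n)
            losses, hits = [], 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb = X[idx]
                if augment is not None:
                    xb = np.stack([augment_pixels(img, augment, aug_rng, max_value=1.0)
                                   for img in xb])
                yb = y[idx]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-15, 1.0)
                losses.append(-np.log(p_true).sum())
                hits += int((probs.argmax(axis=1) == yb).sum())
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad /= len(yb)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                params = [p for layer in self.layers for p in layer.params]
                opt.step(params)
            entry = {"epoch": epoch,
                     "train_loss": float(np.sum(losses) / n),
                     "train_acc": hits / n}
            if validation is not None and len(validation[0]):
                xv, yv = validation
                pv = self.predict_proba(xv).values
                p_true = np.clip(pv[np.arange(len(yv)), yv], 1e-15, 1.0)
                entry["val_loss"] = float(-np.mean(np.log(p_true)))
                entry["val_acc"] = float((pv.argmax(axis=1) == np.asarray(yv)).mean())
            self.history.append(entry)
        return self.history

    def write_history(self, path) -> None:
        import csv

        cols = ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for row in self.history:
                writer.writerow({c: row.get(c, "") for c in cols})


def train_learner(spec: ArchitectureSpec, config: TrainingConfig,
                  train: tuple[np.ndarray, np.ndarray],
                  validation: tuple[np.ndarray, np.ndarray] | None = None,
                  augment: AugmentConfig | None = None,
                  seed: int = 0, learner_id: str = "cnn") -> NumpyCNN:
    """Instantiate a CNN from ``spec`` and train it; returns the learner.

    Per-epoch training/validation loss and accuracy are recorded in
    ``learner.history`` (the material of learning-curve plots).
    """
    learner = NumpyCNN(spec, learner_id=learner_id, seed=seed)
    learner.fit(train[0], train[1], config, validation=validation, augment=augment)
    return learner
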