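"""Shallow convolutional network for binary keratosis recognition.

A LeNet-style architecture sized for 64 x 64 x 3 dermoscopy inputs:

    conv(6 filters, 5x5, stride 1, pad 2) -> LeakyReLU(0.01)
    -> maxpool(2x2, stride 2)
    -> conv(16 filters, 5x5, stride 1, pad 2) -> LeakyReLU
    -> flatten (16384)
    -> dense(fc_width) -> LeakyReLU -> dropout(0.5)
    -> dense(2) -> softmax

Trained with classical momentum SGD (momentum 0.9, fixed learning rate 1e-4,
mini-batches of 10, L2 weight decay 5e-4 on weights only) under a softmax
cross-entropy loss.  Everything is plain seeded NumPy — convolutions via
im2col and BLAS matmuls — so training is bit-reproducible on one CPU from
``(init_seed, shuffle_seed, data)``.

The rationale for staying shallow: keratosis texture is simple compared to
histopathology, so two convolutional stages capture the discriminative scale
and color structure while keeping training to CPU-scale minutes and avoiding
the overfitting deep stacks suffer on ~10^3-image datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "ShallowCNNClassifier",
    "build_model",
    "count_parameters",
    "parameter_counts",
    "layer_shapes",
    "train",
    "predict_proba",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureConfig:
    """Architecture constants of the shallow network."""

    input_size: int = 64
    kernel_size: int = 5
    conv_stride: int = 1
    conv_padding: int = 2
    filters: tuple[int, int] = (6, 16)
    pool_window: int = 2
    fc_width: int = 120
    dropout_p: float = 0.5
    leaky_slope: float = 0.01
    n_classes: int = 2
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_stride != 1:
            raise ConfigurationError("conv_stride must be 1")
        if 2 * self.conv_padding != self.kernel_size - 1:
            raise ConfigurationError(
                "conv_padding must preserve spatial size (2*padding == kernel_size-1)"
            )
        if self.pool_window != 2:
            raise ConfigurationError("pool_window must be 2")
        if self.input_size % 2 != 0 or self.input_size < 8:
            raise ConfigurationError("input_size must be an even integer >= 8")
        if len(self.filters) != 2 or any(f < 1 for f in self.filters):
            raise ConfigurationError("filters must be a pair of positive counts")
        if self.fc_width < 1:
            raise ConfigurationError("fc_width must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ConfigurationError("leaky_slope must be > 0")
        if self.n_classes != 2:
            raise ConfigurationError("only the binary head (n_classes=2) is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Momentum-SGD hyperparameters (defaults: the shallow model's column)."""

    momentum: float = 0.9
    initial_learn_rate: float = 0.0001
    mini_batch_size: int = 10
    l2_regularization: float = 0.0005
    epochs: int = 30
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must be in [0, 1)")
        if self.initial_learn_rate < 0:
            raise ConfigurationError("initial_learn_rate must be >= 0")
        if self.mini_batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("mini_batch_size >= 1 and epochs >= 0 required")


# ---------------------------------------------------------------------------
# layer primitives (NHWC layout, float32, im2col convolutions)

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # (N, H, W, C, k, k) -> rows ordered (ki, kj, channel)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
    return np.ascontiguousarray(cols, dtype=np.float32)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    n, h, w, c = shape
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=np.float32)
    d = dcols.reshape(n, h, w, k, k, c)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki:ki + h, kj:kj + w, :] += d[:, :, :, ki, kj, :]
    return dxp[:, pad:pad + h, pad:pad + w, :]


def _maxpool(x: np.ndarray):
    n, h, w, c = x.shape
    xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
           .transpose(0, 1, 3, 5, 2, 4)
           .reshape(n, h // 2, w // 2, c, 4))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, shape: tuple) -> np.ndarray:
    n, h, w, c = shape
    dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None].astype(np.float32), axis=-1)
    return (dxr.reshape(n, h // 2, w // 2, c, 2, 2)
               .transpose(0, 1, 4, 2, 5, 3)
               .reshape(n, h, w, c))


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, np.float32(1.0), np.float32(slope))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def layer_shapes(config: ArchitectureConfig | None = None) -> list[tuple[str, tuple]]:
    """Per-stage output shapes (H, W, C), plus the flatten length."""
    cfg = config or ArchitectureConfig()
    s = cfg.input_size
    f1, f2 = cfg.filters
    half = s // cfg.pool_window
    return [
        ("conv1", (s, s, f1)),
        ("pool1", (half, half, f1)),
        ("conv2", (half, half, f2)),
        ("flatten", (half * half * f2,)),
        ("fc1", (cfg.fc_width,)),
        ("fc2", (cfg.n_classes,)),
    ]


class ShallowCNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping the shallow keratosis network.

    ``fit`` expects standardized inputs: an (n, input_size, input_size, 3)
    float array with values in [0, 1] (see
    :class:`akscreen.preprocess.ImageStandardizer`) and binary labels with
    1 = actinic keratosis.

    Attributes after fitting
    ------------------------
    params_ : dict of str -> ndarray
        Weight tensors (W1, b1, W2, b2, W3, b3, W4, b4).
    history_ : dict with per-epoch ``loss`` and ``accuracy`` lists
        Mini-batch-averaged training cross-entropy and accuracy.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(self, input_size: int = 64, kernel_size: int = 5,
                 conv_padding: int = 2, filters: tuple = (6, 16),
                 fc_width: int = 120, dropout_p: float = 0.5,
                 leaky_slope: float = 0.01, momentum: float = 0.9,
                 learning_rate: float = 0.0001, batch_size: int = 10,
                 l2: float = 0.0005, epochs: int = 30,
                 init_seed: int = 0, shuffle_seed: int = 0):
        self.input_size = input_size
        self.kernel_size = kernel_size
        self.conv_padding = conv_padding
        self.filters = filters
        self.fc_width = fc_width
        self.dropout_p = dropout_p
        self.leaky_slope = leaky_slope
        self.momentum = momentum
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.l2 = l2
        self.epochs = epochs
        self.init_seed = init_seed
        self.shuffle_seed = shuffle_seed

    # -- config plumbing ----------------------------------------------------

    @classmethod
    def from_configs(cls, arch: ArchitectureConfig | None = None,
                     tc: TrainConfig | None = None) -> "ShallowCNNClassifier":
        arch = arch or ArchitectureConfig()
        tc = tc or TrainConfig()
        return cls(input_size=arch.input_size, kernel_size=arch.kernel_size,
                   conv_padding=arch.conv_padding, filters=tuple(arch.filters),
                   fc_width=arch.fc_width, dropout_p=arch.dropout_p,
                   leaky_slope=arch.leaky_slope, momentum=tc.momentum,
                   learning_rate=tc.initial_learn_rate,
                   batch_size=tc.mini_batch_size, l2=tc.l2_regularization,
                   epochs=tc.epochs, init_seed=arch.init_seed,
                   shuffle_seed=tc.shuffle_seed)

    def architecture(self) -> ArchitectureConfig:
        return ArchitectureConfig(
            input_size=self.input_size, kernel_size=self.kernel_size,
            conv_padding=self.conv_padding, filters=tuple(self.filters),
            fc_width=self.fc_width, dropout_p=self.dropout_p,
            leaky_slope=self.leaky_slope, init_seed=self.init_seed)

    def train_config(self) -> TrainConfig:
        return TrainConfig(momentum=self.momentum,
                           initial_learn_rate=self.learning_rate,
                           mini_batch_size=self.batch_size,
                           l2_regularization=self.l2, epochs=self.epochs,
                           shuffle_seed=self.shuffle_seed)

    # -- weights ------------------------------------------------------------

    def initialize(self) -> "ShallowCNNClassifier":
        """Seeded uniform fan-in initialization (limit sqrt(6/fan_in)).

        The classifier head gets a 10x smaller scale so a freshly built
        network predicts near-uniform class probabilities (initial
        cross-entropy ~ ln 2 on balanced data).
        """
        cfg = self.architecture()  # validates
        rng = np.random.default_rng(cfg.init_seed)
        k, (f1, f2) = cfg.kernel_size, cfg.filters
        flat = (cfg.input_size // 2) ** 2 * f2

        def uniform(shape, fan_in, gain=1.0):
            limit = gain * np.sqrt(6.0 / fan_in)
            return rng.uniform(-limit, limit, size=shape).astype(np.float32)

        self.params_ = {
            "W1": uniform((k * k * 3, f1), k * k * 3),
            "b1": np.zeros(f1, dtype=np.float32),
            "W2": uniform((k * k * f1, f2), k * k * f1),
            "b2": np.zeros(f2, dtype=np.float32),
            "W3": uniform((flat, cfg.fc_width), flat),
            "b3": np.zeros(cfg.fc_width, dtype=np.float32),
            "W4": uniform((cfg.fc_width, cfg.n_classes), cfg.fc_width, gain=0.1),
            "b4": np.zeros(cfg.n_classes, dtype=np.float32),
        }
        self.classes_ = np.array([0, 1])
        self.history_ = {"loss": [], "accuracy": []}
        return self

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, drop_rng: np.random.Generator | None):
        """Returns (probabilities, cache); dropout active iff drop_rng given."""
        p = self.params_
        k, pad, slope = self.kernel_size, self.conv_padding, np.float32(self.leaky_slope)
        n = x.shape[0]
        s = self.input_size
        f1, f2 = self.filters

        cols1 = _im2col(x, k, pad)
        z1 = (cols1 @ p["W1"] + p["b1"]).reshape(n, s, s, f1)
        a1 = _leaky(z1, slope)
        pooled, pool_idx = _maxpool(a1)
        cols2 = _im2col(pooled, k, pad)
        half = s // 2
        z2 = (cols2 @ p["W2"] + p["b2"]).reshape(n, half, half, f2)
        a2 = _leaky(z2, slope)
        flat = a2.reshape(n, -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = _leaky(z3, slope)
        if drop_rng is not None and self.dropout_p > 0:
            keep = np.float32(1.0 - self.dropout_p)
            mask = (drop_rng.random(a3.shape) >= self.dropout_p).astype(np.float32) / keep
            a3d = a3 * mask
        else:
            mask = None
            a3d = a3
        z4 = a3d @ p["W4"] + p["b4"]
        probs = _softmax(z4.astype(np.float64))
        cache = (x, cols1, z1, pool_idx, pooled, cols2, z2, flat, z3, a3d, mask)
        return probs, cache

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache) -> dict:
        p = self.params_
        k, pad, slope = self.kernel_size, self.conv_padding, np.float32(self.leaky_slope)
        x, cols1, z1, pool_idx, pooled, cols2, z2, flat, z3, a3d, mask = cache
        n = x.shape[0]
        s = self.input_size
        half = s // 2
        f1, f2 = self.filters

        dz4 = ((probs - y_onehot) / n).astype(np.float32)
        grads = {"W4": a3d.T @ dz4, "b4": dz4.sum(axis=0)}
        da3 = dz4 @ p["W4"].T
        if mask is not None:
            da3 = da3 * mask
        dz3 = da3 * _leaky_grad(z3, slope)
        grads["W3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        da2 = dflat.reshape(n, half, half, f2)
        dz2 = (da2 * _leaky_grad(z2, slope)).reshape(n * half * half, f2)
        grads["W2"] = cols2.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dcols2 = dz2 @ p["W2"].T
        dpooled = _col2im(dcols2, pooled.shape, k, pad)
        da1 = _maxpool_backward(dpooled, pool_idx, z1.shape)
        dz1 = (da1 * _leaky_grad(z1, slope)).reshape(n * s * s, f1)
        grads["W1"] = cols1.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y) -> "ShallowCNNClassifier":
        X, y = self._validate(X, y, fitting=True)
        if not hasattr(self, "params_"):
            self.initialize()
        tc = self.train_config()  # validates
        shuffle_rng = np.random.default_rng(tc.shuffle_seed)
        # dropout masks come from an independent, equally seeded substream
        drop_rng = np.random.default_rng([tc.shuffle_seed, 1])
        velocity = {name: np.zeros_like(w) for name, w in self.params_.items()}
        onehot = np.eye(2, dtype=np.float32)[y]
        n = X.shape[0]
        lr, mu, l2 = tc.initial_learn_rate, tc.momentum, tc.l2_regularization

        for _ in range(tc.epochs):
            order = shuffle_rng.permutation(n)
            losses, hits, seen = 0.0, 0, 0
            for start in range(0, n, tc.mini_batch_size):  # last partial batch kept
                idx = order[start:start + tc.mini_batch_size]
                xb, yb = X[idx], onehot[idx]
                probs, cache = self._forward(xb, drop_rng)
                grads = self._backward(probs, yb, cache)
                for name, w in self.params_.items():
                    g = grads[name]
                    if name.startswith("W") and l2 > 0:  # decay weights, not biases
                        g = g + np.float32(l2) * w
                    velocity[name] = mu * velocity[name] - lr * g
                    w += velocity[name]
                batch_ce = -np.mean(np.log(np.clip(probs[yb.astype(bool)], 1e-12, None)))
                losses += batch_ce * len(idx)
                hits += int(np.sum(probs.argmax(axis=1) == y[idx]))
                seen += len(idx)
            self.history_["loss"].append(losses / seen)
            self.history_["accuracy"].append(hits / seen)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        self._check_fitted()
        out = np.empty((X.shape[0], 2))
        for start in range(0, X.shape[0], 256):  # bound im2col memory
            probs, _ = self._forward(X[start:start + 256], drop_rng=None)
            out[start:start + 256] = probs
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score_samples(self, X) -> np.ndarray:
        """Positive-class (actinic keratosis) probability per sample."""
        return self.predict_proba(X)[:, 1]

    # -- helpers ------------------------------------------------------------

    def _validate(self, X, y=None, fitting: bool = False):
        X = np.asarray(X, dtype=np.float32)
        s = self.input_size
        if X.ndim != 4 or X.shape[1:] != (s, s, 3):
            raise TypeError(f"expected inputs of shape (n, {s}, {s}, 3), got {X.shape}")
        if X.size and (X.min() < -1e-6 or X.max() > 1 + 1e-6):
            raise TypeError("inputs must be standardized to [0, 1]")
        if y is None:
            return X
        y = np.asarray(y).astype(np.int64)
        if y.shape != (X.shape[0],) or not np.isin(y, [0, 1]).all():
            raise TypeError("labels must be a vector of 0/1 matching the inputs")
        if fitting and len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        return X, y

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise AttributeError("model has no weights; call initialize() or fit() first")

    def parameter_counts(self) -> dict[str, int]:
        self._check_fitted()
        counts = {
            "conv1": self.params_["W1"].size + self.params_["b1"].size,
            "conv2": self.params_["W2"].size + self.params_["b2"].size,
            "fc1": self.params_["W3"].size + self.params_["b3"].size,
            "fc2": self.params_["W4"].size + self.params_["b4"].size,
        }
        counts["total"] = sum(counts.values())
        return counts

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write weights to ``<path>.npz`` plus a JSON config sidecar."""
        self._check_fitted()
        path = Path(path)
        base = path.with_suffix("") if path.suffix == ".npz" else path
        np.savez(base.with_suffix(".npz"), **self.params_)
        sidecar = {"architecture": asdict(self.architecture()),
                   "training": asdict(self.train_config()),
                   "history": getattr(self, "history_", None)}
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return base.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ShallowCNNClassifier":
        path = Path(path)
        base = path.with_suffix("")
        sidecar = json.loads(base.with_suffix(".json").read_text())
        arch = sidecar["architecture"]
        arch["filters"] = tuple(arch["filters"])
        model = cls.from_configs(ArchitectureConfig(**arch),
                                 TrainConfig(**sidecar["training"]))
        with np.load(base.with_suffix(".npz")) as data:
            model.params_ = {k: data[k] for k in data.files}
        model.classes_ = np.array([0, 1])
        model.history_ = sidecar.get("history") or {"loss": [], "accuracy": []}
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers

def build_model(config: ArchitectureConfig | None = None,
                tc: TrainConfig | None = None) -> ShallowCNNClassifier:
    """Construct and deterministically initialize an untrained network."""
    return ShallowCNNClassifier.from_configs(config, tc).initialize()


def count_parameters(model: ShallowCNNClassifier) -> int:
    """Exact number of trainable scalars, biases included."""
    return model.parameter_counts()["total"]


def parameter_counts(model: ShallowCNNClassifier) -> dict[str, int]:
    return model.parameter_counts()


def train(model: ShallowCNNClassifier, X, y,
          tc: TrainConfig | None = None) -> ShallowCNNClassifier:
    """Momentum-SGD training on standardized inputs (in place)."""
    if tc is not None:
        model.set_params(momentum=tc.momentum, learning_rate=tc.initial_learn_rate,
                         batch_size=tc.mini_batch_size, l2=tc.l2_regularization,
                         epochs=tc.epochs, shuffle_seed=tc.shuffle_seed)
    return model.fit(X, y)


def predict_proba(model: ShallowCNNClassifier, X) -> np.ndarray:
    return model.predict_proba(X)
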