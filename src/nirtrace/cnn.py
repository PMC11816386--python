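"""A one-dimensional convolutional network for spectra, in pure numpy.

The architecture is the compact spectral CNN used for origin traceability:
``n_conv_layers`` blocks of [conv1d (32 filters, odd kernel, stride 1,
same-padding) -> batch normalization -> ReLU -> max-pool], a flatten, and
one fully connected softmax head over the origin classes.  Training is
mini-batch Adam on the multiclass cross-entropy, with per-wavenumber
z-score standardization fitted on the training set and stored with the
model.

Forward and backward passes are implemented here directly (im2col
convolution, batch-norm with running statistics, max-pool argmax routing)
and verified against numerical gradients in the test suite.  Everything is
seed-deterministic: weight initialization and the per-epoch shuffler both
draw from one ``numpy`` generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectraError

SWEEP_GRIDS = {
    "layers": [2, 3, 4],
    "kernel_size": [3, 5, 7],
    "batch_size": [8, 16, 32],
    "learning_rate": [5e-5, 1e-4, 5e-4],
}

_AXIS_FIELD = {
    "layers": "n_conv_layers",
    "kernel_size": "kernel_size",
    "batch_size": "batch_size",
    "learning_rate": "learning_rate",
}


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters of the spectral CNN."""

    input_length: int
    n_classes: int = 5
    n_conv_layers: int = 3
    kernels_per_layer: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    batch_size: int = 16
    learning_rate: float = 1e-4
    epochs: int = 25
    seed: int = 0
    dropout: float = 0.0  # optional; the default architecture uses none
    #: "global" = per-wavenumber mean-centering with one pooled scale, which
    #: preserves relative channel magnitudes; "per_wavenumber" = full z-score
    scaler: str = "global"

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise SpectraError("kernel_size must be odd")
        if self.n_classes < 2:
            raise SpectraError("need at least 2 classes")
        if self.learning_rate <= 0:
            raise SpectraError("learning rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise SpectraError("dropout must lie in [0, 1)")
        if self.scaler not in ("global", "per_wavenumber"):
            raise SpectraError(f"unknown scaler {self.scaler!r}")
        if min(self.conv_lengths()) < 1:
            minimal = self.pool_size ** self.n_conv_layers
            raise SpectraError(
                f"input_length {self.input_length} too short for "
                f"{self.n_conv_layers} poolings of {self.pool_size}; "
                f"need at least {minimal}"
            )

    def conv_lengths(self) -> list[int]:
        """Sequence lengths after each conv+pool block."""
        lengths, L = [], self.input_length
        for _ in range(self.n_conv_layers):
            L = L // self.pool_size  # same-padded conv keeps L; pool floors
            lengths.append(L)
        return lengths


@dataclass(frozen=True)
class LayerInfo:
    name: str
    output_shape: tuple
    n_params: int


def build_cnn(config: CNNConfig) -> list[LayerInfo]:
    """Describe every layer's output shape and parameter count."""
    layers = [LayerInfo("input", (1, config.input_length), 0)]
    c_in, L = 1, config.input_length
    for i, L_pool in enumerate(config.conv_lengths(), start=1):
        c_out = config.kernels_per_layer
        layers.append(
            LayerInfo(f"conv{i}", (c_out, L), (c_in * config.kernel_size + 1) * c_out)
        )
        layers.append(LayerInfo(f"batchnorm{i}", (c_out, L), 2 * c_out))
        layers.append(LayerInfo(f"relu{i}", (c_out, L), 0))
        layers.append(LayerInfo(f"maxpool{i}", (c_out, L_pool), 0))
        c_in, L = c_out, L_pool
    flat = c_in * L
    layers.append(LayerInfo("flatten", (flat,), 0))
    layers.append(
        LayerInfo("dense", (config.n_classes,), (flat + 1) * config.n_classes)
    )
    layers.append(LayerInfo("softmax", (config.n_classes,), 0))
    return layers


# ---------------------------------------------------------------------------
# Layers (forward + backward)
# ---------------------------------------------------------------------------

class _Conv1d:
    def __init__(self, c_in, c_out, k, rng, dtype):
        scale = np.sqrt(2.0 / (c_in * k))  # He initialization for ReLU nets
        self.W = rng.normal(0, scale, size=(c_in * k, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad = (k - 1) // 2

    def forward(self, x):  # x: (N, C_in, L)
        N, _, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # (N, C_in, L, k) -> (N, L, C_in*k)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = windows.transpose(0, 2, 1, 3).reshape(N * L, self.c_in * self.k)
        self._cols, self._shape = cols, (N, L)
        out = cols @ self.W + self.b
        return out.reshape(N, L, self.c_out).transpose(0, 2, 1)

    def backward(self, grad):  # grad: (N, C_out, L)
        N, L = self._shape
        g = grad.transpose(0, 2, 1).reshape(N * L, self.c_out)
        self.dW = self._cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(N, L, self.c_in, self.k)
        dxp = np.zeros((N, self.c_in, L + 2 * self.pad), dtype=grad.dtype)
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, self.pad : self.pad + L]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _BatchNorm1d:
    def __init__(self, c, dtype, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):  # x: (N, C, L)
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        N, C, L = grad.shape
        m = N * L
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        gx = grad * self.gamma[None, :, None]
        mean_gx = gx.mean(axis=(0, 2))
        mean_gx_xhat = (gx * self._xhat).mean(axis=(0, 2))
        return (
            gx - mean_gx[None, :, None] - self._xhat * mean_gx_xhat[None, :, None]
        ) / self._std[None, :, None]

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class _MaxPool1d:
    def __init__(self, pool):
        self.pool = pool

    def forward(self, x):  # (N, C, L) -> (N, C, L // pool)
        N, C, L = x.shape
        Lp = L // self.pool
        view = x[:, :, : Lp * self.pool].reshape(N, C, Lp, self.pool)
        self._argmax = view.argmax(axis=3)
        self._in_shape = x.shape
        return view.max(axis=3)

    def backward(self, grad):
        N, C, L = self._in_shape
        Lp = grad.shape[2]
        dview = np.zeros((N, C, Lp, self.pool), dtype=grad.dtype)
        n, c, l = np.indices((N, C, Lp))
        dview[n, c, l, self._argmax] = grad
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, : Lp * self.pool] = dview.reshape(N, C, Lp * self.pool)
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in, d_out, rng, dtype):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0, scale, size=(d_in, d_out)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)

    def forward(self, x):  # (N, D)
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Network:
    """The conv blocks + dense head as an explicit layer stack."""

    def __init__(self, config: CNNConfig, rng, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.blocks = []
        c_in = 1
        for _ in range(config.n_conv_layers):
            self.blocks.append(
                (
                    _Conv1d(c_in, config.kernels_per_layer, config.kernel_size, rng, dtype),
                    _BatchNorm1d(config.kernels_per_layer, dtype),
                    _ReLU(),
                    _MaxPool1d(config.pool_size),
                )
            )
            c_in = config.kernels_per_layer
        flat = c_in * config.conv_lengths()[-1]
        self.dense = _Dense(flat, config.n_classes, rng, dtype)

    def layers(self):
        for block in self.blocks:
            yield from block
        yield self.dense

    def forward(self, X, training=False, rng=None):
        """X: (N, L) standardized spectra -> logits (N, K)."""
        h = X[:, None, :].astype(self.dtype)
        for conv, bn, relu, pool in self.blocks:
            h = pool.forward(relu.forward(bn.forward(conv.forward(h), training)))
        h = h.reshape(h.shape[0], -1)
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            self._drop_mask = (rng.random(h.shape) < keep) / keep
            h = h * self._drop_mask.astype(self.dtype)
        return self.dense.forward(h)

    def backward(self, dlogits):
        grad = self.dense.backward(dlogits.astype(self.dtype))
        if self.config.dropout > 0 and hasattr(self, "_drop_mask"):
            grad = grad * self._drop_mask.astype(self.dtype)
        last_pool = self.blocks[-1][3]
        N = grad.shape[0]
        C = self.config.kernels_per_layer
        grad = grad.reshape(N, C, -1)
        for conv, bn, relu, pool in reversed(self.blocks):
            grad = conv.backward(bn.backward(relu.backward(pool.backward(grad))))
        return grad

    def all_params(self):
        for layer in self.layers():
            for name, value, grad_attr in layer.params():
                yield layer, name, value, grad_attr


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, network: _Network, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.network = network
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, _, v, _ in network.all_params()]
        self.v = [np.zeros_like(v) for _, _, v, _ in network.all_params()]

    def step(self):
        self.t += 1
        for i, (layer, name, value, grad_attr) in enumerate(self.network.all_params()):
            g = getattr(layer, grad_attr)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(value.dtype)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    accuracy: list = field(default_factory=list)  # per-epoch training accuracy
    loss: list = field(default_factory=list)      # per-epoch mean cross-entropy


@dataclass
class FittedCNN:
    config: CNNConfig
    network: _Network
    scaler_mean: np.ndarray
    scaler_std: np.ndarray

    def _standardize(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_length:
            raise SpectraError(
                f"expected {self.config.input_length} wavenumbers, got {X.shape[1]}"
            )
        return (X - self.scaler_mean) / self.scaler_std


def train_cnn(config: CNNConfig, X, y, dtype=np.float32) -> tuple[FittedCNN, TrainHistory]:
    """Train the spectral CNN by mini-batch Adam on cross-entropy.

    Deterministic given ``config.seed`` on a fixed platform: the same
    generator drives initialization and the epoch shuffler.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[1] != config.input_length:
        raise SpectraError(
            f"config.input_length={config.input_length} but data has {X.shape[1]} columns"
        )
    if y.min() < 0 or y.max() >= config.n_classes:
        raise SpectraError("labels outside {0..n_classes-1}")

    mean = X.mean(axis=0)
    if config.scaler == "per_wavenumber":
        std = X.std(axis=0)
        std[std < 1e-8] = 1.0
    else:  # one pooled scale keeps low-variance channels quiet
        pooled = float(np.sqrt((X - mean).var()))
        std = np.full(X.shape[1], pooled if pooled > 1e-12 else 1.0)
    Xs = (X - mean) / std

    rng = np.random.default_rng(config.seed)
    net = _Network(config, rng, dtype=dtype)
    opt = _Adam(net, config.learning_rate)
    n = X.shape[0]
    onehot = np.zeros((n, config.n_classes))
    onehot[np.arange(n), y] = 1.0

    history = TrainHistory()
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_hits = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(Xs[idx], training=True, rng=rng)
            probs = softmax(logits)
            eps = 1e-12
            loss = -np.log(probs[np.arange(idx.size), y[idx]] + eps).mean()
            if not np.isfinite(loss):
                raise SpectraError(
                    f"non-finite training loss at Adam step {opt.t + 1}; "
                    "lower the learning rate"
                )
            epoch_loss += loss * idx.size
            epoch_hits += int((logits.argmax(axis=1) == y[idx]).sum())
            net.backward((probs - onehot[idx]) / idx.size)
            opt.step()
        history.loss.append(float(epoch_loss / n))
        history.accuracy.append(epoch_hits / n)
    return FittedCNN(config, net, mean, std), history


def cnn_predict(model: FittedCNN, X) -> tuple[np.ndarray, np.ndarray]:
    """Predict (labels, softmax probability matrix) for new spectra."""
    Xs = model._standardize(X)
    probs_parts = []
    for start in range(0, Xs.shape[0], 256):
        logits = model.network.forward(Xs[start : start + 256], training=False)
        probs_parts.append(softmax(logits))
    probs = np.vstack(probs_parts)
    return probs.argmax(axis=1), probs


def hyperparameter_sweep(
    base: CNNConfig, axis: str, values, X, y, X_test=None, y_test=None
) -> tuple[list[dict], dict]:
    """Train one model per candidate value of one hyperparameter axis.

    All other settings (and the seed) are held at ``base``.  Returns
    ``(rows, histories)`` where each row carries the candidate value, the
    final training accuracy/loss, and — when test data is supplied — the
    test accuracy.
    """
    if axis not in _AXIS_FIELD:
        raise SpectraError(
            f"unknown sweep axis {axis!r}; expected one of {sorted(_AXIS_FIELD)}"
        )
    rows, histories = [], {}
    for value in values:
        config = replace(base, **{_AXIS_FIELD[axis]: value})
        model, history = train_cnn(config, X, y)
        row = {
            "axis": axis,
            "value": value,
            "final_train_accuracy": history.accuracy[-1],
            "final_train_loss": history.loss[-1],
        }
        if X_test is not None:
            pred, _ = cnn_predict(model, X_test)
            row["test_accuracy"] = float((pred == np.asarray(y_test)).mean())
        rows.append(row)
        histories[value] = history
    return rows, histories


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SpectralCNN1D:
    """Spectral CNN classifier, statsmodels-style: build from data, ``fit()``
    returns a results object carrying the trained network and diagnostics."""

    def __init__(self, X, y, config: CNNConfig | None = None, **config_overrides):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=int)
        if config is None:
            config = CNNConfig(
                input_length=self.X.shape[1],
                n_classes=int(self.y.max()) + 1,
                **config_overrides,
            )
        self.config = config

    def fit(self) -> "CNNResults":
        model, history = train_cnn(self.config, self.X, self.y)
        return CNNResults(self, model, history)


@dataclass
class CNNResults:
    model_input: SpectralCNN1D
    model: FittedCNN
    history: TrainHistory

    def predict(self, X) -> np.ndarray:
        return cnn_predict(self.model, X)[0]

    def predict_proba(self, X) -> np.ndarray:
        return cnn_predict(self.model, X)[1]

    @property
    def training_accuracy(self) -> float:
        return self.history.accuracy[-1]

    def summary(self) -> str:
        c = self.model.config
        lines = [
            "1-D convolutional network for spectra",
            "=" * 44,
            f"conv blocks          {c.n_conv_layers:>10}",
            f"kernels per layer    {c.kernels_per_layer:>10}",
            f"kernel size          {c.kernel_size:>10}",
            f"batch size           {c.batch_size:>10}",
            f"learning rate        {c.learning_rate:>10.2g}",
            f"epochs               {c.epochs:>10}",
            f"parameters           {sum(l.n_params for l in build_cnn(c)):>10}",
            f"final train loss     {self.history.loss[-1]:>10.4f}",
            f"final train accuracy {100 * self.training_accuracy:>9.2f}%",
        ]
        return "\n".join(lines)
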