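"""Feed-forward and 1-D convolutional regression networks in plain numpy.

A compact neural-network engine with manual backpropagation: fully connected
stacks (affine + activation + inverted dropout) for genomic, soil and fusion
modules, and 1-D convolution blocks with max/average pooling for the daily
weather series.  All networks end in a single linear output unit and are
trained by mini-batch Adam on the root-mean-square-error loss.

With the identity activation and a single layer the network degenerates to
ordinary linear regression, which is used as a correctness oracle in the
tests.  Replicate seeds control weight initialization and batch shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigError, ShapeError

__all__ = [
    "ArchitectureSpec",
    "TrainingSpec",
    "FFNConfig",
    "SearchSpace",
    "Network",
    "build_network",
]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda z, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
}


# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: list

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(scale=scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def n_params(self):
        return self.W.size + self.b.size


class Activation(_Layer):
    params = []

    def __init__(self, name):
        self.fn, self.dfn = _ACTIVATIONS[name]

    def forward(self, x, training=False):
        self._z = x
        self._a = self.fn(x)
        return self._a

    def backward(self, grad):
        return grad * self.dfn(self._z, self._a)


class Dropout(_Layer):
    params = []

    def __init__(self, rate, rng):
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv1D(_Layer):
    """Valid 1-D convolution over (batch, channels, length) inputs."""

    def __init__(self, n_channels, n_filters, kernel_size, rng):
        scale = np.sqrt(2.0 / (n_channels * kernel_size))
        self.W = rng.normal(scale=scale, size=(n_filters, n_channels, kernel_size))
        self.b = np.zeros(n_filters)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [(self.W, self.gW), (self.b, self.gb)]
        self.ksize = kernel_size

    def forward(self, x, training=False):
        if x.shape[2] < self.ksize:
            raise ShapeError("input shorter than convolution kernel")
        xs = np.lib.stride_tricks.sliding_window_view(x, self.ksize, axis=2)
        self._xs, self._xshape = xs, x.shape
        return np.einsum("bctk,fck->bft", xs, self.W) + self.b[None, :, None]

    def backward(self, grad):
        self.gW[...] = np.einsum("bft,bctk->fck", grad, self._xs)
        self.gb[...] = grad.sum(axis=(0, 2))
        gx = np.zeros(self._xshape)
        for k in range(self.ksize):
            gx[:, :, k : k + grad.shape[2]] += np.einsum(
                "bft,fc->bct", grad, self.W[:, :, k]
            )
        return gx

    def n_params(self):
        return self.W.size + self.b.size


class Pool1D(_Layer):
    params = []

    def __init__(self, kind="max", size=2):
        if kind not in ("max", "avg"):
            raise InvalidConfigError(f"unknown pooling kind {kind!r}")
        self.kind, self.size = kind, size

    def forward(self, x, training=False):
        b, c, t = x.shape
        n = t // self.size
        if n < 1:
            self._passthrough = True
            return x
        self._passthrough = False
        xr = x[:, :, : n * self.size].reshape(b, c, n, self.size)
        self._in_shape = x.shape
        if self.kind == "max":
            self._arg = xr.argmax(axis=3)
            return xr.max(axis=3)
        return xr.mean(axis=3)

    def backward(self, grad):
        if self._passthrough:
            return grad
        b, c, t = self._in_shape
        n = grad.shape[2]
        gx = np.zeros((b, c, n, self.size))
        if self.kind == "max":
            bi, ci, ni = np.ogrid[:b, :c, :n]
            gx[bi, ci, ni, self._arg] = grad
        else:
            gx[...] = grad[..., None] / self.size
        out = np.zeros(self._in_shape)
        out[:, :, : n * self.size] = gx.reshape(b, c, n * self.size)
        return out


class Flatten(_Layer):
    params = []

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ArchitectureSpec:
    """Architecture of one network module.

    Dense modules (genomic/soil/fusion) use ``units``/``dropout`` per layer;
    the weather module uses convolution blocks of ``conv_layers_per_block``
    convolutions each, followed by pooling, then a dense head.
    """

    kind: str  # genomic | soil | weather | fusion
    activation: str = "relu"
    units: tuple = (32,)
    dropout: tuple = (0.0,)
    conv_blocks: int = 1
    conv_layers_per_block: int = 1
    filters: tuple = (8,)
    pooling: str = "max"
    kernel_size: int = 3

    def __post_init__(self):
        if self.kind not in ("genomic", "soil", "weather", "fusion"):
            raise InvalidConfigError(f"unknown module kind {self.kind!r}")
        if self.activation not in _ACTIVATIONS:
            raise InvalidConfigError(f"unknown activation {self.activation!r}")
        if self.kind == "weather":
            if len(self.filters) != self.conv_blocks * self.conv_layers_per_block:
                raise InvalidConfigError("filters must list one width per conv layer")
            if self.conv_blocks < 1:
                raise InvalidConfigError("at least one convolution block required")
        else:
            if len(self.units) < 1:
                raise InvalidConfigError("at least one layer required")
            if len(self.dropout) != len(self.units):
                raise InvalidConfigError("dropout must list one rate per layer")


@dataclass(frozen=True)
class TrainingSpec:
    """Adam optimizer and batching hyperparameters."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 500


@dataclass(frozen=True)
class FFNConfig:
    arch: ArchitectureSpec
    training: TrainingSpec


@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges per hyperparameter.

    Defaults mirror the study configuration: 1-7 dense layers, 4-256 units
    (genomic) or 4-64 (soil/fusion), dropout 0-0.3, 1-7 convolution blocks of
    1-4 layers with 4-512 filters and max/average pooling, learning-rate grid
    {0.1, 0.01, 0.001, 0.0001}, Adam betas in [0.9, 0.9999], batch size
    32-256 in steps of 16.
    """

    kind: str = "genomic"
    layers: tuple = (1, 7)
    units: tuple = (4, 256)
    dropout: tuple = (0.0, 0.3)
    conv_blocks: tuple = (1, 7)
    conv_layers_per_block: tuple = (1, 4)
    filters: tuple = (4, 512)
    pooling: tuple = ("max", "avg")
    learning_rates: tuple = (0.1, 0.01, 0.001, 0.0001)
    betas: tuple = (0.9, 0.9999)
    batch_size: tuple = (32, 256, 16)
    max_epochs: int = 500
    activations: tuple = ("relu",)

    @classmethod
    def for_kind(cls, kind: str, activations=("relu",)) -> "SearchSpace":
        units = (4, 256) if kind == "genomic" else (4, 64)
        return cls(kind=kind, units=units, activations=tuple(activations))

    @classmethod
    def desk(cls, kind: str, activations=("relu",)) -> "SearchSpace":
        """Shrunk ranges for small simulated datasets."""
        return cls(
            kind=kind,
            layers=(1, 3),
            units=(4, 32),
            conv_blocks=(1, 2),
            conv_layers_per_block=(1, 2),
            filters=(4, 16),
            batch_size=(32, 64, 16),
            max_epochs=100,
            activations=tuple(activations),
        )

    def sample(self, rng) -> FFNConfig:
        """Draw one configuration uniformly from the space."""
        act = str(rng.choice(self.activations))
        if self.kind == "weather":
            nb = int(rng.integers(self.conv_blocks[0], self.conv_blocks[1] + 1))
            npb = int(
                rng.integers(
                    self.conv_layers_per_block[0], self.conv_layers_per_block[1] + 1
                )
            )
            filters = tuple(
                int(rng.integers(self.filters[0], self.filters[1] + 1))
                for _ in range(nb * npb)
            )
            arch = ArchitectureSpec(
                kind=self.kind,
                activation=act,
                conv_blocks=nb,
                conv_layers_per_block=npb,
                filters=filters,
                pooling=str(rng.choice(self.pooling)),
            )
        else:
            nl = int(rng.integers(self.layers[0], self.layers[1] + 1))
            units = tuple(
                int(rng.integers(self.units[0], self.units[1] + 1)) for _ in range(nl)
            )
            drops = tuple(rng.uniform(*self.dropout) for _ in range(nl))
            arch = ArchitectureSpec(
                kind=self.kind, activation=act, units=units, dropout=drops
            )
        lo, hi, step = self.batch_size
        batch = int(rng.choice(np.arange(lo, hi + 1, step)))
        training = TrainingSpec(
            learning_rate=float(rng.choice(self.learning_rates)),
            beta1=float(rng.uniform(*self.betas)),
            beta2=float(rng.uniform(*self.betas)),
            batch_size=batch,
            max_epochs=self.max_epochs,
        )
        return FFNConfig(arch=arch, training=training)


# ---------------------------------------------------------------------------
# network


class Network:
    """A trainable stack of layers with a single linear output unit."""

    def __init__(self, layers, final: Dense, rng):
        self.layers = list(layers)
        self.final = final
        self.rng = rng
        self._adam_state = None
        self._all_layers = self.layers + [self.final]

    # -- passes ----------------------------------------------------------

    def _forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def penultimate(self, X) -> np.ndarray:
        """Final hidden representation (input to the output unit)."""
        return self._forward(np.asarray(X, dtype=float), training=False)

    def predict(self, X) -> np.ndarray:
        h = self.penultimate(X)
        return (self.final.forward(h)).ravel()

    def n_params(self) -> int:
        return sum(
            layer.n_params() for layer in self._all_layers if hasattr(layer, "n_params")
        )

    # -- training --------------------------------------------------------

    def _adam_step(self, lr, beta1, beta2, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = [
                (np.zeros_like(p), np.zeros_like(p))
                for layer in self._all_layers
                for (p, _) in layer.params
            ]
            self._adam_t = 0
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self._all_layers:
            for p, grad in layer.params:
                m, v = self._adam_state[i]
                m *= beta1
                m += (1 - beta1) * grad
                v *= beta2
                v += (1 - beta2) * grad**2
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    def _loss_and_grad(self, pred, y):
        # monitored loss is RMSE; the optimization gradient is that of the
        # mean squared error, which shares the minimizer and stays smooth at 0
        resid = pred.ravel() - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        grad = (2.0 * resid / resid.size).reshape(pred.shape)
        return rmse, grad

    def evaluate(self, X, y) -> float:
        """RMSE on a dataset (evaluation mode, no dropout)."""
        pred = self.predict(X)
        return float(np.sqrt(np.mean((pred - np.asarray(y)) ** 2)))

    def fit(
        self,
        X,
        y,
        epochs: int,
        X_val=None,
        y_val=None,
        patience: int = None,
        spec: TrainingSpec = None,
    ) -> list:
        """Train by mini-batch Adam; returns the per-epoch validation RMSE.

        Without a validation set the training RMSE trajectory is returned.
        ``patience`` enables early stopping when the monitored loss has not
        improved for that many epochs.
        """
        spec = spec or TrainingSpec()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        history = []
        best, since_best = np.inf, 0
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                xb, yb = X[idx], y[idx]
                h = self._forward(xb, training=True)
                pred = self.final.forward(h)
                _, grad = self._loss_and_grad(pred, yb)
                grad = self.final.backward(grad)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self._adam_step(spec.learning_rate, spec.beta1, spec.beta2)
            if X_val is not None:
                loss = self.evaluate(X_val, y_val)
            else:
                loss = self.evaluate(X, y)
            history.append(loss)
            if patience is not None:
                if loss < best - 1e-12:
                    best, since_best = loss, 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        return history


def build_network(spec: ArchitectureSpec, input_shape, seed: int = 0) -> Network:
    """Instantiate a trainable network for the given input shape.

    ``input_shape`` is an int (number of features) for dense modules or a
    (channels, length) pair for the weather module.
    """
    rng = np.random.default_rng(seed)
    layers = []
    if spec.kind == "weather":
        try:
            channels, length = input_shape
        except TypeError:
            raise ShapeError("weather module needs a (channels, length) input shape")
        c = channels
        t = length
        fi = iter(spec.filters)
        for _ in range(spec.conv_blocks):
            for _ in range(spec.conv_layers_per_block):
                f = next(fi)
                if t < 3:
                    raise ShapeError("weather series too short for the requested blocks")
                layers.append(Conv1D(c, f, spec.kernel_size, rng))
                layers.append(Activation(spec.activation))
                c, t = f, t - spec.kernel_size + 1
            layers.append(Pool1D(spec.pooling, 2))
            t = t // 2 if t >= 2 else t  # Pool1D passes through length-1 inputs
        layers.append(Flatten())
        n_feat = c * t
    else:
        n_feat = int(input_shape)
        for units, rate in zip(spec.units, spec.dropout):
            layers.append(Dense(n_feat, units, rng))
            layers.append(Activation(spec.activation))
            if rate > 0:
                layers.append(Dropout(rate, rng))
            n_feat = units
    final = Dense(n_feat, 1, rng)
    return Network(layers, final, rng)
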