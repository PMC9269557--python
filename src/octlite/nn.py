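"""Minimal numpy backend for the model family: layers, backprop, Adam.

The architecture module describes models abstractly; this module turns an
:class:`~octlite.arch.ArchitectureSpec` into a runnable network. Every layer
implements ``forward`` (caching what backward needs) and ``backward``
(returning the input gradient and accumulating parameter gradients), so the
same machinery drives training, prediction and Grad-CAM.

Conventions match the usual channels-last deep-learning stack: tensors are
``(N, H, W, C)`` float32, convolutions are valid with stride 1, pools use
stride = pool size, batch normalization keeps momentum-0.9 moving statistics
(eps 1e-3; the faster-adapting momentum suits the desk-scale runs this
backend is built for), dropout is inverted (scaled at train time), and the final dense
layer's softmax is applied together with the categorical cross-entropy loss
for numerical stability.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import ArchitectureSpec

__all__ = ["Network", "Adam", "softmax"]

_BN_MOMENTUM = 0.9
_BN_EPS = 1e-3


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted for stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base runtime layer. Subclasses fill ``params``/``grads`` dicts and the
    ``trainable`` name set; non-trainable entries (batch-norm statistics) are
    saved with the weights but skipped by the optimizer."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable: set[str] = set()

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, rng, kernel: int, c_in: int, c_out: int) -> None:
        super().__init__()
        self.k = kernel
        self.params = {
            "W": _he_normal(rng, (kernel, kernel, c_in, c_out), kernel * kernel * c_in),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.trainable = {"W", "b"}

    def forward(self, x, training, rng):
        self._patches = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        return (
            np.einsum("nhwcij,ijco->nhwo", self._patches, self.params["W"], optimize=True)
            + self.params["b"]
        )

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] = np.einsum("nhwcij,nhwo->ijco", self._patches, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        n, ho, wo, _ = dy.shape
        dx = np.zeros(
            (n, ho + self.k - 1, wo + self.k - 1, W.shape[2]), dtype=np.float32
        )
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i : i + ho, j : j + wo, :] += np.einsum(
                    "nhwo,co->nhwc", dy, W[i, j], optimize=True
                )
        return dx


class SeparableConv2D(Layer):
    """Depthwise (multiplier 1) spatial convolution + 1x1 pointwise mix."""

    def __init__(self, rng, kernel: int, c_in: int, c_out: int) -> None:
        super().__init__()
        self.k = kernel
        self.params = {
            "Wd": _he_normal(rng, (kernel, kernel, c_in), kernel * kernel),
            "Wp": _he_normal(rng, (c_in, c_out), c_in),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.trainable = {"Wd", "Wp", "b"}

    def forward(self, x, training, rng):
        self._patches = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        self._mid = np.einsum(
            "nhwcij,ijc->nhwc", self._patches, self.params["Wd"], optimize=True
        )
        return self._mid @ self.params["Wp"] + self.params["b"]

    def backward(self, dy):
        Wd, Wp = self.params["Wd"], self.params["Wp"]
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        self.grads["Wp"] = np.einsum("nhwc,nhwo->co", self._mid, dy, optimize=True)
        dmid = dy @ Wp.T
        self.grads["Wd"] = np.einsum(
            "nhwcij,nhwc->ijc", self._patches, dmid, optimize=True
        )
        n, ho, wo, c = dmid.shape
        dx = np.zeros((n, ho + self.k - 1, wo + self.k - 1, c), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i : i + ho, j : j + wo, :] += dmid * Wd[i, j]
        return dx


class BatchNorm(Layer):
    """Per-channel normalization over all non-channel axes."""

    def __init__(self, c: int) -> None:
        super().__init__()
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
            "moving_mean": np.zeros(c, dtype=np.float32),
            "moving_var": np.ones(c, dtype=np.float32),
        }
        self.trainable = {"gamma", "beta"}

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            p = self.params
            p["moving_mean"] = (
                _BN_MOMENTUM * p["moving_mean"] + (1 - _BN_MOMENTUM) * mean
            ).astype(np.float32)
            p["moving_var"] = (
                _BN_MOMENTUM * p["moving_var"] + (1 - _BN_MOMENTUM) * var
            ).astype(np.float32)
        else:
            mean = self.params["moving_mean"]
            var = self.params["moving_var"]
        self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) * self._inv_std
        self._m = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not self._training:
            # Inference normalization is a fixed affine map per channel.
            return dy * (g * self._inv_std)
        m = self._m
        dxhat = dy * g
        return (
            self._inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        ).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool(Layer):
    def __init__(self, pool: tuple[int, int]) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        ph, pw = self.pool
        n, h, w, c = x.shape
        ho, wo = h // ph, w // pw
        self._in_shape = x.shape
        self._windows = x[:, : ho * ph, : wo * pw, :].reshape(n, ho, ph, wo, pw, c)
        out = self._windows.max(axis=(2, 4))
        # Maxima mask for backward; exact float ties share the gradient.
        self._mask = self._windows == out[:, :, None, :, None, :]
        return out

    def backward(self, dy):
        ph, pw = self.pool
        n, h, w, c = self._in_shape
        ho, wo = h // ph, w // pw
        spread = self._mask * dy[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : ho * ph, : wo * pw, :] = spread.reshape(n, ho * ph, wo * pw, c)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        return dy if self._mask is None else (dy * self._mask).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int) -> None:
        super().__init__()
        self.params = {
            "W": _he_normal(rng, (n_in, n_out), n_in),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.trainable = {"W", "b"}

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Network:
    """A runnable model built from an :class:`ArchitectureSpec`.

    The last dense layer's logits are returned raw; ``predict_proba``
    applies the softmax. ReLU activations declared on conv/dense spec layers
    are inserted after the batch normalization that follows them.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        self.conv_layer_names: list[str] = []

        shape: tuple[int, ...] = tuple(spec.input_shape)
        pending_relu: str | None = None
        counts: dict[str, int] = {}

        def add(layer: Layer, kind: str) -> None:
            idx = counts.get(kind, 0)
            counts[kind] = idx + 1
            layer.name = f"{kind}_{idx}"
            self.layers.append(layer)

        specs = list(spec.layers)
        for i, ls in enumerate(specs):
            nxt = specs[i + 1] if i + 1 < len(specs) else None
            if ls.kind == "conv2d":
                add(Conv2D(self.rng, ls.kernel, shape[-1], ls.filters), "conv")
                shape = (shape[0] - ls.kernel + 1, shape[1] - ls.kernel + 1, ls.filters)
            elif ls.kind == "separable_conv2d":
                add(SeparableConv2D(self.rng, ls.kernel, shape[-1], ls.filters), "sepconv")
                shape = (shape[0] - ls.kernel + 1, shape[1] - ls.kernel + 1, ls.filters)
            elif ls.kind == "batch_norm":
                add(BatchNorm(shape[-1]), "bn")
            elif ls.kind == "max_pool":
                add(MaxPool(ls.pool), "pool")
                shape = (shape[0] // ls.pool[0], shape[1] // ls.pool[1], shape[2])
            elif ls.kind == "dropout":
                add(Dropout(ls.rate), "dropout")
            elif ls.kind == "flatten":
                add(Flatten(), "flatten")
                n = 1
                for d in shape:
                    n *= d
                shape = (n,)
            elif ls.kind == "dense":
                add(Dense(self.rng, shape[-1], ls.units), "dense")
                shape = (ls.units,)
            else:
                raise ValueError(f"unknown layer kind {ls.kind!r}")

            if ls.kind in ("conv2d", "separable_conv2d"):
                self.conv_layer_names.append(self.layers[-1].name)
            if ls.kind in ("conv2d", "separable_conv2d", "dense") and ls.activation == "relu":
                if nxt is not None and nxt.kind == "batch_norm":
                    pending_relu = "after_bn"
                else:
                    add(ReLU(), "relu")
            elif ls.kind == "batch_norm" and pending_relu == "after_bn":
                add(ReLU(), "relu")
                pending_relu = None

    # -- execution ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch (N, H, W, C) of float32 inputs."""
        out = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training, self.rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, batched; rows sum to 1."""
        x = np.asarray(x, dtype=np.float32)
        chunks = [
            softmax(self.forward(x[i : i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def train_step(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        """One forward/backward pass; returns the mean cross-entropy loss.

        Parameter gradients are left in each layer's ``grads`` for the
        optimizer to consume.
        """
        logits = self.forward(x, training=True)
        probs = softmax(logits)
        n = len(x)
        loss = float(-np.mean(np.log(np.sum(probs * y_onehot, axis=1) + 1e-12)))
        grad = ((probs - y_onehot) / n).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def gradient_wrt_layer(
        self, x: np.ndarray, class_idx: int, layer_name: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Activations of ``layer_name`` and the gradient of the target
        class's pre-softmax score with respect to them (inference mode)."""
        names = [l.name for l in self.layers]
        if layer_name not in names:
            raise ValueError(f"no layer named {layer_name!r}; have {names}")
        idx = names.index(layer_name)
        out = np.ascontiguousarray(x, dtype=np.float32)
        activation = None
        for layer in self.layers:
            out = layer.forward(out, training=False, rng=self.rng)
            if layer.name == layer_name:
                activation = out
        grad = np.zeros_like(out)
        grad[:, class_idx] = 1.0
        for layer in reversed(self.layers[idx + 1 :]):
            grad = layer.backward(grad)
        return activation, grad

    # -- parameters ---------------------------------------------------------

    def parameter_arrays(self) -> list[tuple[str, np.ndarray, bool]]:
        """Every weight container as (qualified name, array, trainable)."""
        out = []
        for layer in self.layers:
            for key, arr in layer.params.items():
                out.append((f"{layer.name}.{key}", arr, key in layer.trainable))
        return out

    def save_weights(self, path) -> None:
        np.savez(path, **{name: arr for name, arr, _ in self.parameter_arrays()})

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for layer in self.layers:
                for key in layer.params:
                    layer.params[key] = data[f"{layer.name}.{key}"]


class Adam:
    """Adam optimizer over a network's trainable parameters."""

    def __init__(self, network: Network, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.network = network
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for layer in self.network.layers:
            for key in layer.trainable:
                grad = layer.grads.get(key)
                if grad is None:
                    continue
                slot = f"{layer.name}.{key}"
                m = self.m.setdefault(slot, np.zeros_like(layer.params[key]))
                v = self.v.setdefault(slot, np.zeros_like(layer.params[key]))
                m[...] = self.b1 * m + (1 - self.b1) * grad
                v[...] = self.b2 * v + (1 - self.b2) * grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                layer.params[key] -= (
                    self.lr * mhat / (np.sqrt(vhat) + self.eps)
                ).astype(np.float32)
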