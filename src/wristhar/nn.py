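"""Minimal 1D convolutional network engine in numpy.

Implements exactly the pieces the activity classifier needs — valid 1D
convolutions, swish/ReLU activations, spatial (whole-channel) dropout,
ordinary dropout, global average pooling, dense layers, a softmax
cross-entropy head, transient Gaussian weight noise, Adam and SGD with
step learning-rate decay, and per-layer freezing — with hand-written
backpropagation.  Everything is driven by an explicit
``numpy.random.Generator``, so training is exactly reproducible from a
seed, and frozen layers are bit-identical before and after training.

Shapes: convolutional tensors are (N, C, L); dense tensors (N, F).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: optional parameters in ``params``, matching ``grads``."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding) 1D convolution, stride 1.

    ``weight_noise_sd > 0`` adds transient Gaussian noise to the weights on
    training forward passes only; the stored parameters stay noise-free
    and gradients are applied to the clean weights.
    """

    def __init__(self, name: str, c_in: int, c_out: int, kernel: int,
                 weight_noise_sd: float = 0.0, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.name = name
        self.kernel = kernel
        self.weight_noise_sd = weight_noise_sd
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": (rng.standard_normal((c_out, c_in, kernel)) * scale),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training, rng):
        W = self.params["W"]
        if training and self.weight_noise_sd > 0:
            W = W + rng.normal(0.0, self.weight_noise_sd, W.shape)
        self._x = x
        self._W_used = W
        windows = sliding_window_view(x, self.kernel, axis=2)  # (N, C_in, L_out, K)
        return np.einsum("nclk,ock->nol", windows, W, optimize=True) + self.params["b"][None, :, None]

    def backward(self, dy):
        x, W = self._x, self._W_used
        windows = sliding_window_view(x, self.kernel, axis=2)
        self.grads["W"] = np.einsum("nclk,nol->ock", windows, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2))
        # dx = full correlation of dy with the flipped kernel
        pad = self.kernel - 1
        dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad)))
        dyw = sliding_window_view(dyp, self.kernel, axis=2)  # (N, C_out, L_in, K)
        Wf = W[:, :, ::-1]
        return np.einsum("nolk,ock->ncl", dyw, Wf, optimize=True)


class Swish(Layer):
    def forward(self, x, training, rng):
        s = _sigmoid(x)
        self._x, self._s = x, s
        return x * s

    def backward(self, dy):
        x, s = self._x, self._s
        return dy * (s + x * s * (1.0 - s))


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class SpatialDropout(Layer):
    """Whole-channel dropout for (N, C, L) feature maps (inverted scaling)."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=(x.shape[0], x.shape[1], 1)) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C) mean over time."""

    def forward(self, x, training, rng):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._L, axis=2) / self._L


class Dense(Layer):
    def __init__(self, name: str, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.name = name
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.standard_normal((n_in, n_out)) * scale, "b": np.zeros(n_out)}

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-15, 1.0)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Network:
    """An ordered stack of layers with named parameterized layers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def named_layers(self) -> dict[str, Layer]:
        return {l.name: l for l in self.layers if l.params}

    def get_params(self) -> dict[str, dict[str, np.ndarray]]:
        return {name: {k: v.copy() for k, v in l.params.items()} for name, l in self.named_layers().items()}

    def set_params(self, params: dict[str, dict[str, np.ndarray]]) -> None:
        for name, layer in self.named_layers().items():
            for k in layer.params:
                layer.params[k] = params[name][k].copy()

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SGD:
    def __init__(self, lr: float) -> None:
        self.lr = lr

    def step(self, network: Network, frozen: set[str]) -> None:
        for name, layer in network.named_layers().items():
            if name in frozen:
                continue
            for k in layer.params:
                layer.params[k] -= self.lr * layer.grads[k]


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple, np.ndarray] = {}
        self.v: dict[tuple, np.ndarray] = {}

    def step(self, network: Network, frozen: set[str]) -> None:
        self.t += 1
        for name, layer in network.named_layers().items():
            if name in frozen:
                continue
            for k, g in layer.grads.items():
                key = (name, k)
                m = self.m.setdefault(key, np.zeros_like(g))
                v = self.v.setdefault(key, np.zeros_like(g))
                m[:] = self.beta1 * m + (1 - self.beta1) * g
                v[:] = self.beta2 * v + (1 - self.beta2) * g * g
                mh = m / (1 - self.beta1**self.t)
                vh = v / (1 - self.beta2**self.t)
                layer.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class StepDecay:
    """Multiply the learning rate by ``factor`` every ``every`` epochs."""

    def __init__(self, base_lr: float, every: int, factor: float) -> None:
        if not 0 < factor < 1:
            raise ValueError("decay factor must be in (0, 1)")
        self.base_lr, self.every, self.factor = base_lr, every, factor

    def lr_at(self, epoch: int) -> float:
        return self.base_lr * self.factor ** (epoch // self.every)
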