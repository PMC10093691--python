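"""Minimal numpy CNN engine: layers with explicit backprop, Adam, losses.

All tensors are float32 NCHW. Every layer caches what its backward pass
needs on forward; ``backward`` consumes the upstream gradient and both
accumulates parameter gradients and returns the input gradient. Freezing
is per-parameter (``Parameter.trainable``): the optimizer skips frozen
parameters entirely, so frozen weights stay bit-identical through
training.

Convolutions use im2col via ``numpy.lib.stride_tricks.sliding_window_view``
and a single BLAS matmul; col2im in the backward pass is a k*k loop over
array slices (no per-pixel scatter).
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np

from .exceptions import TrainingError, ValidationError


class Parameter:
    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer. Subclasses implement forward/backward."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' output size for odd kernels.

    For even kernels the padding is (0, k-1) style asymmetric so the
    spatial size is preserved (used by the 2x2 up-convolutions).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, name: str = ""):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in), name=f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32), name=f"{name}.bias")
        self._pad = ((kernel - 1) // 2, kernel // 2)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValidationError(f"Conv2d expected {self.c_in} channels, got {c}")
        pl, pr = self._pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        wmat = self.weight.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.bias.value
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cols is None or self._xshape is None:
            raise TrainingError("backward called before forward(train=True)")
        n, c, h, w = self._xshape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.weight.grad += (g.T @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.value.reshape(self.c_out, -1)  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        pl, pr = self._pad
        dxp = np.zeros((n, c, h + pl + pr, w + pl + pr), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, pl : pl + h, pl : pl + w]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = ""):
        self.n_in, self.n_out = n_in, n_out
        self.weight = Parameter(_he_init(rng, (n_in, n_out), n_in), name=f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32), name=f"{name}.bias")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.n_in:
            raise ValidationError(f"Dense expected {self.n_in} features, got {x.shape[-1]}")
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.value.T
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return grad * self._mask


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = sigmoid(x)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._out is not None
        return grad * self._out * (1.0 - self._out)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Spatial dims must be even."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValidationError("MaxPool2 needs even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._idx is not None and self._shape is not None
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; active only when train=True. Draws from its own rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValidationError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(np.float32).copy()


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def backward_until(self, grad: np.ndarray, stop: int) -> np.ndarray:
        """Backward through layers[stop:] only (prefix is frozen/untouched)."""
        for layer in reversed(self.layers[stop:]):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# parameter accounting / freezing


def parameter_count(model: Layer, trainable_only: bool = True) -> int:
    return sum(int(p.value.size) for p in model.parameters() if p.trainable or not trainable_only)


def set_trainable(layers: Iterable[Layer], trainable: bool) -> None:
    for layer in layers:
        for p in layer.parameters():
            p.trainable = trainable


# ---------------------------------------------------------------------------
# losses


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits.

    Returns (mean loss, gradient w.r.t. logits).
    """
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(logits.astype(np.float32)) - targets.reshape(logits.shape)) / z.size).astype(np.float32)
    return loss, grad


DICE_EPS = 1e-6


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    """Per-sample soft Dice loss, averaged over the batch.

    pred: probabilities (n, 1, h, w); target: binary, same shape.
    Returns (mean loss, gradient w.r.t. pred).
    """
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {target.shape}")
    p = pred.astype(np.float64)
    g = target.astype(np.float64)
    axes = tuple(range(1, p.ndim))
    inter = (p * g).sum(axis=axes)
    sums = p.sum(axis=axes) + g.sum(axis=axes)
    dice = (2.0 * inter + eps) / (sums + eps)
    loss = float(np.mean(1.0 - dice))
    n = p.shape[0]
    # d(1 - dice_i)/dp = -(2 g (sums+eps) - (2 inter+eps)) / (sums+eps)^2, /n for the mean
    denom = (sums + eps)[:, None, None, None] if p.ndim == 4 else (sums + eps).reshape((-1,) + (1,) * (p.ndim - 1))
    num = (2.0 * inter + eps).reshape(denom.shape)
    grad = (-(2.0 * g * denom - num) / denom**2 / n).astype(np.float32)
    return loss, grad


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# checkpoint I/O (native .npz + JSON sidecar)


def save_checkpoint(model: Layer, path: str, sidecar: dict | None = None) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def load_checkpoint(model: Layer, path: str) -> None:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    params = model.parameters()
    if len(data.files) != len(params):
        raise ValidationError("checkpoint does not match model architecture")
    for i, p in enumerate(params):
        arr = data[f"p{i}"]
        if arr.shape != p.value.shape:
            raise ValidationError(f"checkpoint shape mismatch at parameter {i}")
        p.value[...] = arr
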