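"""A small 1-D convolutional network in pure numpy.

The architecture mirrors the VTA predictor: four stacks of
convolution (ReLU) -> batch normalization -> max pooling over a 1000-point
resampled RR input, a flatten, and a dense head ending in a single sigmoid
unit. Filter counts and kernel sizes default to (3,102), (10,24), (10,11),
(10,9); convolutions are stride 1 with valid (no) padding and pooling is
max-pool of size 2, stride 2.

Training is mini-batch Adam on the binary cross-entropy, computed on logits
for numerical stability; the sigmoid is applied at prediction time. With a
fixed seed and single-threaded BLAS the fit is bit-reproducible.

Arrays flow as (batch, channels, length); dense layers as (batch, features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class SpecificationError(ValueError):
    """A layer specification is inconsistent with the input shape."""


class DivergenceError(RuntimeError):
    """Training loss became NaN; try a lower learning rate."""


@dataclass(frozen=True)
class ConvBlockSpec:
    filters: int
    kernel_size: int
    stride: int = 1
    padding: str = "valid"  # or "same"
    batch_norm: bool = True
    pool_size: int = 2


@dataclass(frozen=True)
class CNNSpec:
    """Declarative description of the network."""

    input_length: int = 1000
    conv_blocks: Tuple[ConvBlockSpec, ...] = (
        ConvBlockSpec(3, 102),
        ConvBlockSpec(10, 24),
        ConvBlockSpec(10, 11),
        ConvBlockSpec(10, 9),
    )
    dense_head: Tuple[int, ...] = (22, 22, 1)

    def validate(self) -> None:
        if self.input_length < 2:
            raise SpecificationError("input_length must be >= 2")
        if not self.dense_head or self.dense_head[-1] != 1:
            raise SpecificationError("dense_head must end in a single output unit")
        shape_trace(self)


def _conv_out_len(length: int, kernel: int, stride: int, padding: str) -> int:
    if padding == "same":
        return -(-length // stride)
    return (length - kernel) // stride + 1


def shape_trace(spec: CNNSpec) -> dict:
    """Analytic shape propagation through the spec.

    Returns ``{"lengths": [...], "channels": [...], "flattened": int}`` where
    ``lengths`` alternates post-conv and post-pool lengths. Raises
    :class:`SpecificationError` naming the first block whose kernel or pool
    underflows the remaining length.
    """
    length = spec.input_length
    channels = 1
    lengths: List[int] = []
    chans: List[int] = []
    for i, blk in enumerate(spec.conv_blocks, start=1):
        if blk.padding == "valid" and blk.kernel_size > length:
            raise SpecificationError(
                f"conv block {i}: kernel {blk.kernel_size} exceeds input length {length}"
            )
        length = _conv_out_len(length, blk.kernel_size, blk.stride, blk.padding)
        if length < 1:
            raise SpecificationError(f"conv block {i}: output length underflow")
        lengths.append(length)
        if blk.pool_size > 1:
            if blk.pool_size > length:
                raise SpecificationError(
                    f"conv block {i}: pool {blk.pool_size} exceeds length {length}"
                )
            length = length // blk.pool_size
            lengths.append(length)
        channels = blk.filters
        chans.append(channels)
    return {"lengths": lengths, "channels": chans, "flattened": channels * length}


# ---------------------------------------------------------------------------
# layers


class _Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []


class Conv1D(_Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, padding: str, rng):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.padding = padding

    def forward(self, x, train):
        if self.padding == "same":
            k, s = self.w.shape[2], self.stride
            out_len = -(-x.shape[2] // s)
            total = max((out_len - 1) * s + k - x.shape[2], 0)
            x = np.pad(x, ((0, 0), (0, 0), (total // 2, total - total // 2)))
        self._x = x
        windows = sliding_window_view(x, self.w.shape[2], axis=2)[:, :, :: self.stride]
        self._windows = windows
        return np.einsum("bclk,fck->bfl", windows, self.w, optimize=True) + self.b[None, :, None]

    def backward(self, grad):
        self.dw[...] = np.einsum("bfl,bclk->fck", grad, self._windows, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        k, s, n_out = self.w.shape[2], self.stride, grad.shape[2]
        for j in range(k):
            contrib = np.einsum("bfl,fc->bcl", grad, self.w[:, :, j], optimize=True)
            dx[:, :, j : j + s * n_out : s] += contrib
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm1D(_Layer):
    """Per-channel normalization over the batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._m = x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, m = self._xhat, self._m
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2))
        self.dbeta[...] = grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma[None, :, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        ) / self._std[None, :, None]
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class MaxPool1D(_Layer):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        b, c, length = x.shape
        n = length // self.size
        self._in_shape = x.shape
        xr = x[:, :, : n * self.size].reshape(b, c, n, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        b, c, length = self._in_shape
        n = grad.shape[2]
        dxr = np.zeros((b, c, n, self.size))
        bi, ci, ni = np.ogrid[:b, :c, :n]
        dxr[bi, ci, ni, self._argmax] = grad
        dx = np.zeros(self._in_shape)
        dx[:, :, : n * self.size] = dxr.reshape(b, c, n * self.size)
        return dx


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


# ---------------------------------------------------------------------------
# network


@dataclass
class TrainConfig:
    """Adam / mini-batch settings for the numpy network."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 40
    patience: int = 10  # stop when train loss fails to improve this long
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    """An ordered stack of layers producing a single logit per input."""

    def __init__(self, layers: Sequence[_Layer]):
        self.layers = list(layers)
        self.fitted = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def decision_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, float), train=False).ravel()

    def predict_proba1(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid positive-class probability per input row."""
        z = self.decision_logits(x)
        return 1.0 / (1.0 + np.exp(-z))

    def fit(self, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> List[float]:
        """Mini-batch Adam on binary cross-entropy. Returns the per-epoch
        mean loss history; raises :class:`DivergenceError` on NaN loss."""
        cfg.validate()
        x = np.asarray(x, float)
        y = np.asarray(y, float).ravel()
        if x.shape[0] != y.shape[0]:
            raise ValueError(f"{x.shape[0]} inputs vs {y.shape[0]} labels")
        rng = np.random.default_rng(cfg.seed)
        opt = _Adam(self.params(), cfg.learning_rate)
        history: List[float] = []
        best, since_best = np.inf, 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(x.shape[0])
            losses = []
            for start in range(0, x.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                z = self.forward(xb, train=True).ravel()
                # BCE on logits: log(1+e^z) - y*z, stable form
                loss = float(np.mean(np.maximum(z, 0) - z * yb + np.log1p(np.exp(-np.abs(z)))))
                if np.isnan(loss):
                    raise DivergenceError(
                        "training loss is NaN; lower the learning rate"
                    )
                losses.append(loss)
                p = 1.0 / (1.0 + np.exp(-z))
                dz = ((p - yb) / z.size)[:, None]
                self.backward(dz)
                opt.step()
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if epoch_loss < best - 1e-6:
                best, since_best = epoch_loss, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self.fitted = True
        return history


def build_network(spec: CNNSpec, seed: int = 0) -> Sequential:
    """Instantiate the conv -> ReLU -> batch-norm -> max-pool stacks and the
    dense head described by ``spec``. Raises :class:`SpecificationError` if
    any stage underflows the input length."""
    spec.validate()
    rng = np.random.default_rng(seed)
    trace = shape_trace(spec)
    layers: List[_Layer] = []
    in_ch = 1
    for blk in spec.conv_blocks:
        layers.append(Conv1D(in_ch, blk.filters, blk.kernel_size, blk.stride, blk.padding, rng))
        layers.append(ReLU())
        if blk.batch_norm:
            layers.append(BatchNorm1D(blk.filters))
        if blk.pool_size > 1:
            layers.append(MaxPool1D(blk.pool_size))
        in_ch = blk.filters
    layers.append(Flatten())
    width = trace["flattened"]
    for w in spec.dense_head[:-1]:
        layers.append(Dense(width, w, rng))
        layers.append(ReLU())
        width = w
    layers.append(Dense(width, spec.dense_head[-1], rng))
    return Sequential(layers)
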