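"""Minimal numpy layer stack for the lightweight gaze-decoding networks.

Implements exactly the operations the two architectures need — bias-free 1-D
convolutions with length-preserving padding, affine batch normalization,
ReLU, stride-1 same-length max pooling, global average pooling, dense layers,
inverted dropout — together with Adam and a cosine learning-rate decay.
Forward/backward passes are hand-derived and verified against finite
differences in the test suite.

All arrays use ``(batch, channels, time)`` layout for temporal layers and
``(batch, features)`` for dense layers.
"""
from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1dSame",
    "GlobalAvgPool",
    "Linear",
    "Dropout",
    "Sequential",
    "InceptionBlock",
    "InceptionTimeTinyNet",
    "MLPNet",
    "Adam",
    "softmax_cross_entropy",
    "mse_loss",
    "euclidean_loss",
    "cosine_lr",
]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d(Layer):
    """Bias-free 1-D convolution (cross-correlation) with 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dtype=np.float32):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pl = (kernel - 1) // 2
        self.pr = kernel - 1 - self.pl
        self.W = Parameter(_kaiming(rng, (out_ch, in_ch, kernel), in_ch * kernel, dtype))

    def parameters(self):
        return [self.W]

    def forward(self, x, train=False):
        n, c, t = x.shape
        if self.k > 1:
            x = np.pad(x, ((0, 0), (0, 0), (self.pl, self.pr)))
        cols = sliding_window_view(x, self.k, axis=2)  # (n, c, t, k)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * t, c * self.k)
        self._cols2, self._shape = cols2, (n, c, t)
        out = cols2 @ self.W.value.reshape(self.out_ch, -1).T
        return np.ascontiguousarray(out.reshape(n, t, self.out_ch).transpose(0, 2, 1))

    def backward(self, grad):
        n, c, t = self._shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * t, self.out_ch)
        self.W.grad += (g2.T @ self._cols2).reshape(self.W.value.shape)
        gcols = (g2 @ self.W.value.reshape(self.out_ch, -1)).reshape(n, t, c, self.k)
        gcols = gcols.transpose(0, 2, 1, 3)  # (n, c, t, k)
        if self.k == 1:
            return np.ascontiguousarray(gcols[..., 0])
        gxp = np.zeros((n, c, t + self.k - 1), dtype=grad.dtype)
        for j in range(self.k):
            gxp[:, :, j : j + t] += gcols[:, :, :, j]
        return gxp[:, :, self.pl : self.pl + t]


class BatchNorm1d(Layer):
    """Affine batch normalization over (batch, time) per channel."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2]
        self._train = train
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma.value[None, :, None]
        if not self._train:
            return gxhat * inv[None, :, None]
        # train-mode: mean and variance depend on the batch
        s1 = gxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[None, :, None] / m) * (m * gxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1dSame(Layer):
    """Stride-1 max pool with length-preserving padding (-inf edges)."""

    def __init__(self, kernel: int = 3):
        self.k = kernel
        self.pl = (kernel - 1) // 2
        self.pr = kernel - 1 - self.pl

    def forward(self, x, train=False):
        n, c, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pl, self.pr)), constant_values=-np.inf)
        win = sliding_window_view(xp, self.k, axis=2)  # (n, c, t, k)
        self._idx = win.argmax(axis=3)
        self._shape = (n, c, t)
        return np.take_along_axis(win, self._idx[..., None], axis=3)[..., 0]

    def backward(self, grad):
        n, c, t = self._shape
        gwin = np.zeros((n, c, t, self.k), dtype=grad.dtype)
        np.put_along_axis(gwin, self._idx[..., None], grad[..., None], axis=3)
        gxp = np.zeros((n, c, t + self.k - 1), dtype=grad.dtype)
        for j in range(self.k):
            gxp[:, :, j : j + t] += gwin[:, :, :, j]
        return gxp[:, :, self.pl : self.pl + t]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._t, axis=2) / self._t


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng, dtype=np.float32):
        self.W = Parameter(_kaiming(rng, (out_f, in_f), in_f, dtype))
        self.b = Parameter(np.zeros(out_f, dtype=dtype))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Dropout(Layer):
    """Inverted dropout; identity at inference. Draws from a shared rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class InceptionBlock(Layer):
    """One multiscale block: bottleneck -> three parallel convolutions, plus a
    max-pool branch -> 1x1 convolution; concatenation, batch norm, ReLU.

    No residual shortcut: at depth 2 the canonical shortcut (every third
    block) is never reached.
    """

    def __init__(self, in_ch: int, n_filters: int, kernel_sizes, rng, dtype=np.float32):
        self.bottleneck = Conv1d(in_ch, n_filters, 1, rng, dtype)
        self.convs = [Conv1d(n_filters, n_filters, k, rng, dtype) for k in kernel_sizes]
        self.pool = MaxPool1dSame(3)
        self.pool_conv = Conv1d(in_ch, n_filters, 1, rng, dtype)
        self.out_ch = n_filters * (len(kernel_sizes) + 1)
        self.bn = BatchNorm1d(self.out_ch, dtype=dtype)
        self.relu = ReLU()
        self._nf = n_filters

    def parameters(self):
        ps = self.bottleneck.parameters() + [p for c in self.convs for p in c.parameters()]
        return ps + self.pool_conv.parameters() + self.bn.parameters()

    def forward(self, x, train=False):
        b = self.bottleneck.forward(x, train)
        branches = [c.forward(b, train) for c in self.convs]
        branches.append(self.pool_conv.forward(self.pool.forward(x, train), train))
        out = np.concatenate(branches, axis=1)
        return self.relu.forward(self.bn.forward(out, train), train)

    def backward(self, grad):
        grad = self.bn.backward(self.relu.backward(grad))
        nf = self._nf
        gb = None
        for i, c in enumerate(self.convs):
            g = c.backward(grad[:, i * nf : (i + 1) * nf, :])
            gb = g if gb is None else gb + g
        gx = self.bottleneck.backward(gb)
        gp = self.pool_conv.backward(grad[:, len(self.convs) * nf :, :])
        return gx + self.pool.backward(gp)


class InceptionTimeTinyNet(Layer):
    """Two-depth InceptionTime variant: blocks -> global average pooling ->
    affine head. Convolutions are bias-free; normalization is affine."""

    def __init__(
        self,
        in_channels: int = 10,
        n_filters: int = 32,
        kernel_sizes=(17, 7, 3),
        depth: int = 2,
        n_classes: int = 4,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.blocks = []
        ch = in_channels
        for _ in range(depth):
            block = InceptionBlock(ch, n_filters, kernel_sizes, rng, dtype)
            self.blocks.append(block)
            ch = block.out_ch
        self.gap = GlobalAvgPool()
        self.head = Linear(ch, n_classes, rng, dtype)

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()] + self.head.parameters()

    def forward(self, x, train=False):
        for b in self.blocks:
            x = b.forward(x, train)
        return self.head.forward(self.gap.forward(x, train), train)

    def backward(self, grad):
        grad = self.gap.backward(self.head.backward(grad))
        for b in reversed(self.blocks):
            grad = b.backward(grad)
        return grad


class MLPNet(Sequential):
    """Dense ladder with ReLU activations and dropout after each hidden layer."""

    def __init__(
        self,
        in_features: int = 10,
        hidden=(256, 128, 64),
        out_features: int = 1,
        dropout: float = 0.2,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        layers: list[Layer] = []
        prev = in_features
        for h in hidden:
            layers += [Linear(prev, h, rng, dtype), ReLU(), Dropout(dropout, rng)]
            prev = h
        layers.append(Linear(prev, out_features, rng, dtype))
        super().__init__(layers)


# ---------------------------------------------------------------------------
# losses and optimization
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy from raw logits; returns (loss, dloss/dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).astype(pred.dtype)


def euclidean_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-8):
    """Mean Euclidean distance between predicted and target points (n, d)."""
    diff = pred - target
    dist = np.sqrt((diff**2).sum(axis=1) + eps)
    grad = diff / dist[:, None] / pred.shape[0]
    return float(dist.mean()), grad.astype(pred.dtype)


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.value.dtype)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from base_lr toward ~0 over the training run."""
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / max(1, total_epochs)))


def all_layers(layer: Layer):
    """Depth-first iteration over a composite layer tree."""
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from all_layers(sub)
    elif isinstance(layer, InceptionBlock):
        for sub in [layer.bottleneck, *layer.convs, layer.pool, layer.pool_conv,
                    layer.bn, layer.relu]:
            yield from all_layers(sub)
    elif isinstance(layer, InceptionTimeTinyNet):
        for sub in [*layer.blocks, layer.gap, layer.head]:
            yield from all_layers(sub)


def net_state(net: Layer) -> dict[str, np.ndarray]:
    """Flat dict of all parameters and batch-norm running statistics."""
    state: dict[str, np.ndarray] = {}
    for i, p in enumerate(net.parameters()):
        state[f"param_{i}"] = p.value.copy()
    bn_layers = [l for l in all_layers(net) if isinstance(l, BatchNorm1d)]
    for i, bn in enumerate(bn_layers):
        state[f"bn_{i}_mean"] = bn.running_mean.copy()
        state[f"bn_{i}_var"] = bn.running_var.copy()
    return state


def load_net_state(net: Layer, state: dict) -> None:
    for i, p in enumerate(net.parameters()):
        w = np.asarray(state[f"param_{i}"])
        if w.shape != p.value.shape:
            raise ValueError("checkpoint does not match network architecture")
        p.value = w.astype(p.value.dtype).copy()
    bn_layers = [l for l in all_layers(net) if isinstance(l, BatchNorm1d)]
    for i, bn in enumerate(bn_layers):
        bn.running_mean = np.asarray(state[f"bn_{i}_mean"]).astype(bn.running_mean.dtype)
        bn.running_var = np.asarray(state[f"bn_{i}_var"]).astype(bn.running_var.dtype)


def count_net_parameters(net: Layer) -> int:
    return int(sum(p.value.size for p in net.parameters()))


def get_weights(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.parameters()]


def set_weights(net: Layer, weights: list[np.ndarray]) -> None:
    params = net.parameters()
    if len(params) != len(weights):
        raise ValueError("weight list does not match network parameters")
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError("weight shape mismatch")
        p.value = w.astype(p.value.dtype).copy()
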