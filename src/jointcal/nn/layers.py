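"""Minimal feed-forward layers with explicit reverse-mode gradients.

The calibration framework only needs small fully connected stacks
(batch normalization, affine maps, leaky rectifiers, a terminal sigmoid),
so the layers here implement exactly those primitives on NumPy arrays.
Every layer exposes a functional ``forward(x, training)`` returning the
output together with a cache, and a ``backward(cache, grad_out)`` that
accumulates parameter gradients into ``self.grads`` and returns the
gradient with respect to the input.  Caches are per-call, so one layer
instance can be run on several minibatches (e.g. source then target)
before the backward passes are taken in any order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Linear", "BatchNorm1d", "LeakyReLU", "Sigmoid", "Sequential"]


class Layer:
    """Base class: parameterized differentiable map on (n, d) arrays."""

    kind: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False):
        raise NotImplementedError

    def backward(self, cache, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def spec(self) -> dict:
        return {"kind": self.kind}


class Linear(Layer):
    """Affine map ``y = x W + b`` with uniform Kaiming fan-in initialization."""

    kind = "affine"

    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        super().__init__()
        if in_width < 1 or out_width < 1:
            raise ValueError("layer widths must be positive")
        self.in_width = int(in_width)
        self.out_width = int(out_width)
        bound = 1.0 / np.sqrt(in_width)
        self.params["W"] = rng.uniform(-bound, bound, size=(in_width, out_width))
        self.params["b"] = rng.uniform(-bound, bound, size=out_width)
        self.zero_grad()

    def forward(self, x, training=False):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, cache, grad_out):
        x = cache
        self.grads["W"] += x.T @ grad_out
        self.grads["b"] += grad_out.sum(axis=0)
        return grad_out @ self.params["W"].T

    def spec(self):
        return {"kind": self.kind, "in_width": self.in_width, "out_width": self.out_width}


class BatchNorm1d(Layer):
    """Per-feature standardization with learnable scale/shift.

    In training mode the statistics of the current minibatch are used and
    exponentially averaged into running buffers; with ``training=False``
    the behaviour depends on ``batch_stats``: the frozen running buffers
    (a fixed affine map, suitable for streaming single samples) or the
    statistics of the array being transformed (the transductive mode used
    when a whole measurement batch is calibrated at once, mirroring how
    batches are standardized during training).  Running buffers are only
    updated on training passes.
    """

    kind = "batch_norm"

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.width = int(width)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.params["gamma"] = np.ones(width)
        self.params["beta"] = np.zeros(width)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.zero_grad()

    def forward(self, x, training=False, batch_stats=False):
        if training or batch_stats:
            mean = x.mean(axis=0)
            var = x.var(axis=0)  # biased, as used for normalization
            if training:
                n = x.shape[0]
                unbiased = var * (n / max(n - 1, 1))
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        y = self.params["gamma"] * x_hat + self.params["beta"]
        return y, (x_hat, inv_std, training)

    def backward(self, cache, grad_out):
        x_hat, inv_std, was_training = cache
        self.grads["gamma"] += (grad_out * x_hat).sum(axis=0)
        self.grads["beta"] += grad_out.sum(axis=0)
        g = self.params["gamma"] * inv_std
        if not was_training:
            return grad_out * g
        # minibatch statistics participate in the gradient
        m = grad_out.shape[0]
        return g * (grad_out - grad_out.mean(axis=0) - x_hat * (grad_out * x_hat).mean(axis=0)) \
            if m > 1 else np.zeros_like(grad_out)

    def spec(self):
        return {"kind": self.kind, "width": self.width,
                "momentum": self.momentum, "eps": self.eps}


class LeakyReLU(Layer):
    kind = "leaky_rectifier"

    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        if not 0.0 < negative_slope < 1.0:
            raise ValueError("negative_slope must lie in (0, 1)")
        self.negative_slope = float(negative_slope)

    def forward(self, x, training=False):
        mask = x >= 0
        return np.where(mask, x, self.negative_slope * x), mask

    def backward(self, cache, grad_out):
        mask = cache
        return np.where(mask, grad_out, self.negative_slope * grad_out)

    def spec(self):
        return {"kind": self.kind, "negative_slope": self.negative_slope}


class Sigmoid(Layer):
    kind = "sigmoid"

    def forward(self, x, training=False):
        # numerically stable two-sided logistic
        y = np.empty_like(x, dtype=float)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        return y, y

    def backward(self, cache, grad_out):
        y = cache
        return grad_out * y * (1.0 - y)


class Sequential:
    """An ordered stack of layers sharing the cache-passing protocol."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False, batch_stats=False):
        caches = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                x, c = layer.forward(x, training=training, batch_stats=batch_stats)
            else:
                x, c = layer.forward(x, training=training)
            caches.append(c)
        return x, caches

    def backward(self, caches, grad_out):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            grad_out = layer.backward(cache, grad_out)
        return grad_out

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        """Yield (layer_index, name, array) triples for every parameter."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    def specs(self) -> list[dict]:
        return [layer.spec() for layer in self.layers]
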