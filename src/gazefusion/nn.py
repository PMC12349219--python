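"""Minimal reverse-mode neural-network layers on numpy arrays.

The package trains small CNNs (a few convolutional blocks, a global average
pool and a linear head) plus the 1x1-convolution attention gate, so the layer
zoo is deliberately tiny: every layer implements ``forward`` (with an internal
cache) and ``backward``, and exposes its parameters and gradients as dicts.
All arrays are float64, shape convention ``(N, C, H, W)``.

Gradient capture for class-activation mapping is built into
:class:`Sequential`: the backward pass can record the upstream gradient
arriving at any named layer's output, which is exactly the quantity
``d y_c / d A`` that Grad-CAM pools.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Shift",
    "Conv2d",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "GlobalAvgPool",
    "Linear",
    "AttentionGate",
    "Sequential",
    "DualBranchNetwork",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all (sample, label) entries.

    Returns ``(loss, dloss/dlogits)``. Computed in the log-sum-exp form so
    saturated logits do not overflow.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    # softplus(-z)*y + softplus(z)*(1-y), with softplus(t) = log1p(exp(-|t|)) + max(t, 0)
    softplus_pos = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)
    softplus_neg = softplus_pos - z  # softplus(-z)
    loss = float(np.mean(y * softplus_neg + (1.0 - y) * softplus_pos))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


class Layer:
    """Base layer: stateless by default, no parameters."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def reseed(self, rng: np.random.Generator) -> None:
        """Hand stochastic layers a fresh generator (no-op for most)."""


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding.

    Weights are ``(out_ch, in_ch, kh, kw)``; initialization is He-normal,
    drawn from the generator supplied to :meth:`init_params` so identical
    seeds give identical networks.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1, pad: int = 1):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = {
            "W": np.zeros((out_ch, in_ch, kernel, kernel)),
            "b": np.zeros(out_ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.kernel * self.kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.params["W"].shape)
        self.params["b"] = np.zeros(self.out_ch)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"Conv2d expects (N, {self.in_ch}, H, W) input, got shape {x.shape}"
            )
        p, s, k = self.pad, self.stride, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        view = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = np.einsum("nchwij,ocij->nohw", view, self.params["W"], optimize=True)
        out += self.params["b"][None, :, None, None]
        self._cache = (x.shape, xp.shape, view)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, view = self._cache
        p, s, k = self.pad, self.stride, self.kernel
        W = self.params["W"]
        self.grads["W"] = np.einsum("nchwij,nohw->ocij", view, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dxp = np.zeros(xp_shape)
        _, _, ho, wo = dout.shape
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + s * ho : s, dj : dj + s * wo : s] += np.einsum(
                    "nohw,oc->nchw", dout, W[:, :, di, dj], optimize=True
                )
        if p:
            return dxp[:, :, p : p + x_shape[2], p : p + x_shape[3]]
        return dxp


class Shift(Layer):
    """Fixed additive offset (input centering); identity gradient."""

    def __init__(self, offset: float):
        super().__init__()
        self.offset = offset

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x + self.offset

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._out = sigmoid(x)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode and at rate 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._rng = np.random.default_rng(0)

    def reseed(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params = {"W": np.zeros((out_dim, in_dim)), "b": np.zeros(out_dim)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_params(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self.in_dim)
        self.params["W"] = rng.uniform(-bound, bound, (self.out_dim, self.in_dim))
        self.params["b"] = np.zeros(self.out_dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"Linear expects feature dimension {self.in_dim}, got shape {x.shape}"
            )
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class AttentionGate(Layer):
    """Spatial attention gate: conv1x1 -> ReLU -> conv1x1 -> sigmoid -> multiply.

    The second convolution produces a single score map by default, broadcast
    multiplicatively over all input channels; ``per_channel=True`` gives one
    score map per input channel instead. Optional dropout is applied to the
    scores in train mode only, so in eval mode the gate output is exactly
    ``input * sigmoid(scores)`` with scores in [0, 1].
    """

    def __init__(self, in_ch: int, hidden_ch: int = 8, per_channel: bool = False,
                 dropout: float = 0.1):
        super().__init__()
        self.in_ch = in_ch
        self.per_channel = per_channel
        out_ch = in_ch if per_channel else 1
        self.conv1 = Conv2d(in_ch, hidden_ch, kernel=1, stride=1, pad=0)
        self.conv2 = Conv2d(hidden_ch, out_ch, kernel=1, stride=1, pad=0)
        self.relu = ReLU()
        self.drop = Dropout(dropout)

    @property
    def params(self):  # type: ignore[override]
        return {
            "W1": self.conv1.params["W"], "b1": self.conv1.params["b"],
            "W2": self.conv2.params["W"], "b2": self.conv2.params["b"],
        }

    @params.setter
    def params(self, value):  # Layer.__init__ assigns {}; ignore it
        pass

    @property
    def grads(self):  # type: ignore[override]
        return {
            "W1": self.conv1.grads["W"], "b1": self.conv1.grads["b"],
            "W2": self.conv2.grads["W"], "b2": self.conv2.grads["b"],
        }

    @grads.setter
    def grads(self, value):
        pass

    def init_params(self, rng: np.random.Generator) -> None:
        self.conv1.init_params(rng)
        self.conv2.init_params(rng)

    def reseed(self, rng: np.random.Generator) -> None:
        self.drop.reseed(rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.relu.forward(self.conv1.forward(x, train), train)
        scores = self.conv2.forward(h, train)
        a = sigmoid(scores)
        a_used = self.drop.forward(a, train)
        self._x, self._a, self._a_used = x, a, a_used
        return x * a_used

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a, a_used = self._x, self._a, self._a_used
        dx_direct = dout * a_used
        da_used = dout * x
        if not self.per_channel:
            da_used = da_used.sum(axis=1, keepdims=True)
        da = self.drop.backward(da_used)
        dscores = da * a * (1.0 - a)
        dh = self.relu.backward(self.conv2.backward(dscores))
        dx_gate = self.conv1.backward(dh)
        return dx_direct + dx_gate

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode sigmoid score map for an input batch (no dropout)."""
        h = np.maximum(self.conv1.forward(x), 0.0)
        return sigmoid(self.conv2.forward(h))


class Sequential:
    """Ordered named layers with gradient capture for saliency mapping."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self.layers = layers

    def __getitem__(self, name: str) -> Layer:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(f"no layer named {name!r}; have {[n for n, _ in self.layers]}")

    @property
    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def init_params(self, rng: np.random.Generator) -> None:
        for _, layer in self.layers:
            if hasattr(layer, "init_params"):
                layer.init_params(rng)
            layer.reseed(np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.activations = {}
        for name, layer in self.layers:
            x = layer.forward(x, train)
            self.activations[name] = x
        return x

    def backward(self, dout: np.ndarray, capture: str | None = None):
        """Backpropagate; optionally record d(output-loss)/d(activation of `capture`).

        Returns ``(dinput, captured_gradient_or_None)``.
        """
        if capture is not None and capture not in self.layer_names:
            raise KeyError(f"no layer named {capture!r}")
        captured = None
        for name, layer in reversed(self.layers):
            if name == capture:
                captured = dout.copy()
            dout = layer.backward(dout)
        return dout, captured

    def iter_params(self):
        for name, layer in self.layers:
            for key in layer.params:
                yield f"{name}.{key}", layer.params[key], layer.grads[key]

    def set_param(self, qualified: str, value: np.ndarray) -> None:
        name, key = qualified.split(".")
        layer = self[name]
        if layer.params[key].shape != value.shape:
            raise ValueError(f"shape mismatch for {qualified}")
        if isinstance(layer, AttentionGate):
            target = {"W1": layer.conv1, "b1": layer.conv1,
                      "W2": layer.conv2, "b2": layer.conv2}[key]
            target.params[key[0]] = np.asarray(value, dtype=np.float64)
        else:
            layer.params[key] = np.asarray(value, dtype=np.float64)

    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.iter_params())


class DualBranchNetwork:
    """Two parallel backbones (image branch, heatmap branch) with feature
    concatenation before a shared linear head — the no-parameter-sharing
    baseline. No attention gate."""

    def __init__(self, image_branch: Sequential, gaze_branch: Sequential,
                 head: Linear, image_channels: int = 1):
        self.image_branch = image_branch
        self.gaze_branch = gaze_branch
        self.head = head
        self.image_channels = image_channels

    @property
    def layer_names(self) -> list[str]:
        return (["image." + n for n in self.image_branch.layer_names]
                + ["gaze." + n for n in self.gaze_branch.layer_names] + ["head"])

    def init_params(self, rng: np.random.Generator) -> None:
        self.image_branch.init_params(rng)
        self.gaze_branch.init_params(rng)
        self.head.init_params(rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c = self.image_channels
        fi = self.image_branch.forward(x[:, :c], train)
        fg = self.gaze_branch.forward(x[:, c:], train)
        self._split = fi.shape[1]
        return self.head.forward(np.concatenate([fi, fg], axis=1), train)

    def backward(self, dout: np.ndarray, capture: str | None = None):
        if capture is not None:
            raise ValueError("gradient capture is not supported on the dual-branch baseline")
        dfeat = self.head.backward(dout)
        di, _ = self.image_branch.backward(dfeat[:, : self._split])
        dg, _ = self.gaze_branch.backward(dfeat[:, self._split:])
        return np.concatenate([di, dg], axis=1), None

    def iter_params(self):
        for prefix, seq in (("image", self.image_branch), ("gaze", self.gaze_branch)):
            for name, p, g in seq.iter_params():
                yield f"{prefix}.{name}", p, g
        for key in self.head.params:
            yield f"head.{key}", self.head.params[key], self.head.grads[key]

    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.iter_params())


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, network) -> None:
        self._t += 1
        b1, b2 = self.betas
        for key, p, g in network.iter_params():
            if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                g = g + self.weight_decay * p
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
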