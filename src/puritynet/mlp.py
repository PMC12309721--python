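"""Minimal feed-forward regression network in numpy.

Implements exactly what the purity model needs: fully connected layers with
ReLU hidden activations and a linear scalar output, inverted dropout on the
input layer (training mode only), L1 loss with its subgradient, and the Adam
optimizer with L2 weight decay folded into the gradient (the semantics of
``torch.optim.Adam(weight_decay=...)``).

Weight initialization follows the fan-in uniform scheme used by standard
linear layers: ``W, b ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Linear:
    W: np.ndarray  # (fan_in, fan_out)
    b: np.ndarray  # (fan_out,)


def init_layers(sizes: list[int], rng: np.random.Generator) -> list[Linear]:
    """Fan-in uniform initialization for a chain of linear layers.

    ``sizes`` lists the widths including input and output, e.g. ``[d, 32, 16, 1]``.
    """
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        layers.append(Linear(W, b))
    return layers


def forward(
    layers: list[Linear],
    X: np.ndarray,
    input_dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass; returns (predictions of shape (n,), cache for backward).

    Inverted dropout: in training mode each input unit is zeroed with
    probability ``input_dropout`` and survivors are scaled by
    ``1/(1 - input_dropout)``; in eval mode inputs pass through unchanged, so
    evaluation is deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    if training and input_dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(X.shape) >= input_dropout) / (1.0 - input_dropout)
        X = X * mask
    cache: dict = {"inputs": [X]}
    h = X
    for i, layer in enumerate(layers):
        z = h @ layer.W + layer.b
        h = np.maximum(z, 0.0) if i < len(layers) - 1 else z  # ReLU on hidden only
        cache["inputs"].append(h)
    return h[:, 0], cache


def l1_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error, ``(1/n) sum |y_i - yhat_i|``."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError(f"length mismatch or empty: {y.shape} vs {yhat.shape}")
    return float(np.mean(np.abs(y - yhat)))


def backward_l1(
    layers: list[Linear], cache: dict, y: np.ndarray
) -> list[Linear]:
    """Gradients of the L1 loss w.r.t. every weight and bias.

    Uses the subgradient ``sign(yhat - y)/n`` at the output; the sign
    convention at exact ties (0) is the numpy ``sign`` of zero.
    """
    inputs = cache["inputs"]
    n = y.shape[0]
    yhat = inputs[-1][:, 0]
    delta = (np.sign(yhat - y) / n)[:, None]  # (n, 1)
    grads: list[Linear] = [None] * len(layers)  # type: ignore[list-item]
    for i in range(len(layers) - 1, -1, -1):
        h_in = inputs[i]
        grads[i] = Linear(h_in.T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ layers[i].W.T) * (inputs[i] > 0)
    return grads


@dataclass
class Adam:
    """Adam with L2 weight decay added to the raw gradient (coupled decay)."""

    lr: float = 3e-5
    weight_decay: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    _m: list[Linear] = field(default_factory=list)
    _v: list[Linear] = field(default_factory=list)

    def step(self, layers: list[Linear], grads: list[Linear]) -> None:
        if not self._m:
            self._m = [Linear(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
            self._v = [Linear(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for layer, grad, m, v in zip(layers, grads, self._m, self._v):
            for attr in ("W", "b"):
                p = getattr(layer, attr)
                g = getattr(grad, attr) + self.weight_decay * p
                mm = getattr(m, attr)
                vv = getattr(v, attr)
                mm *= self.beta1
                mm += (1 - self.beta1) * g
                vv *= self.beta2
                vv += (1 - self.beta2) * g * g
                p -= self.lr * (mm / bc1) / (np.sqrt(vv / bc2) + self.eps)


def parameter_count(sizes: list[int]) -> int:
    """Total number of weights and biases for the given layer widths."""
    return sum(fi * fo + fo for fi, fo in zip(sizes[:-1], sizes[1:]))


def copy_layers(layers: list[Linear]) -> list[Linear]:
    return [Linear(l.W.copy(), l.b.copy()) for l in layers]
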