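"""Small convolutional building blocks and the Adam optimizer.

All learnable parameters are :class:`~relaxmore.autodiff.Tensor` objects with
``requires_grad=True``; the networks here are plain parameter containers whose
``__call__`` builds the forward graph.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = ["ConvNet", "Adam", "xavier_uniform"]


def xavier_uniform(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Glorot/Xavier uniform initialization for a conv kernel
    [Cout, Cin, kh, kw]: U(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    cout, cin, kh, kw = shape
    fan_in, fan_out = cin * kh * kw, cout * kh * kw
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


class ConvNet:
    """A stack of 3x3 same-padded convolutions with ReLU between layers.

    ``widths`` lists the channel progression, e.g. [2, 32, 32, 32, 32, 2]
    builds 4 hidden Conv(3x3, 32) + ReLU layers followed by a linear
    Conv(3x3) head — the layer pattern used by the coil-combination and
    initialization networks.  No activation after the last layer.
    """

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        zero_init: bool = False,
        zero_last: bool = False,
    ):
        """``zero_init`` zeroes every layer; ``zero_last`` zeroes only the
        output layer so a residual branch starts as the identity."""
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = list(int(w) for w in widths)
        self.weights: list[ad.Tensor] = []
        self.biases: list[ad.Tensor] = []
        n = len(self.widths) - 1
        for i, (cin, cout) in enumerate(zip(self.widths[:-1], self.widths[1:])):
            if zero_init or (zero_last and i == n - 1):
                w = np.zeros((cout, cin, 3, 3))
            else:
                w = xavier_uniform(rng, (cout, cin, 3, 3))
            self.weights.append(ad.Tensor(w, requires_grad=True))
            self.biases.append(ad.Tensor(np.zeros(cout), requires_grad=True))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self) -> list[ad.Tensor]:
        return [t for pair in zip(self.weights, self.biases) for t in pair]

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        """Forward pass on a [B, Cin, H, W] tensor."""
        h = x
        last = self.n_layers - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.conv2d(h, w, b)
            if i != last:
                h = ad.relu(h)
        return h

    def reversed_widths(self) -> list[int]:
        """Channel progression of the mirror-image (adjoint-shaped) network."""
        return list(reversed(self.widths))

    # --- state (de)serialization -------------------------------------------------
    def state(self) -> dict:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w.data
            out[f"b{i}"] = b.data
        return out

    def load_state(self, state: dict) -> None:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if state[f"w{i}"].shape != w.data.shape:
                raise ValueError(
                    f"layer {i}: checkpoint weight {state[f'w{i}'].shape} "
                    f"!= model {w.data.shape}"
                )
            w.data = np.array(state[f"w{i}"], dtype=np.float64)
            b.data = np.array(state[f"b{i}"], dtype=np.float64)


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[ad.Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(np.abs(p.data)) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * np.abs(g) ** 2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
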