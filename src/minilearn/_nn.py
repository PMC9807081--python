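"""Minimal 1-D convolutional network machinery with manual backpropagation.

The scorer networks in this package are small stacks of one kernel-k
convolution followed by 1x1 convolutions, so a full deep-learning framework is
unnecessary: forward passes reduce to a handful of matrix products and the
gradients are written out by hand. Everything here operates on float32
(C, L)-shaped channel-major activations and is exact (no stochastic layers),
so runs are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "relu", "ConvStack", "Adam", "sigmoid", "sigmoid_grad"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_grad(y: np.ndarray) -> np.ndarray:
    """d sigmoid / dx expressed in terms of the output y."""
    return y * (1.0 - y)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv1d:
    """Valid-mode 1-D convolution: (C_in, L) -> (C_out, L - kernel + 1).

    Implemented as a sum of shifted matrix products, which is optimal for the
    tiny kernels used here (k <= ~20, then 1x1).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.kernel = kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * kernel))
        self.weight = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        l_out = x.shape[1] - self.kernel + 1
        if l_out < 1:
            raise ValueError(f"input length {x.shape[1]} shorter than kernel {self.kernel}")
        out = np.empty((self.weight.shape[0], l_out), dtype=np.float32)
        out[:] = self.bias[:, None]
        for j in range(self.kernel):
            out += self.weight[:, :, j] @ x[:, j : j + l_out]
        return out

    def backward(self, x: np.ndarray, dout: np.ndarray,
                 need_dx: bool = True) -> tuple[list[np.ndarray], np.ndarray | None]:
        l_out = dout.shape[1]
        dw = np.empty_like(self.weight)
        for j in range(self.kernel):
            dw[:, :, j] = dout @ x[:, j : j + l_out].T
        db = dout.sum(axis=1).astype(np.float32)
        dx = None
        if need_dx:
            dx = np.zeros_like(x)
            for j in range(self.kernel):
                dx[:, j : j + l_out] += self.weight[:, :, j].T @ dout
        return [dw, db], dx


class ConvStack:
    """Conv -> ReLU -> ... -> Conv -> head activation, channel-major.

    ``head`` is "sigmoid" (scores in (0,1)) or "tanh" (noise in (-1,1)).
    """

    def __init__(self, c_in: int, channels: tuple[int, ...], kernels: tuple[int, ...],
                 rng: np.random.Generator, head: str = "sigmoid",
                 zero_init_last: bool = False, head_scale: float = 1.0):
        if len(kernels) != len(channels) + 1:
            raise ValueError("need one kernel per layer (hidden layers + head)")
        self.head = head
        dims = (c_in,) + tuple(channels) + (1,)
        self.layers = [
            Conv1d(dims[i], dims[i + 1], kernels[i], rng,
                   zero_init=zero_init_last and i == len(kernels) - 1)
            for i in range(len(kernels))
        ]
        if head_scale != 1.0:
            self.layers[-1].weight *= head_scale

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, flat: list[np.ndarray]) -> None:
        it = iter(flat)
        for layer in self.layers:
            layer.weight = next(it).astype(np.float32)
            layer.bias = next(it).astype(np.float32)

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Return scores of shape (L_out,); optionally the activation cache."""
        cache = [x]
        h = x
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i < len(self.layers) - 1:
                h = relu(h)
            cache.append(h)
        y = sigmoid(h[0]) if self.head == "sigmoid" else np.tanh(h[0])
        if keep_cache:
            return y, cache
        return y

    def backward(self, cache: list[np.ndarray], y: np.ndarray,
                 dy: np.ndarray) -> list[np.ndarray]:
        """Gradients of sum(dy * y) w.r.t. params, in ``params`` order."""
        if self.head == "sigmoid":
            dh = (dy * y * (1.0 - y)).astype(np.float32)[None, :]
        else:
            dh = (dy * (1.0 - y * y)).astype(np.float32)[None, :]
        grads: list[list[np.ndarray]] = []
        for i in range(len(self.layers) - 1, -1, -1):
            x_in = cache[i]
            if i > 0:
                # cache[i] holds post-ReLU activations for hidden layers
                g, dx = self.layers[i].backward(x_in, dh, need_dx=True)
                dh = dx * (x_in > 0)
            else:
                g, _ = self.layers[i].backward(x_in, dh, need_dx=False)
            grads.append(g)
        out: list[np.ndarray] = []
        for g in reversed(grads):
            out.extend(g)
        return out


class Adam:
    """Plain Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
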