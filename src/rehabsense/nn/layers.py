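"""Layer modules built on the autograd core: Dense, Conv1d, LSTM stacks."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d, max_pool1d

__all__ = ["Module", "Dense", "Conv1d", "LSTM", "max_pool1d", "concat"]


class Module:
    """Base class: parameter collection and recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, module has {len(params)} parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data[...] = arr


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = Tensor(rng.normal(0.0, scale, (c_out, c_in, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b)


class LSTMCellLayer(Module):
    """One LSTM layer unrolled over time with a single gate matmul per step."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        s = np.sqrt(1.0 / n_hidden)
        self.Wx = Tensor(rng.uniform(-s, s, (n_in, 4 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.uniform(-s, s, (n_hidden, 4 * n_hidden)), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        B = xs[0].data.shape[0]
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        hs: list[Tensor] = []
        for x in xs:
            gates = x @ self.Wx + h @ self.Wh + self.b
            i = gates.narrow(1, 0, H).sigmoid()
            f = gates.narrow(1, H, H).sigmoid()
            g = gates.narrow(1, 2 * H, H).tanh()
            o = gates.narrow(1, 3 * H, H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return hs


class LSTM(Module):
    """Stack of LSTM layers; returns the last time-step hidden state."""

    def __init__(self, n_in: int, dims: tuple[int, ...], rng: np.random.Generator):
        layers = []
        prev = n_in
        for d in dims:
            layers.append(LSTMCellLayer(prev, d, rng))
            prev = d
        self.layers = layers

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, C) -> (B, dims[-1]) last hidden state of the top layer."""
        B, T, C = x.data.shape
        xs = [x.narrow(1, t, 1).reshape(B, C) for t in range(T)]
        for layer in self.layers:
            xs = layer(xs)
        return xs[-1]
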