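"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the network family needs: broadcasted
arithmetic, matmul, reshape/concat/narrow, elementwise nonlinearities,
1-D convolution (same padding), max pooling, reductions, and fused
softmax cross-entropy.  Everything is float64 so training is
bit-reproducible on CPU given a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "max_pool1d", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from BPTT exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = _bw
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis (differentiable)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        out._backward = _bw
        return out

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        out._backward = _bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * s)

        out._backward = _bw
        return out

    def arccos(self):
        """arccos with inputs clipped away from ±1 for a finite gradient."""
        x = np.clip(self.data, -1.0 + 1e-9, 1.0 - 1e-9)
        out = Tensor(np.arccos(x), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (-1.0 / np.sqrt(1.0 - x * x)))

        out._backward = _bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, start + s)
                t._accum(g[tuple(idx)])
            start += s

    out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 1-D convolution.

    x: (B, C, L); w: (O, C, K) with K odd; b: (O,).  Output (B, O, L).
    """
    B, C, L = x.data.shape
    O, C2, K = w.data.shape
    assert C == C2 and K % 2 == 1
    p = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,L,K)
    y = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
    y += b.data[None, :, None]
    out = Tensor(y, _prev=(x, w, b))

    def _bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bol,bclk->ock", g, cols, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("bol,ock->bclk", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k:k + L] += dcols[:, :, :, k]
            x._accum(dxp[:, :, p:p + L])

    out._backward = _bw
    return out


def max_pool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (trailing remainder
    dropped)."""
    B, C, L = x.data.shape
    Lp = (L // size) * size
    xv = x.data[:, :, :Lp].reshape(B, C, Lp // size, size)
    am = xv.argmax(axis=3)
    y = np.take_along_axis(xv, am[..., None], axis=3)[..., 0]
    out = Tensor(y, _prev=(x,))

    def _bw(g):
        if not x.requires_grad:
            return
        dxv = np.zeros((B, C, Lp // size, size))
        np.put_along_axis(dxv, am[..., None], g[..., None], axis=3)
        dx = np.zeros_like(x.data)
        dx[:, :, :Lp] = dxv.reshape(B, C, Lp)
        x._accum(dx)

    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of softmax(logits) at integer labels y.

    Returns (loss Tensor, probabilities ndarray).  Fused for numerical
    stability; probabilities are clamped implicitly by the log-sum-exp form.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    logp = (z - zmax) - np.log(ez.sum(axis=1, keepdims=True))
    loss_val = -logp[np.arange(n), y].mean()
    out = Tensor(loss_val, _prev=(logits,))

    def _bw(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), y] -= 1.0
            logits._accum(g * d / n)

    out._backward = _bw
    return out, probs
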