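"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model families in this package need only a small, fixed set of
differentiable operations (affine maps, 1-D convolutions, recurrent
cells, attention, the usual pointwise nonlinearities and reductions), so
they are built on this self-contained engine rather than an external deep
learning framework: float64 throughout, fully deterministic, and with no
dependencies beyond numpy.

A :class:`Tensor` wraps an ``ndarray`` plus a closure that accumulates
gradients into its parents; :meth:`Tensor.backward` runs the reverse
topological sweep.  Only tensors with ``requires_grad`` (parameters, or
anything derived from them) participate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "softplus"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._bw = _bw

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Reverse sweep from this (typically scalar loss) tensor."""
        topo: list = []
        seen = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._bw = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._bw = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._bw = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data)
                else:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._bw = bw
        return out

    # -- pointwise nonlinearities -------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._bw = lambda g: self._accum(g * val) if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._bw = lambda g: self._accum(g / self.data) if self.requires_grad else None
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))
        out._bw = lambda g: self._accum(g * (1 - val**2)) if self.requires_grad else None
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(val, _parents=(self,))
        out._bw = (
            lambda g: self._accum(g * val * (1 - val)) if self.requires_grad else None
        )
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._bw = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._bw = (
            lambda g: self._accum(g.reshape(orig)) if self.requires_grad else None
        )
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._bw = (
            lambda g: self._accum(np.swapaxes(g, a, b)) if self.requires_grad else None
        )
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), _parents=(self,))
        out._bw = (
            lambda g: self._accum(np.flip(g, axis=axis)) if self.requires_grad else None
        )
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._bw = bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max over one axis; gradients flow to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = Tensor(np.squeeze(val, axis=axis), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            self._accum(full)

        out._bw = bw
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._bw = bw
    return out


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(x))."""
    val = np.logaddexp(0.0, x.data)
    out = Tensor(val, _parents=(x,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out._bw = lambda g: x._accum(g * sig) if x.requires_grad else None
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution over (batch, positions, channels).

    ``weight`` has shape (kernel, in_channels, filters) with odd kernel so
    the positional length is preserved.
    """
    B, L, C = x.data.shape
    k, Cw, F = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cw}")
    if k % 2 != 1:
        raise ValueError("conv1d kernel size must be odd")
    pad = k // 2
    xp = np.zeros((B, L + 2 * pad, C))
    xp[:, pad : pad + L, :] = x.data
    # windows: (B, L, k, C)
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k,), axis=1)
    windows = np.swapaxes(windows, 2, 3)  # (B, L, k, C)
    val = np.einsum("blkc,kcf->blf", windows, weight.data) + bias.data
    out = Tensor(val, _parents=(x, weight, bias))

    def bw(g):
        if weight.requires_grad:
            weight._accum(np.einsum("blkc,blf->kcf", windows, g))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dwin = np.einsum("blf,kcf->blkc", g, weight.data)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, j : j + L, :] += dwin[:, :, j, :]
            x._accum(dxp[:, pad : pad + L, :])

    out._bw = bw
    return out
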