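"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps a
float64 ndarray and remembers the operation that produced it as a
vector-Jacobian-product closure.  It supports exactly the operations the
emotion-recognition networks need (broadcast arithmetic, matmul,
elementwise nonlinearities, reductions, shape surgery, 1-D convolution)
and is validated against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "conv1d",
    "softmax",
    "logsumexp",
    "sigmoid",
    "tanh",
    "exp",
    "log",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        vjp: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._vjp = vjp if self.requires_grad else None

    # ---- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- autodiff ------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar tensor, accumulating into ``.grad``."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data + o.data,
            parents=(self, o),
            vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), vjp=lambda g: (-g,))

    def __sub__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data - o.data,
            parents=(self, o),
            vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)),
        )

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data * o.data,
            parents=(self, o),
            vjp=lambda g: (
                _unbroadcast(g * o.data, self.shape),
                _unbroadcast(g * self.data, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data / o.data,
            parents=(self, o),
            vjp=lambda g: (
                _unbroadcast(g / o.data, self.shape),
                _unbroadcast(-g * self.data / o.data**2, o.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        p = float(p)
        return Tensor(
            self.data**p,
            parents=(self,),
            vjp=lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        o = as_tensor(other)
        out = np.matmul(self.data, o.data)

        def vjp(g):
            ga = np.matmul(g, np.swapaxes(o.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, o.shape)

        return Tensor(out, parents=(self, o), vjp=vjp)

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(out, parents=(self,), vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int | None = None, keepdims: bool = False):
        if axis is None:
            idx = np.unravel_index(np.argmax(self.data), self.shape)
            out = self.data[idx]

            def vjp(g):
                gx = np.zeros_like(self.data)
                gx[idx] = g
                return (gx,)

            return Tensor(out, parents=(self,), vjp=vjp)
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out = np.squeeze(out, axis=axis)

        def vjp(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), gg, axis=axis)
            return (gx,)

        return Tensor(out, parents=(self,), vjp=vjp)

    # ---- shape surgery -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            vjp=lambda g: (g.reshape(self.shape),),
        )

    def swapaxes(self, a: int, b: int):
        return Tensor(
            np.swapaxes(self.data, a, b),
            parents=(self,),
            vjp=lambda g: (np.swapaxes(g, a, b),),
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(
            np.transpose(self.data, axes),
            parents=(self,),
            vjp=lambda g: (np.transpose(g, inv),),
        )

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = self.data[idx]

        def vjp(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor(out, parents=(self,), vjp=vjp)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- elementwise nonlinearities ---------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor(out, parents=(x,), vjp=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.data), parents=(x,), vjp=lambda g: (g / x.data,))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    return Tensor(out, parents=(x,), vjp=lambda g: (g * (1.0 - out**2),))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out, parents=(x,), vjp=lambda g: (g * out * (1.0 - out),))


# ---- structural ops ----------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), vjp=vjp)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def vjp(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(out, parents=tuple(tensors), vjp=vjp)


def conv1d(x: Tensor, w: Tensor) -> Tensor:
    """Valid 1-D correlation.

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K) -> (B, C_out, L-K+1).
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, L = x.shape
    Cout, Cin2, K = w.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, filters {Cin2}")
    if K > L:
        raise ValueError(f"filter length {K} exceeds signal length {L}")
    win = sliding_window_view(x.data, K, axis=-1)  # (B, Cin, Lout, K)
    out = np.einsum("bcik,ock->boi", win, w.data)

    def vjp(g):
        gw = np.einsum("bcik,boi->ock", win, g)
        gpad = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
        gwin = sliding_window_view(gpad, K, axis=-1)  # (B, Cout, L, K)
        gx = np.einsum("boik,ock->bci", gwin, w.data[:, :, ::-1])
        return gx, gw

    return Tensor(out, parents=(x, w), vjp=vjp)


# ---- composed helpers ---------------------------------------------------

def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.max(axis=axis, keepdims=True)
    out = log(exp(x - m).sum(axis=axis, keepdims=True)) + m
    if not keepdims:
        out = out.reshape(np.squeeze(out.data, axis=axis).shape)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.max(axis=axis, keepdims=True)
    e = exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)
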