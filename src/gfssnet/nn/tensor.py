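"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-free graph of :class:`Tensor` nodes; each op records a backward
closure on its output.  Only the operations needed by the segmentation
network are provided.  Arrays are kept in float32 by default; gradients
accumulate in the same dtype as the data.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype if dtype is not None else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __len__(self) -> int:
        return self.data.shape[0]

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep (BPTT)
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not (parent.requires_grad or parent._parents):
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
                    if parent.requires_grad and not parent._parents:
                        pass  # leaf grads are set when popped above

    # ------------------------------------------------------------- factories
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], list] | None) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bwd(g):
            return [(a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))]

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: [(a, -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bwd(g):
            return [(a, _unbroadcast(g * b.data, a.shape)),
                    (b, _unbroadcast(g * a.data, b.shape))]

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bwd(g):
            return [(a, _unbroadcast(g / b.data, a.shape)),
                    (b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))]

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            return [(a, g * p * np.power(a.data, p - 1))]

        return Tensor._make(np.power(a.data, p), (a,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        a, b = self, other

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return [(a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape))]

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: [(a, g * out_data)])

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: [(a, g / (2.0 * out_data))])

    def abs(self):
        a = self
        return Tensor._make(np.abs(a.data), (a,), lambda g: [(a, g * np.sign(a.data))])

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: [(a, g * mask)])

    def sigmoid(self):
        a = self
        # overflow-safe: exp of a non-positive argument on both branches
        pos = a.data >= 0
        e = np.exp(np.where(pos, -a.data, a.data))
        out_data = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._make(out_data, (a,),
                            lambda g: [(a, g * out_data * (1.0 - out_data))])

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,),
                            lambda g: [(a, g * (1.0 - out_data * out_data))])

    def softplus(self):
        a = self
        out_data = np.logaddexp(0.0, a.data)
        pos = a.data >= 0
        e = np.exp(np.where(pos, -a.data, a.data))
        sig = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._make(out_data, (a,), lambda g: [(a, g * sig)])

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return [(a, np.broadcast_to(g, a.shape).copy())]
            g2 = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(ax % a.ndim for ax in axes)
                for ax in sorted(axes):
                    g2 = np.expand_dims(g2, ax)
            return [(a, np.broadcast_to(g2, a.shape).copy())]

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            full = a.data.max(axis=axis, keepdims=True)
            mask = (a.data == full).astype(a.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)
            g2 = g if keepdims or axis is None else np.expand_dims(
                g, axis if isinstance(axis, int) else tuple(axis))
            return [(a, mask * g2)]

        return Tensor._make(out_data, (a,), bwd)

    # ---------------------------------------------------------- shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: [(a, g.reshape(a.shape))])

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: [(a, g.transpose(inv))])

    def moveaxis(self, src, dst):
        a = self
        return Tensor._make(np.moveaxis(a.data, src, dst), (a,),
                            lambda g: [(a, np.moveaxis(g, dst, src))])

    def __getitem__(self, idx):
        a = self
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis)))
                    for p in parts)

        def bwd(g):
            out = np.zeros_like(a.data)
            if basic:
                out[idx] += g  # basic indexing views have no duplicates
            else:
                np.add.at(out, idx, g)
            return [(a, out)]

        return Tensor._make(a.data[idx], (a,), bwd)

    def pad(self, pad_width):
        a = self
        slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, a.shape))
        return Tensor._make(np.pad(a.data, pad_width), (a,),
                            lambda g: [(a, g[slices])])

    # ------------------------------------------------------------ composites
    def softmax(self, axis: int = -1):
        z = self - self.max(axis=axis, keepdims=True).detach()
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if arr.dtype == np.float64 and arr.ndim > 0:
        return Tensor(arr)  # keep double precision for oracle tests
    dtype = like.dtype if like is not None else np.float32
    return Tensor(arr.astype(dtype))


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return out

    return Tensor._make(data, tuple(tensors), bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return [(t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts)]

    return Tensor._make(data, tuple(tensors), bwd)
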