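"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything trainable in this package (Chebyshev graph convolutions, the
1D-CNN branch, the fusion head, the population GCN) is built from the small
set of differentiable primitives below.  Tensors wrap float64 arrays; the
graph is taped dynamically and freed after :meth:`Tensor.backward`.

Only what the models need is implemented: broadcasting elementwise
arithmetic, batched matmul, relu/exp/log/sqrt, reductions, reshaping,
concatenation, fancy indexing (gather) and a strided valid 1-D
cross-correlation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, out):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(self.data**exponent, (self,), backward)

    # -- matmul ----------------------------------------------------------------
    def __matmul__(self, other):
        other = self._wrap(other)
        if self.data.ndim == 1 and other.data.ndim == 2:
            return (self.reshape(1, -1) @ other).reshape(-1)
        a, b = self.data, other.data
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D")

        def backward(g, out):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(a @ b, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def exp(self):
        def backward(g, out):
            self._accum(g * out.data)

        return Tensor._from_op(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        def backward(g, out):
            self._accum(g * 0.5 / out.data)

        return Tensor._from_op(np.sqrt(self.data), (self,), backward)

    # -- reductions --------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, out):
            self._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g, out):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._from_op(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- composed helpers ----------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- autodiff engine -------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)
        # free the tape
        for node in order:
            node._backward = None
            node._parents = ()


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Valid (no-padding) strided 1-D cross-correlation.

    ``x``: (batch, in_channels, length); ``w``: (out_channels, in_channels,
    kernel); ``b``: (out_channels,).  Output length is
    ``(length - kernel) // stride + 1``; the kernel is applied as written
    (no flip), y_i = sum_j w_j x_{i*stride+j} + b.
    """
    x, w, b = Tensor._wrap(x), Tensor._wrap(w), Tensor._wrap(b)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    batch, c_in, length = x.data.shape
    c_out, c_in_w, kernel = w.data.shape
    if c_in_w != c_in:
        raise ValueError(f"channel mismatch: input {c_in}, kernel {c_in_w}")
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    l_out = (length - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, kernel, axis=2)
    windows = windows[:, :, :: stride, :][:, :, :l_out, :]  # (B, C_in, L_out, n)
    y = np.einsum("bcln,ocn->bol", windows, w.data) + b.data[None, :, None]

    def backward(g, out):
        if w.requires_grad:
            w._accum(np.einsum("bol,bcln->ocn", g, windows))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for j in range(kernel):
                contrib = np.einsum("bol,oc->bcl", g, w.data[:, :, j])
                gx[:, :, j : j + stride * l_out : stride] += contrib
            x._accum(gx)

    return Tensor._from_op(y, (x, w, b), backward)
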