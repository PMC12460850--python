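"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine implements exactly the primitives the spectral networks need:
broadcast-aware elementwise arithmetic, reductions, matrix products,
shape manipulation, a stride-1 "same"-padded 1-D convolution (and its
transpose), and the pointwise nonlinearities.  Gradients are accumulated
by reverse topological traversal from a scalar loss.

Arrays are kept in float64 throughout; that keeps finite-difference
gradient checks meaningful at tight tolerances.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "conv1d_same", "conv1d_transpose_same"]


def _as_array(x) -> np.ndarray:
    """Dtype-preserving array view; non-float inputs become float64.

    The engine computes in whatever float precision the inputs carry:
    reference checks run in float64, network training may cast its
    parameters and batches to float32 for speed.
    """
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
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
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- construction helpers ------------------------------------------
    @staticmethod
    def param(data, name: str = "") -> "Tensor":
        return Tensor(data, requires_grad=True, name=name)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: backward closures may pass through views of upstream grads
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (a scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise binary ops ----------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        if not isinstance(other, Tensor):
            # python scalars adopt self's dtype so float32 graphs stay float32
            if np.isscalar(other):
                other = Tensor(np.asarray(other, dtype=self.data.dtype))
            else:
                other = Tensor(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor(out_data, True, (self, other), backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor(self.data ** p, self.requires_grad, (self,), None)
        if self.requires_grad:
            def backward(g):
                self._accumulate(g * p * self.data ** (p - 1.0))
            out._backward = backward
        return out

    def maximum(self, other) -> "Tensor":
        """Elementwise max; ties send the gradient to `self`."""
        return self._binary(other, np.maximum,
                            lambda g, a, b: g * (a >= b),
                            lambda g, a, b: g * (a < b))

    def minimum(self, other) -> "Tensor":
        return self._binary(other, np.minimum,
                            lambda g, a, b: g * (a <= b),
                            lambda g, a, b: g * (a > b))

    # -- elementwise unary ops -----------------------------------------
    def _unary(self, out_data, grad_fn) -> "Tensor":
        if not self.requires_grad:
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,), None)

        def backward(g):
            self._accumulate(grad_fn(g, out_data))
        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        return self._unary(y, lambda g, y: g * y)

    def log(self) -> "Tensor":
        return self._unary(np.log(self.data), lambda g, y: g / self.data)

    def abs(self) -> "Tensor":
        return self._unary(np.abs(self.data), lambda g, y: g * np.sign(self.data))

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, lambda g, y: g * y * (1.0 - y))

    def relu(self) -> "Tensor":
        return self._unary(np.maximum(self.data, 0.0),
                           lambda g, y: g * (self.data > 0))

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        y = np.where(self.data >= 0, self.data, alpha * self.data)
        return self._unary(y, lambda g, y: g * np.where(self.data >= 0, 1.0, alpha))

    def elu(self, alpha: float = 1.0) -> "Tensor":
        d = self.data
        pos = d >= 0
        # single exp pass on the clipped input; exact where d < 0
        expd = np.exp(np.minimum(d, 0.0))
        y = np.where(pos, d, alpha * (expd - 1.0))
        return self._unary(y, lambda g, y: g * np.where(pos, 1.0, alpha * expd))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,), None)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient routed to the (first) argmax."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,), None)

        def backward(g):
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            mask = (self.data == expanded)
            # split gradient among ties (measure-zero for continuous data)
            counts = mask.sum(axis=axis, keepdims=True)
            ge = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(mask * ge / counts)
        out._backward = backward
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not self.requires_grad:
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,), None)

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))
        out._backward = backward
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out_data = self.data.transpose(axes)
        if not self.requires_grad:
            return Tensor(out_data)
        inv = tuple(np.argsort(axes))
        out = Tensor(out_data, True, (self,), None)

        def backward(g):
            self._accumulate(g.transpose(inv))
        out._backward = backward
        return out

    # -- linear algebra ------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = backward
        return out

    __matmul__ = matmul


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(out_data, True, tuple(tensors), None)

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = backward
    return out


# ---------------------------------------------------------------------
# Stride-1 "same"-padded 1-D convolution.
# x: (N, C_in, L), w: (C_out, C_in, k) with k odd, b: (C_out,)
# y[n, o, i] = sum_{c, j} w[o, c, j] * x[n, c, i + j - (k-1)/2] + b[o]
# ---------------------------------------------------------------------

def _corr1d_same_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """y[n,o,i] = sum_{c,j} w[o,c,j] * xpad[n,c,i+j], as k broadcast matmuls."""
    n, c, length = x.shape
    k = w.shape[2]
    if k == 1:
        return np.matmul(w[:, :, 0], x)
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    out = np.matmul(w[:, :, 0], xp[:, :, :length])
    for j in range(1, k):
        out += np.matmul(w[:, :, j], xp[:, :, j:j + length])
    return out


def _corr1d_grad_w(x: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """Gradient wrt the kernel: gw[o,c,j] = sum_{n,i} g[n,o,i] * xpad[n,c,i+j]."""
    n, c, length = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    gw = np.empty((g.shape[1], c, k), dtype=x.dtype)
    for j in range(k):
        # (n,o,l) x (n,c,l) summed over n and l
        gw[:, :, j] = np.einsum("nol,ncl->oc", g, xp[:, :, j:j + length],
                                optimize=True)
    return gw


def conv1d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Cross-correlation with zero "same" padding at stride 1."""
    k = w.data.shape[2]
    if k % 2 == 0:
        raise ValueError("kernel width must be odd for symmetric same padding")
    out_data = _corr1d_same_raw(x.data, w.data)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in parents)
    if not req:
        return Tensor(out_data)
    out = Tensor(out_data, True, parents, None)

    def backward(g):
        if x.requires_grad:
            # gradient wrt input: correlate g with channel-transposed, flipped kernel
            x._accumulate(_corr1d_same_raw(g, w.data.transpose(1, 0, 2)[:, :, ::-1]))
        if w.requires_grad:
            w._accumulate(_corr1d_grad_w(x.data, g, k))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
    out._backward = backward
    return out


def conv1d_transpose_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 "same" transposed convolution: y[i] = sum_j w[j] * x[i - j].

    At stride 1 this equals cross-correlation with the index-reversed
    kernel, which is how it is realised here (the equivalence is exercised
    directly in the test-suite against the literal summation).
    """
    w_flipped = w.transpose((0, 1, 2))  # no-op keeps graph simple; flip below
    # flip along the tap axis with gradient support
    out_w_data = w.data[:, :, ::-1].copy()
    if w.requires_grad:
        w_flipped = Tensor(out_w_data, True, (w,), None)

        def backward_w(g):
            w._accumulate(g[:, :, ::-1])
        w_flipped._backward = backward_w
    else:
        w_flipped = Tensor(out_w_data)
    return conv1d_same(x, w_flipped, b)
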