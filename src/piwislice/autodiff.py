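"""A minimal reverse-mode tensor autodiff engine on numpy.

The predictor is a small network (per-position projection, positional table,
1D convolution, multi-head self-attention, dense head) that must expose exact
gradients both with respect to its parameters (training) and with respect to
its inputs (gradient saliency). This module provides just the operations that
network needs, as a tape-based reverse-mode engine over ``numpy.ndarray``:
elementwise arithmetic with broadcasting, batched matmul, reductions, reshape
and transpose, concatenation, ReLU/abs, fused softmax, layer normalization,
1D convolution, and dropout.

Every op returns a new :class:`Tensor` holding a closure that propagates the
upstream gradient to its parents; :meth:`Tensor.backward` runs the closures in
reverse topological order. Arrays are float32 by default (plenty for
optimization); wrap finite-difference gradient checks in
``use_dtype(np.float64)``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

#: default floating dtype of the engine. float32 is plenty for optimization
#: and halves memory traffic; switch to float64 (``use_dtype``) for
#: finite-difference gradient verification.
DTYPE = np.float32


@contextlib.contextmanager
def use_dtype(dtype) -> Iterator[None]:
    """Temporarily change the engine's floating dtype (e.g. for grad checks)."""
    global DTYPE
    previous = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(grad, self.data.shape))
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    def __pow__(self, exponent: float) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, _parents=(self,), _backward=bw)

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bw)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    ex = np.exp(shifted)
    y = ex / ex.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor(y, _parents=(x,), _backward=bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, x.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, x.shape[-1]).sum(axis=0))
        if x.requires_grad:
            dxhat = g * gamma.data
            term = dxhat - dxhat.mean(axis=-1, keepdims=True) - xhat * (dxhat * xhat).mean(
                axis=-1, keepdims=True
            )
            x._accumulate(inv_std * term)

    return Tensor(gamma.data * xhat + beta.data, _parents=(x, gamma, beta), _backward=bw)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Length-preserving 1D convolution.

    ``x``: (B, L, C_in); ``weight``: (C_out, C_in, K) with K odd; ``bias``:
    (C_out,). Zero padding of width (K-1)/2 on both ends keeps the output at
    (B, L, C_out).
    """
    B, L, c_in = x.shape
    c_out, c_in_w, K = weight.shape
    if c_in_w != c_in:
        raise ValueError(f"conv1d: input has {c_in} channels, weight expects {c_in_w}")
    if K % 2 != 1:
        raise ValueError("conv1d kernel size must be odd")
    pad = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B, L, C_in, K)
    out = np.einsum("blck,ock->blo", windows, weight.data) + bias.data

    def bw(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            weight._accumulate(np.einsum("blck,blo->ock", windows, g))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k : k + L, :] += g @ weight.data[:, :, k]
            x._accumulate(dxp[:, pad : pad + L, :])

    return Tensor(out, _parents=(x, weight, bias), _backward=bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(DTYPE)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=bw)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
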