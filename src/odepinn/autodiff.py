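"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for training physics-informed networks:
:class:`Tensor` wraps an ``ndarray``, records the operations applied to it,
and :meth:`Tensor.backward` accumulates gradients by walking the tape in
reverse topological order.  Broadcasting follows numpy semantics; gradients
of broadcast operands are summed back to the operand's shape.

The op set is deliberately minimal — elementwise arithmetic, ``matmul``,
smooth activations, reductions, basic slicing, plus fused ``linear``,
``dtanh_mul`` and ``mse`` kernels that keep the tape short on the hot
training path.  Gradients of operands that are constants (no ``requires_grad``
anywhere upstream) are never computed.  Correctness is established against
central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "tanh", "exp", "sigmoid", "softplus",
    "linear", "dtanh_mul", "mse", "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], tuple] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def _track(self) -> bool:
        return self.requires_grad or self._parents != ()

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf.

        ``grad`` defaults to 1 and must then be called on a scalar tensor.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p._parents and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        if self.requires_grad:
            g0 = grads[id(self)]
            self.grad = g0 if self.grad is None else self.grad + g0
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if parent.requires_grad:
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                if parent._parents:
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data)
        if self._track() or other._track():
            out._parents = (self, other)

            def _bw(g):
                res = []
                if self._track():
                    res.append((self, _unbroadcast(g, self.data.shape)))
                if other._track():
                    res.append((other, _unbroadcast(g, other.data.shape)))
                return res

            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        if self._track():
            out._parents = (self,)
            out._backward = lambda g: ((self, -g),)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data)
        if self._track() or other._track():
            out._parents = (self, other)

            def _bw(g):
                res = []
                if self._track():
                    res.append((self, _unbroadcast(g * other.data, self.data.shape)))
                if other._track():
                    res.append((other, _unbroadcast(g * self.data, other.data.shape)))
                return res

            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data)
        if self._track() or other._track():
            out._parents = (self, other)

            def _bw(g):
                res = []
                if self._track():
                    res.append((self, _unbroadcast(g / other.data, self.data.shape)))
                if other._track():
                    res.append(
                        (other,
                         _unbroadcast(-g * self.data / other.data**2,
                                      other.data.shape))
                    )
                return res

            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not isinstance(exponent, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**exponent)
        if self._track():
            out._parents = (self,)
            out._backward = lambda g: (
                (self, g * exponent * self.data ** (exponent - 1)),
            )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data)
        if self._track() or other._track():
            out._parents = (self, other)

            def _bw(g):
                res = []
                if self._track():
                    res.append((self, g @ other.data.T))
                if other._track():
                    res.append((other, self.data.T @ g))
                return res

            out._backward = _bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key])
        if self._track():
            out._parents = (self,)

            def _bw(g, key=key):
                full = np.zeros_like(self.data)
                if isinstance(key, np.ndarray) or (
                        isinstance(key, tuple)
                        and any(isinstance(k, np.ndarray) for k in key)):
                    np.add.at(full, key, g)  # fancy keys may repeat indices
                else:
                    full[key] += g
                return ((self, full),)

            out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum())
        if self._track():
            out._parents = (self,)
            out._backward = lambda g: (
                (self, np.broadcast_to(g, self.data.shape).copy()),
            )
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean())
        if self._track():
            out._parents = (self,)
            out._backward = lambda g: (
                (self, np.broadcast_to(g / n, self.data.shape).copy()),
            )
        return out


def as_tensor(value) -> Tensor:
    """Wrap scalars/arrays into a constant :class:`Tensor`; pass tensors through."""
    return value if isinstance(value, Tensor) else Tensor(value)


def _unary(x: Tensor, value: np.ndarray, deriv: np.ndarray) -> Tensor:
    out = Tensor(value)
    if x._track():
        out._parents = (x,)
        out._backward = lambda g: ((x, g * deriv),)
    return out


def tanh(x) -> Tensor:
    x = as_tensor(x)
    value = np.tanh(x.data)
    return _unary(x, value, 1.0 - value**2)


def exp(x) -> Tensor:
    x = as_tensor(x)
    value = np.exp(x.data)
    return _unary(x, value, value)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    value = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, value, value * (1.0 - value))


def softplus(x) -> Tensor:
    """log(1 + e^x), evaluated stably; gradient is the logistic sigmoid."""
    x = as_tensor(x)
    value = np.logaddexp(0.0, x.data)
    return _unary(x, value, 1.0 / (1.0 + np.exp(-x.data)))


# -- fused kernels for the training hot path ---------------------------------

def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map ``x @ weight + bias`` as a single tape node."""
    x = as_tensor(x)
    value = x.data @ weight.data
    if bias is not None:
        value = value + bias.data
    out = Tensor(value)
    if x._track() or weight._track() or (bias is not None and bias._track()):
        parents = (x, weight) if bias is None else (x, weight, bias)
        out._parents = parents

        def _bw(g):
            res = []
            if x._track():
                res.append((x, g @ weight.data.T))
            if weight._track():
                res.append((weight, x.data.T @ g))
            if bias is not None and bias._track():
                res.append((bias, _unbroadcast(g, bias.data.shape)))
            return res

        out._backward = _bw
    return out


def dtanh_mul(a: Tensor, dz: Tensor) -> Tensor:
    """``(1 - a^2) * dz`` — tangent propagation through ``a = tanh(z)``.

    `a` must already be the tanh output; fusing saves three tape nodes per
    hidden layer in the derivative pass.
    """
    sech2 = 1.0 - a.data**2
    out = Tensor(sech2 * dz.data)
    if a._track() or dz._track():
        out._parents = (a, dz)

        def _bw(g):
            res = []
            if a._track():
                res.append((a, _unbroadcast(-2.0 * g * a.data * dz.data,
                                            a.data.shape)))
            if dz._track():
                res.append((dz, _unbroadcast(g * sech2, dz.data.shape)))
            return res

        out._backward = _bw
    return out


def mse(pred: Tensor, target) -> Tensor:
    """Mean squared error ``mean((pred - target)^2)`` as a single node."""
    pred = as_tensor(pred)
    target = as_tensor(target)
    diff = pred.data - target.data
    out = Tensor(np.mean(diff**2))
    if pred._track() or target._track():
        out._parents = (pred, target)
        n = diff.size

        def _bw(g):
            base = (2.0 / n) * g * diff
            res = []
            if pred._track():
                res.append((pred, _unbroadcast(base, pred.data.shape)))
            if target._track():
                res.append((target, _unbroadcast(-base, target.data.shape)))
            return res

        out._backward = _bw
    return out


def grad_check(fn: Callable[[Sequence[Tensor]], Tensor], tensors: Sequence[Tensor],
               eps: float = 1e-6) -> float:
    """Max relative error between backprop and central finite differences.

    Test utility: perturbs every entry of every tensor in `tensors`.
    """
    for t in tensors:
        t.zero_grad()
    fn(tensors).backward()
    worst = 0.0
    for t in tensors:
        flat = t.data.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(tensors).item()
            flat[i] = orig - eps
            lo = fn(tensors).item()
            flat[i] = orig
            fd = (hi - lo) / (2 * eps)
            ad = t.grad.reshape(-1)[i]
            scale = max(abs(fd), abs(ad), 1.0)
            worst = max(worst, abs(fd - ad) / scale)
    return worst
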