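"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the velocity model's objective needs:
broadcasting arithmetic, matmul, exp/log, sigmoid/softplus/relu, reductions,
log-sum-exp, and the log-gamma/digamma pair required for closed-form Dirichlet
KL divergences.  Gradients of ``gammaln`` and ``digamma`` come from
``scipy.special`` (digamma and trigamma respectively).

This is a deliberately small engine: a tape of ``Tensor`` nodes, topological
sort, and per-op backward closures.  It is single-threaded numpy throughout,
which keeps training runs bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import gammainc as _gammainc
from scipy.special import gammaln as _gammaln

__all__ = ["Tensor", "Adam", "no_grad", "gamma_sample"]


def _trigamma(x: np.ndarray) -> np.ndarray:
    """Vectorized psi'(x) for x > 0: upward recurrence into the asymptotic
    range, then the standard series (much faster than polygamma's zeta path)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    y = x.copy()
    for _ in range(6):  # shift y up to >= 6 accumulating 1/y^2 terms
        small = y < 6.0
        if not small.any():
            break
        out[small] += 1.0 / y[small] ** 2
        y[small] += 1.0
    inv = 1.0 / y
    inv2 = inv * inv
    out += inv * (1.0 + inv * (0.5 + inv * (1.0 / 6.0 - inv2 * (1.0 / 30.0 - inv2 * (1.0 / 42.0 - inv2 / 30.0)))))
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


import contextlib

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def softplus(self):
        # numerically stable: log(1+e^x) = max(x,0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * sig,))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def gammaln(self):
        return self._make(_gammaln(self.data), (self,), lambda g: (g * _digamma(self.data),))

    def digamma(self):
        return self._make(
            _digamma(self.data), (self,), lambda g: (g * _trigamma(self.data),)
        )

    # -- shape / reductions ---------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int):
        m = self.data.max(axis=axis, keepdims=True)  # detached shift
        shifted = self - Tensor(m)
        s = shifted.exp().sum(axis=axis)
        return s.log() + Tensor(np.squeeze(m, axis=axis))

    def where(self, cond: np.ndarray, other: "Tensor"):
        """cond is a constant boolean mask: cond ? self : other."""
        other = self._lift(other)
        out_data = np.where(cond, self.data, other.data)

        def backward(g):
            return (
                _unbroadcast(np.where(cond, g, 0.0), self.shape),
                _unbroadcast(np.where(cond, 0.0, g), other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def detach(self):
        return Tensor(self.data)

    # -- backprop -------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g)  # copy: g may be reused by the op
                else:
                    parent.grad += g


def gamma_sample(conc: Tensor, rng: np.random.Generator) -> Tensor:
    """Reparameterized draw y ~ Gamma(conc, 1) with implicit gradients.

    The pathwise derivative keeps the draw's quantile fixed:
    dy/da = -(dF/da) / pdf(y; a), with F the regularized lower incomplete
    gamma function; dF/da is evaluated by central finite difference.  Used to
    differentiate through Dirichlet samples (normalized gamma draws).
    """
    a = conc.data
    y = np.maximum(rng.gamma(np.maximum(a, 1e-8)), 1e-300)

    def backward(g):
        h = 1e-5 * np.maximum(a, 1e-3)
        dF_da = (_gammainc(a + h, y) - _gammainc(a - h, y)) / (2 * h)
        log_pdf = (a - 1) * np.log(y) - y - _gammaln(a)
        dy_da = -dF_da * np.exp(-log_pdf)
        # guard against overflow where the density underflows
        dy_da = np.clip(np.nan_to_num(dy_da), -1e6, 1e6)
        return (g * dy_da,)

    out = Tensor(y)
    if conc.requires_grad and _GRAD_ENABLED[-1]:
        out.requires_grad = True
        out._parents = (conc,)
        out._backward = backward
    return out


class Adam:
    """Adam with decoupled weight decay over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr=1e-2, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            if self.weight_decay:
                p.data *= 1 - self.lr * self.weight_decay
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
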