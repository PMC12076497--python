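"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: just the primitives the few-shot
model needs (broadcast arithmetic, batched matmul, softmax, layer norm,
logistic losses).  Values are float64 throughout; gradients are exact
vector-Jacobian products and are verified against central differences in
the test suite.

Only ``Tensor`` objects created with ``requires_grad=True`` (parameters)
receive gradients; everything reachable from them on the tape does too.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad=False, _parents=(), _vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = _parents
        self._vjp = _vjp

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return take(self, key)

    # -- autodiff --------------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._vjp(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad = parent.grad + pgrad


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitives ---------------------------------------------------------------


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.value + b.value,
        _parents=(a, b),
        _vjp=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.value * b.value,
        _parents=(a, b),
        _vjp=lambda g: (
            _unbroadcast(g * b.value, a.shape),
            _unbroadcast(g * a.value, b.shape),
        ),
    )


def power(a, exponent: float):
    a = as_tensor(a)
    out = a.value**exponent
    return Tensor(
        out,
        _parents=(a,),
        _vjp=lambda g: (g * exponent * a.value ** (exponent - 1.0),),
    )


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = g @ np.swapaxes(b.value, -1, -2)
        gb = np.swapaxes(a.value, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return Tensor(a.value @ b.value, _parents=(a, b), _vjp=vjp)


def reshape(a, shape):
    a = as_tensor(a)
    return Tensor(
        a.value.reshape(shape),
        _parents=(a,),
        _vjp=lambda g: (g.reshape(a.shape),),
    )


def transpose(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)
    return Tensor(
        a.value.transpose(axes),
        _parents=(a,),
        _vjp=lambda g: (g.transpose(inv),),
    )


def broadcast_to(a, shape):
    a = as_tensor(a)
    return Tensor(
        np.broadcast_to(a.value, shape).copy(),
        _parents=(a,),
        _vjp=lambda g: (_unbroadcast(g, a.shape),),
    )


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def take(a, key):
    a = as_tensor(a)

    def vjp(g):
        out = np.zeros(a.shape)
        np.add.at(out, key, g)
        return (out,)

    return Tensor(a.value[key], _parents=(a,), _vjp=vjp)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.shape).copy(),)

    return Tensor(
        a.value.sum(axis=axis, keepdims=keepdims), _parents=(a,), _vjp=vjp
    )


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.value.size if axis is None else a.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def relu(a):
    a = as_tensor(a)
    mask = a.value > 0
    return Tensor(a.value * mask, _parents=(a,), _vjp=lambda g: (g * mask,))


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.value)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out,))


def log(a):
    a = as_tensor(a)
    return Tensor(np.log(a.value), _parents=(a,), _vjp=lambda g: (g / a.value,))


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.value)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * 0.5 / out,))


def sigmoid(a):
    a = as_tensor(a)
    out = _sigmoid_np(a.value)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out * (1.0 - out),))


def _sigmoid_np(x):
    # numerically stable in both tails
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(a):
    a = as_tensor(a)
    out = np.logaddexp(0.0, a.value)
    return Tensor(
        out, _parents=(a,), _vjp=lambda g: (g * _sigmoid_np(a.value),)
    )


def softmax(a, axis=-1):
    a = as_tensor(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        return (out * (g - (g * out).sum(axis=axis, keepdims=True)),)

    return Tensor(out, _parents=(a,), _vjp=vjp)


def layer_norm(x, gain, bias, eps: float = 1e-5):
    """Normalize over the last axis, then apply elementwise affine."""
    x, gain, bias = as_tensor(x), as_tensor(gain), as_tensor(bias)
    mu = x.value.mean(axis=-1, keepdims=True)
    var = x.value.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.value - mu) * inv
    out = xhat * gain.value + bias.value

    def vjp(g):
        dxhat = g * gain.value
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        dgain = _unbroadcast(g * xhat, gain.shape)
        dbias = _unbroadcast(g, bias.shape)
        return dx, dgain, dbias

    return Tensor(out, _parents=(x, gain, bias), _vjp=vjp)


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy, numerically stable in the logits."""
    logits, targets = as_tensor(logits), as_tensor(targets)
    z, y = logits.value, targets.value
    n = z.size
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))

    def vjp(g):
        return (g * (_sigmoid_np(z) - y) / n, None)

    return Tensor(loss, _parents=(logits, targets), _vjp=vjp)
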