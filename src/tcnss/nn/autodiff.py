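"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the tensor operations the sequence models in this package
need: broadcasting arithmetic, (batched) matrix products, the usual
activations, softmax/log-softmax, concatenation/slicing, left-padded dilated
causal convolution and length-aware sequence reversal for padded batches.
Gradients are accumulated by topological traversal of the recorded graph.

All tensors are float64; the models here are desk-scale, so precision is
preferred over speed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph recording (evaluation-mode forward passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    if _grad_enabled and any(p.requires_grad for p in parents):
        out = Tensor(data, requires_grad=True)
        out._parents = parents
        out._backward = backward
        return out
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce `grad` back to `shape` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# -- arithmetic ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return (_unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        return (_unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _node(data, (a, b), backward)


def pow_const(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def backward(g):
        return (g * p * a.data ** (p - 1),)

    return _node(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(data, (a, b), backward)


# -- activations --------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return (g * data * (1.0 - data),)

    return _node(data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        return (g * (1.0 - data ** 2),)

    return _node(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        return (g * (a.data > 0.0),)

    return _node(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return (g * data,)

    return _node(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return _node(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return (data * (g - dot),)

    return _node(data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse
    probs = np.exp(data)

    def backward(g):
        return (g - probs * g.sum(axis=axis, keepdims=True),)

    return _node(data, (a,), backward)


# -- shape ops ----------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.shape),)

    return _node(data, (a,), backward)


def transpose_last(a) -> Tensor:
    """Swap the last two axes."""
    a = as_tensor(a)
    data = np.swapaxes(a.data, -1, -2)

    def backward(g):
        return (np.swapaxes(g, -1, -2),)

    return _node(data, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(data, tuple(tensors), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Slice `length` entries from `start` along `axis`."""
    a = as_tensor(a)
    index = [slice(None)] * a.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    data = a.data[index]

    def backward(g):
        out = np.zeros(a.shape)
        out[index] = g
        return (out,)

    return _node(data, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _node(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -- sequence ops -------------------------------------------------------

def causal_dilated_conv(x, weight, bias=None, dilation: int = 1) -> Tensor:
    """Left-padded dilated causal 1-D convolution.

    `x` is (B, L, C_in), `weight` is (k, C_in, C_out).  Output position t is
    ``sum_i x[t - d*i] @ weight[i]``, with out-of-range taps treated as zero
    (equivalent to left-padding (k-1)*d zero rows), so the output at t
    depends only on inputs at positions <= t.
    """
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    x, weight = as_tensor(x), as_tensor(weight)
    k = weight.shape[0]
    B, L, _ = x.shape
    c_out = weight.shape[2]
    data = np.zeros((B, L, c_out))
    for i in range(k):
        s = dilation * i
        if s >= L:
            break
        data[:, s:, :] += x.data[:, :L - s, :] @ weight.data[i]
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        data += bias.data
        parents.append(bias)

    def backward(g):
        gx = np.zeros(x.shape)
        gw = np.zeros(weight.shape)
        for i in range(k):
            s = dilation * i
            if s >= L:
                break
            gx[:, :L - s, :] += g[:, s:, :] @ weight.data[i].T
            gw[i] = np.einsum("blc,bld->cd", x.data[:, :L - s, :], g[:, s:, :])
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 1)))
        return tuple(grads)

    return _node(data, tuple(parents), backward)


def reverse_padded(x, lengths) -> Tensor:
    """Reverse each sequence of a padded (B, L, C) batch over its valid prefix.

    Padding rows stay at the tail.  Applying the op twice is the identity.
    """
    x = as_tensor(x)
    B, L = x.shape[0], x.shape[1]
    lengths = np.asarray(lengths, dtype=int)
    idx = np.tile(np.arange(L), (B, 1))
    for b in range(B):
        n = lengths[b]
        idx[b, :n] = np.arange(n - 1, -1, -1)
    rows = np.arange(B)[:, None]
    data = x.data[rows, idx]

    def backward(g):
        return (g[rows, idx],)   # involution: same gather

    return _node(data, (x,), backward)


def dropout(x, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not training or rate <= 0.0:
        return as_tensor(x)
    x = as_tensor(x)
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)

    def backward(g):
        return (g * mask,)

    return _node(x.data * mask, (x,), backward)
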