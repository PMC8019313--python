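"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine sized for small recurrent networks: dense float64
tensors, broadcasting elementwise ops, (batched) matmul, and a few fused
ops (layer norm, softmax, sigmoid, softplus) where a single node is both
faster and numerically safer than a composition of primitives.

Gradient propagation is lazy: a node participates in backprop only if one
of its ancestors requires gradients, so constant inputs (embeddings,
targets) cost nothing extra.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "glorot", "zeros", "ones"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = _unbroadcast(g, a.data.shape)
                a._accum(ga, owned=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.data.shape)
                b._accum(gb, owned=gb is not g)

        return self._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g, owned=True)

        return self._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape), owned=True)
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape), owned=True)

        return self._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape), owned=True)
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data),
                                      b.data.shape), owned=True)

        return self._from_op(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g, a=self, n=exponent):
            if a.requires_grad:
                a._accum(g * n * a.data ** (n - 1), owned=True)

        return self._from_op(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2),
                                      a.data.shape), owned=True)
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g,
                                      b.data.shape), owned=True)

        return self._from_op(self.data @ other.data, (self, other), backward)

    def __getitem__(self, index):
        basic = isinstance(index, (int, slice)) or (
            isinstance(index, tuple)
            and all(isinstance(i, (int, slice)) for i in index))

        def backward(g, a=self, idx=index):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                if basic:
                    full[idx] = g
                else:
                    np.add.at(full, idx, g)
                a._accum(full, owned=True)

        return self._from_op(self.data[index], (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return self._from_op(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(np.swapaxes(g, ax1, ax2))

        return self._from_op(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy(), owned=True)

        return self._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities (fused) ----------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y), owned=True)

        return self._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y), owned=True)

        return self._from_op(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * (0.5 * (1.0 + np.tanh(0.5 * a.data))), owned=True)

        return self._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y, owned=True)

        return self._from_op(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / y, owned=True)

        return self._from_op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)),
                         owned=True)

        return self._from_op(out_data, (self,), backward)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """y = gain * (x - mean) / sqrt(var + eps) + bias, over the last axis."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = gain.data * xhat + bias.data

        def backward(g, a=self, gn=gain, bs=bias, xh=xhat, iv=inv):
            if gn.requires_grad:
                gn._accum(_unbroadcast(g * xh, gn.data.shape), owned=True)
            if bs.requires_grad:
                gb = _unbroadcast(g, bs.data.shape)
                bs._accum(gb, owned=gb is not g)
            if a.requires_grad:
                gx = g * gn.data
                m1 = gx.mean(axis=-1, keepdims=True)
                m2 = (gx * xh).mean(axis=-1, keepdims=True)
                a._accum(iv * (gx - m1 - xh * m2), owned=True)

        return self._from_op(out_data, (self, gain, bias), backward)

    # -- autodiff driver ------------------------------------------------------

    def _accum(self, g: np.ndarray, owned: bool = False) -> None:
        """Accumulate a gradient contribution.

        ``owned=True`` promises `g` is a freshly allocated array no other
        node aliases, so it can be adopted without a defensive copy.
        """
        if self.grad is None:
            self.grad = g if owned else np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go; parameters keep their grads
                node._backward = None
                node._parents = ()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tuple(tensors), offs=offsets):
        for i, t in enumerate(ts):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offs[i], offs[i + 1])
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tensors, backward)


# -- parameter initialisers ---------------------------------------------------


def glorot(shape: tuple[int, int], rng: np.random.Generator) -> Tensor:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones(shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Adam:
    """Adam optimizer with bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
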