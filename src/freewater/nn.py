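"""Minimal reverse-mode automatic differentiation over numpy arrays.

The estimators in this package are small (tens of thousands of parameters)
and train on CPU, so they run on a purpose-built tape-based autograd rather
than a deep-learning framework: a :class:`Tensor` wraps an ndarray and
records the backward closure of the op that produced it; :meth:`Tensor.backward`
walks the tape in reverse topological order.  Supported ops cover exactly
what the models use: broadcast arithmetic, two-operand einsum, pointwise
nonlinearities, reductions, slicing and concatenation.

Float32 is the working precision throughout the networks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "Linear", "Dropout", "BatchNorm1d", "rmse_loss"]

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            ga = _unbroadcast(g * other.data, self.shape) if self.requires_grad else None
            gb = _unbroadcast(g * self.data, other.shape) if other.requires_grad else None
            return (ga, gb)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def square(self):
        return self._make(self.data**2, (self,), lambda g: (2.0 * g * self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / np.maximum(out_data, 1e-12),))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def abs(self):
        return self._make(np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),))

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return self._make(self.data[key], (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]

        def backward(g):
            return tuple(np.split(g, np.cumsum(sizes)[:-1], axis=axis))

        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
        out.requires_grad = any(t.requires_grad for t in tensors)
        if out.requires_grad:
            out._prev = tuple(tensors)
            out._backward = backward
        return out

    # -- contractions ---------------------------------------------------------
    @staticmethod
    def einsum(spec: str, a: "Tensor", b: "Tensor") -> "Tensor":
        """Two-operand einsum.  Every index of each operand must appear in
        the output or in the other operand (no internal sums), which makes
        the adjoint another einsum with permuted subscripts."""
        a, b = Tensor._lift(a), Tensor._lift(b)
        ins, out_s = spec.split("->")
        sa, sb = ins.split(",")

        def backward(g):
            ga = np.einsum(f"{out_s},{sb}->{sa}", g, b.data) if a.requires_grad else None
            gb = np.einsum(f"{out_s},{sa}->{sb}", g, a.data) if b.requires_grad else None
            return (ga, gb)

        res = Tensor(np.einsum(spec, a.data, b.data))
        res.requires_grad = a.requires_grad or b.requires_grad
        if res.requires_grad:
            res._prev = (a, b)
            res._backward = backward
        return res

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            ga = g @ other.data.swapaxes(-1, -2) if self.requires_grad else None
            gb = self.data.swapaxes(-1, -2) @ g if other.requires_grad else None
            return (ga, gb)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def poly_quadratic(self) -> "Tensor":
        """Fused pointwise g -> g + g² (the tensor-product nonlinearity)."""
        return self._make(
            self.data + self.data**2, (self,), lambda g: (g * (1.0 + 2.0 * self.data),)
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- engine ---------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._prev, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=DTYPE)
                parent.grad = g if parent.grad is None else parent.grad + g


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def make_node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Build a graph node for a custom fused op.

    ``backward(grad)`` must return one gradient (or None) per parent.
    """
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._prev = tuple(parents)
        out._backward = backward
    return out


def rmse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Root-mean-square error, the training criterion of every estimator."""
    diff = pred - Tensor(np.asarray(target, dtype=DTYPE).reshape(pred.shape))
    return diff.square().mean().sqrt()


class Adam:
    """Adam with optional per-call parameter subset (used by fc-only tuning)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Module:
    """Tiny module base: parameter registry + train/eval mode flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.standard_normal((n_in, n_out)) * scale)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Standard batch normalization over the batch axis (used by the FCNs)."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        # mu/var treated as constants wrt the graph (standard small-batch BN approx)
        xhat = (x - Tensor(mu)) * Tensor(inv)
        return xhat * self.gamma + self.beta
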