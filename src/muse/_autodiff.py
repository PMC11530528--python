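"""Minimal reverse-mode automatic differentiation over numpy arrays.

This backs all model training in the package. The design is deliberately
small: a :class:`Tensor` wraps a float64 ndarray, records its parents and a
backward closure, and :meth:`Tensor.backward` runs a topological sweep.
Only the operations the models need are implemented. Everything is
deterministic given the numpy RNG state, which is what makes seed-exact
reproducibility contracts possible without a deep-learning framework.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

ArrayLike = Union[np.ndarray, float, int, list, tuple]


def _as_array(x: ArrayLike) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    for _ in range(ndim_extra):
        grad = grad.sum(axis=0)
    for i, dim in enumerate(shape):
        if dim == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = grad.astype(np.float64, copy=True)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(
            self.data ** exponent,
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(
            np.maximum(self.data, 0.0),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(
            np.log(self.data),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        from scipy.special import expit

        val = expit(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - val * val))

        out._backward = bw
        return out

    # -- shaping / indexing --------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(
            self.data.reshape(*shape),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = bw
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Select rows by integer index (with repetition allowed)."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(
            self.data[index],
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accumulate(acc)

        out._backward = bw
        return out


# ----------------------------------------------------------------------
# Free functions
# ----------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    acc = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(acc, segment_ids, t.data)
    out = Tensor(acc, requires_grad=t.requires_grad, _parents=(t,))

    def bw(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accumulate(g[segment_ids])

    out._backward = bw
    return out


def sparse_matmul(mat: sp.spmatrix, t: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a differentiable tensor."""
    mat = mat.tocsr()
    out = Tensor(mat @ t.data, requires_grad=t.requires_grad, _parents=(t,))

    def bw(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accumulate(mat.T @ g)

    out._backward = bw
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    shifted = t.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    val = shifted - lse
    out = Tensor(val, requires_grad=t.requires_grad, _parents=(t,))
    softmax = np.exp(val)

    def bw(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def stack_params(tensors: Iterable[Tensor]) -> list[Tensor]:
    return [t for t in tensors if t.requires_grad]


# ----------------------------------------------------------------------
# Module / parameter machinery
# ----------------------------------------------------------------------

class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data: ArrayLike):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny nn.Module analogue: parameter discovery plus train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            params.extend(_collect_params(value, seen))
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            mods.extend(_collect_modules(value))
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state dict size mismatch")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=np.float64).copy()


def _collect_params(value, seen: set[int]) -> list[Parameter]:
    if isinstance(value, Parameter):
        if id(value) in seen:
            return []
        seen.add(id(value))
        return [value]
    if isinstance(value, Module):
        out = []
        for v in vars(value).values():
            out.extend(_collect_params(v, seen))
        return out
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_params(v, seen))
        return out
    return []


def _collect_modules(value) -> list[Module]:
    if isinstance(value, Module):
        return value.modules()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """ReLU MLP; `dims` includes input and output widths."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class BatchNorm1d(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            )
            norm = centered * (var + self.eps) ** -0.5
        else:
            norm = (x - self.running_mean) * (
                Tensor(self.running_var + self.eps) ** -0.5
            )
        return norm * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1): {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class AdamW:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
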