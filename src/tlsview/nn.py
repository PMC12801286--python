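"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

Sized for the small dense networks in this package (gated-attention pooling,
a few-layer MLPs, the two-branch fusion head): dense tensors, broadcasting
elementwise ops, (batched) matmul, reductions, concatenation and the usual
activations, with an Adam/AdamW optimizer and the learning-rate schedules the
training protocol prescribes.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


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

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
            if node._backward is not None:
                node._backward(node.grad)

    # -- ops ---------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * np.power(self.data, p - 1.0))

        return Tensor._make(np.power(self.data, p), (self,), bw)

    def matmul(self, other: "Tensor"):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._make(np.maximum(self.data, 0.0), (self,), bw)

    def exp(self):
        out_data = np.exp(np.clip(self.data, -700, 700))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def sqrt(x: Tensor) -> Tensor:
    return x.pow(0.5)


# -- parameters and layers ---------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Module:
    """Minimal parameter container with nested-module discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[name] = v.data.copy()
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            out[f"{name}.{i}.{k}"] = arr
                    elif isinstance(item, Parameter):
                        out[f"{name}.{i}"] = item.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in state.items():
            obj = self
            parts = key.split(".")
            for part in parts[:-1]:
                obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
            leaf = parts[-1]
            target = obj[int(leaf)] if leaf.isdigit() else getattr(obj, leaf)
            target.data = np.array(arr, dtype=np.float64)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class BatchNorm1d(Module):
    """Batch normalization with running statistics (momentum 0.1).

    Batch statistics are used while ``training`` is True; the frozen running
    statistics are used at evaluation, making repeated eval calls bit-identical.
    """

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * x.data.mean(axis=0)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            xhat = centered / sqrt(var + self.eps)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    def state_dict(self):
        out = super().state_dict()
        out["running_mean"] = self.running_mean.copy()
        out["running_var"] = self.running_var.copy()
        return out

    def load_state_dict(self, state):
        self.running_mean = np.array(state.pop("running_mean"))
        self.running_var = np.array(state.pop("running_var"))
        super().load_state_dict(state)


class MLP(Module):
    """Fully connected stack with ReLU between layers (linear final layer)."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 final_relu: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.final_relu = final_relu

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_relu:
                x = x.relu()
        return x


# -- optimization ------------------------------------------------------------

class Adam:
    """Adam / AdamW (decoupled weight decay) for Parameter lists."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def inverse_time_lr(lr0: float, decay_rate: float, epoch: int) -> float:
    """lr0 / (1 + decay_rate * epoch) — the fusion-model schedule."""
    return lr0 / (1.0 + decay_rate * epoch)


def warmup_cosine_lr(peak: float, warmup: int, total: int, epoch: int) -> float:
    """Linear warm-up from 0 over ``warmup`` epochs to ``peak``, then cosine decay to 0."""
    if epoch < warmup:
        return peak * (epoch + 1) / warmup
    frac = (epoch - warmup) / max(total - warmup, 1)
    return peak * 0.5 * (1.0 + math.cos(math.pi * min(frac, 1.0)))
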