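"""Minimal reverse-mode autodiff on numpy arrays, with the few layers the
pipeline needs (linear, conv, pooling, norms, dropout) and an Adam optimizer.

All arithmetic is float64 and single-threaded numpy, so a fixed seed gives
bit-identical training trajectories across runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(g, self.data.shape)

    def backward(self, grad=None):
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._result(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._result(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._result(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._result(self.data @ other.data, (self, other), bwd)

    # -- elementwise ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._result(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._result(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), bwd)

    # -- reductions / shape ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._result(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        return Tensor._result(self.data[idx], (self,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(np.concatenate(datas, axis=axis), tensors, bwd)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)  # detached shift for stability
    s = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        s = s.reshape(tuple(d for i, d in enumerate(s.shape) if i != (axis % x.ndim)))
    return s


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x - np.max(x.data, axis=axis, keepdims=True)
    e = z.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under `logits` (N, K)."""
    n = logits.shape[0]
    lse = logsumexp(logits, axis=-1)
    picked = logits[np.arange(n), np.asarray(labels, dtype=int)]
    return (lse - picked).mean()


# -- structured ops ------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout; `w` is (out_ch, in_ch, kh, kw)."""
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True) + b.data[None, :, None, None]
    n, _, ho, wo = out.shape

    def bwd(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                    )
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return Tensor._result(out, (x, w, b), bwd)


def max_pool2d(x: Tensor, k: int = 2, stride: int | None = None) -> Tensor:
    stride = stride or k
    win = sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        ni, ci, hi, wi = np.meshgrid(
            np.arange(n), np.arange(c), np.arange(ho), np.arange(wo), indexing="ij"
        )
        rows = hi * stride + idx // k
        cols = wi * stride + idx % k
        np.add.at(gx, (ni, ci, rows, cols), g)
        x._accum(gx)

    return Tensor._result(out, (x,), bwd)


# -- modules -------------------------------------------------------------


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        out.extend(m.parameters())
        return out

    def _named(self, prefix="") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                out[prefix + k] = v.data
            elif isinstance(v, Module):
                out.update(v._named(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        out.update(m._named(f"{prefix}{k}.{i}."))
            elif isinstance(v, np.ndarray):  # running stats
                out[prefix + k] = v
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        refs = self._named_refs()
        for k, v in state.items():
            holder, attr_or_idx = refs[k]
            tgt = getattr(holder, attr_or_idx) if isinstance(attr_or_idx, str) else None
            if isinstance(tgt, Tensor):
                tgt.data = np.array(v, dtype=np.float64)
            else:
                setattr(holder, attr_or_idx, np.array(v))

    def _named_refs(self, prefix=""):
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (Tensor, np.ndarray)):
                out[prefix + k] = (self, k)
            elif isinstance(v, Module):
                out.update(v._named_refs(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        out.update(m._named_refs(f"{prefix}{k}.{i}."))
        return out

    def train(self):
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        m.train()
        return self

    def eval(self):
        self.train()
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        m.eval()
        return self


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.w = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        super().__init__()
        fan_in = c_in * k * k
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xn = (x - mu) * (var + self.eps) ** (-0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** (-0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
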