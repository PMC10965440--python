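"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the neural substrate for the volumetric models in this package: a
tape-based :class:`Tensor`, the ops needed for 3D convolutional nets and
encoder-decoder transformers (conv3d/conv2d, matmul, softmax, layer-norm
building blocks, embeddings), a small ``Module`` hierarchy and an Adam
optimizer.  Everything is plain numpy; dtypes follow the inputs, so graphs
can be run in float32 (training) or float64 (gradient checks).
"""

from __future__ import annotations

import json
import zipfile
import io
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv3d",
    "Conv2d",
    "LayerNorm",
    "Embedding",
    "Adam",
    "concat",
    "softmax",
    "log_softmax",
]


def _as_array(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    elif a.dtype == np.float64 or a.dtype == np.float32:
        pass
    else:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient tape bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = _as_array(data, dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        t = Tensor.__new__(Tensor)
        t.data = data
        t.grad = None
        t.requires_grad = req
        t._backward = backward if req else None
        t._parents = tuple(p for p in parents if p.requires_grad) if req else ()
        return t

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort (graphs can be deep)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- elementwise / arithmetic --------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        o = self._coerce(other)
        out_data = self.data + o.data
        def bw(g):
            return [(self, _unbroadcast(g, self.data.shape)), (o, _unbroadcast(g, o.data.shape))]
        return Tensor._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        out_data = self.data * o.data
        def bw(g):
            return [(self, _unbroadcast(g * o.data, self.data.shape)),
                    (o, _unbroadcast(g * self.data, o.data.shape))]
        return Tensor._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        out_data = self.data / o.data
        def bw(g):
            return [(self, _unbroadcast(g / o.data, self.data.shape)),
                    (o, _unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))]
        return Tensor._make(out_data, (self, o), bw)

    def __pow__(self, p: float):
        out_data = self.data ** p
        def bw(g):
            return [(self, g * p * self.data ** (p - 1))]
        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: [(self, g * out_data)])

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: [(self, g / self.data)])

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: [(self, g * (1.0 - out_data ** 2))])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: [(self, g * mask)])

    def softplus(self):
        # numerically stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        x = self.data
        out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-x))
        return Tensor._make(out_data, (self,), lambda g: [(self, g * sig)])

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: [(self, g * out_data * (1 - out_data))])

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape
        def bw(g):
            if axis is None:
                return [(self, np.broadcast_to(g, shape).copy() if np.ndim(g) else np.full(shape, g, dtype=self.data.dtype))]
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(a % len(shape) for a in ax)
            if not keepdims:
                for a in sorted(ax):
                    g = np.expand_dims(g, a)
            return [(self, np.broadcast_to(g, shape).copy())]
        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: [(self, g.reshape(old))])

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: [(self, g.transpose(inv))])

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape
        def bw(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            return [(self, full)]
        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        o = self._coerce(other)
        out_data = self.data @ o.data
        def bw(g):
            ga = g @ np.swapaxes(o.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return [(self, _unbroadcast(ga, self.data.shape)),
                    (o, _unbroadcast(gb, o.data.shape))]
        return Tensor._make(out_data, (self, o), bw)


# ---------------------------------------------------------------------------
# free functions


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        out = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            out.append((t, g[tuple(sl)]))
        return out
    return Tensor._make(out_data, tuple(tensors), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    s = e / e.sum(axis=axis, keepdims=True)
    def bw(g):
        return [(t, s * (g - (g * s).sum(axis=axis, keepdims=True)))]
    return Tensor._make(s, (t,), bw)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data - t.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    out = x - lse
    s = np.exp(out)
    def bw(g):
        return [(t, g - s * g.sum(axis=axis, keepdims=True))]
    return Tensor._make(out, (t,), bw)


def _conv_nd(x: Tensor, w: Tensor, b: Tensor | None, stride, pad, nd: int) -> Tensor:
    """Shared N-D convolution (nd=2 or 3), channels-last, loop over kernel taps."""
    stride = tuple(stride)
    pad = tuple(pad)
    pads = ((0, 0),) + tuple((p, p) for p in pad) + ((0, 0),)
    xp = np.pad(x.data, pads)
    ksp = w.data.shape[:nd]
    cin, cout = w.data.shape[nd], w.data.shape[nd + 1]
    sp_in = xp.shape[1:1 + nd]
    out_sp = tuple((sp_in[i] - ksp[i]) // stride[i] + 1 for i in range(nd))
    if any(o <= 0 for o in out_sp):
        raise ValueError(f"input spatial shape {x.data.shape[1:1+nd]} too small for "
                         f"kernel {ksp} with stride {stride} and padding {pad}")
    B = xp.shape[0]
    out = np.zeros((B,) + out_sp + (cout,), dtype=x.data.dtype)
    flat = int(np.prod(out_sp))
    taps = list(np.ndindex(*ksp))
    slabs = {}
    for tap in taps:
        sl = (slice(None),) + tuple(
            slice(tap[i], tap[i] + out_sp[i] * stride[i], stride[i]) for i in range(nd)
        ) + (slice(None),)
        xs = np.ascontiguousarray(xp[sl]).reshape(B * flat, cin)
        slabs[tap] = (sl, xs)
        out += (xs @ w.data[tap]).reshape((B,) + out_sp + (cout,))
    if b is not None:
        out = out + b.data
    def bw(g):
        gflat = g.reshape(B * flat, cout)
        dw = np.zeros_like(w.data)
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        for tap in taps:
            sl, xs = slabs[tap]
            dw[tap] = xs.T @ gflat
            if need_dx:
                dxp[sl] += (gflat @ w.data[tap].T).reshape((B,) + out_sp + (cin,))
        grads = [(w, dw)]
        if need_dx:
            unpad = (slice(None),) + tuple(
                slice(p, dxp.shape[1 + i] - p) for i, p in enumerate(pad)
            ) + (slice(None),)
            grads.append((x, dxp[unpad]))
        if b is not None:
            grads.append((b, g.sum(axis=tuple(range(g.ndim - 1)))))
        return grads
    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1, 1), pad=(0, 0, 0)) -> Tensor:
    """x: (B, D, H, W, Cin); w: (kd, kh, kw, Cin, Cout)."""
    return _conv_nd(x, w, b, stride, pad, 3)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), pad=(0, 0)) -> Tensor:
    """x: (B, H, W, Cin); w: (kh, kw, Cin, Cout)."""
    return _conv_nd(x, w, b, stride, pad, 2)


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of a (B, D, H, W, C) tensor."""
    f = int(factor)
    d = x.data
    out = d.repeat(f, axis=1).repeat(f, axis=2).repeat(f, axis=3)
    B, D, H, W, C = d.shape
    def bw(g):
        gg = g.reshape(B, D, f, H, f, W, f, C).sum(axis=(2, 4, 6))
        return [(x, gg)]
    return Tensor._make(out, (x,), bw)


def embedding_lookup(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = weight.data[idx]
    def bw(g):
        dw = np.zeros_like(weight.data)
        np.add.at(dw, idx.reshape(-1), g.reshape(-1, weight.data.shape[1]))
        return [(weight, dw)]
    return Tensor._make(out, (weight,), bw)


# ---------------------------------------------------------------------------
# modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with named parameters and submodules (torch-like, minimal)."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
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

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # checkpointing: JSON descriptor + npz weights in one zip archive
    def save(self, path, descriptor: dict | None = None) -> None:
        buf = io.BytesIO()
        np.savez(buf, **{k: p.data for k, p in self.named_parameters()})
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("architecture.json", json.dumps(descriptor or {}, indent=2))
            zf.writestr("weights.npz", buf.getvalue())

    def load_weights(self, path) -> dict:
        with zipfile.ZipFile(path) as zf:
            desc = json.loads(zf.read("architecture.json"))
            arrs = np.load(io.BytesIO(zf.read("weights.npz")))
            params = dict(self.named_parameters())
            for k in arrs.files:
                params[k].data = arrs[k].astype(params[k].data.dtype)
        return desc


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype=np.float32):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = Parameter(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride=(1, 1, 1), pad=None):
        fan_in = k ** 3 * cin
        self.w = Parameter(_glorot(rng, (k, k, k, cin, cout), fan_in, cout))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.stride = tuple(stride) if hasattr(stride, "__len__") else (stride,) * 3
        self.pad = tuple(pad) if pad is not None else ((k - 1) // 2,) * 3

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride=(1, 1), pad=None):
        fan_in = k ** 2 * cin
        self.w = Parameter(_glorot(rng, (k, k, cin, cout), fan_in, cout))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.stride = tuple(stride) if hasattr(stride, "__len__") else (stride,) * 2
        self.pad = tuple(pad) if pad is not None else ((k - 1) // 2,) * 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.w = Parameter((rng.standard_normal((n_tokens, dim)) * 0.02).astype(np.float32))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding_lookup(self.w, idx)


class Adam:
    """Adam with optional gradient clipping; state keyed by parameter identity."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip = clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.clip is not None:
                norm = np.sqrt((g ** 2).sum())
                if norm > self.clip:
                    g = g * (self.clip / norm)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
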