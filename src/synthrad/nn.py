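"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the modality-translation networks need:
2D convolution (arbitrary stride, zero padding), instance normalization,
nearest-neighbour upsampling, channel concatenation, matrix products,
pointwise nonlinearities, and reductions.  Gradients are validated against
central finite differences in the test suite.

Layout convention: activation tensors are ``(N, C, H, W)``; convolution
weights are ``(C_out, C_in, k, k)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "InstanceNorm2d", "Linear",
    "Adam", "concat", "upsample_nearest2x", "conv2d", "instance_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # parents: sequence of (Tensor, vjp) pairs
        self._parents = tuple(parents)

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents) -> "Tensor":
        parents = tuple((p, fn) for p, fn in parents if p.requires_grad or p._parents)
        return Tensor(data, requires_grad=bool(parents), parents=parents)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for p, vjp in node._parents:
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(self.data + other.data, [
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(self.data * other.data, [
            (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
        ])

    __rmul__ = __mul__

    def square(self):
        return Tensor._make(self.data ** 2, [(self, lambda g: g * 2.0 * self.data)])

    def abs(self):
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * np.sign(self.data))])

    def mean(self):
        n = self.data.size
        return Tensor._make(self.data.mean(), [
            (self, lambda g: np.full_like(self.data, 1.0 / n) * g)])

    def sum_axes(self, axes: tuple[int, ...], keepdims: bool = True):
        out = self.data.sum(axis=axes, keepdims=keepdims)

        def vjp(g):
            if not keepdims:
                g = np.expand_dims(g, axes)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._make(out, [(self, vjp)])

    def mean_axes(self, axes: tuple[int, ...], keepdims: bool = True):
        n = np.prod([self.data.shape[a] for a in axes])
        return self.sum_axes(axes, keepdims) * (1.0 / float(n))

    def reshape(self, shape):
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape),
                            [(self, lambda g: g.reshape(old))])

    def matmul(self, other: "Tensor"):
        a, b = self.data, other.data
        return Tensor._make(a @ b, [
            (self, lambda g: g @ b.T),
            (other, lambda g: a.T @ g),
        ])

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        m = self.data > 0
        return Tensor._make(self.data * m, [(self, lambda g: g * m)])

    def leaky_relu(self, alpha: float = 0.2):
        dt = self.data.dtype
        m = np.where(self.data > 0, np.asarray(1.0, dt), np.asarray(alpha, dt))
        return Tensor._make(self.data * m, [(self, lambda g: g * m)])

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._make(y, [(self, lambda g: g * (1.0 - y * y))])

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(y, [(self, lambda g: g * y * (1.0 - y))])

    @property
    def shape(self):
        return self.data.shape


# ----------------------------------------------------------------------
# structural ops

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        def vjp(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]
        parents.append((t, vjp))
    return Tensor._make(data, parents)


def upsample_nearest2x(x: Tensor) -> Tensor:
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def vjp(g):
        n, c, h, w = x.data.shape
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    return Tensor._make(data, [(x, vjp)])


def _pad_hw(a: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return a
    return np.pad(a, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, kh: int, kw: int, ho: int, wo: int, stride: int) -> np.ndarray:
    """Patch matrix of shape (n, cin*kh*kw, ho*wo)."""
    n, cin = xp.shape[:2]
    cols = np.empty((n, cin, kh, kw, ho, wo), dtype=xp.dtype)
    for di in range(kh):
        for dj in range(kw):
            cols[:, :, di, dj] = xp[:, :, di:di + stride * ho:stride,
                                    dj:dj + stride * wo:stride]
    return cols.reshape(n, cin * kh * kw, ho * wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation with zero padding (im2col + GEMM)."""
    xd, wd = x.data, w.data
    n, cin, h, wid = xd.shape
    cout, cin_w, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_w}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wid + 2 * padding - kw) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"conv output empty for input {xd.shape} kernel {wd.shape}")
    xp = _pad_hw(xd, padding)
    cols = _im2col(xp, kh, kw, ho, wo, stride)
    wmat = wd.reshape(cout, cin * kh * kw)
    out = (wmat @ cols).reshape(n, cout, ho, wo)
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    def vjp_x(g):
        gm = g.reshape(n, cout, ho * wo)
        gcols = np.matmul(wmat.T[None], gm)  # (n, cin*kh*kw, ho*wo)
        gcols = gcols.reshape(n, cin, kh, kw, ho, wo)
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                gxp[:, :, di:di + stride * ho:stride,
                    dj:dj + stride * wo:stride] += gcols[:, :, di, dj]
        if padding:
            return gxp[:, :, padding:-padding, padding:-padding]
        return gxp

    def vjp_w(g):
        gm = g.reshape(n, cout, ho * wo).transpose(1, 0, 2).reshape(cout, n * ho * wo)
        cm = cols.transpose(1, 0, 2).reshape(cin * kh * kw, n * ho * wo)
        return (gm @ cm.T).reshape(wd.shape)

    parents = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor._make(out, parents)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    xd = x.data
    mu = xd.mean(axis=(2, 3), keepdims=True)
    var = xd.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    gd = gamma.data.reshape(1, -1, 1, 1)
    out = xhat * gd + beta.data.reshape(1, -1, 1, 1)
    m = xd.shape[2] * xd.shape[3]

    def vjp_x(g):
        gh = g * gd
        return (inv / m) * (m * gh - gh.sum(axis=(2, 3), keepdims=True)
                            - xhat * (gh * xhat).sum(axis=(2, 3), keepdims=True))

    return Tensor._make(out, [
        (x, vjp_x),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    ])


# ----------------------------------------------------------------------
# modules

class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Parameter container with recursive discovery (names are stable and
    used for checkpoints)."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


DTYPE = np.float32  # network parameter/activation dtype; ops preserve input dtype


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = Parameter(rng.normal(0.0, init_std, (cout, cin, k, k)).astype(DTYPE))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {f"{prefix}weight": self.weight}
        if self.bias is not None:
            out[f"{prefix}bias"] = self.bias
        return out


class InstanceNorm2d(Module):
    def __init__(self, c: int):
        self.gamma = Parameter(np.ones(c, dtype=DTYPE))
        self.beta = Parameter(np.zeros(c, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = 1.0 / np.sqrt(cin)
        self.weight = Parameter(rng.uniform(-std, std, (cin, cout)).astype(DTYPE))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Adam:
    """Adam with an optional per-step learning-rate schedule."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8,
                 lr_schedule=None):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.lr_schedule = lr_schedule
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        lr = self.lr if self.lr_schedule is None else self.lr * self.lr_schedule(self.t)
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
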