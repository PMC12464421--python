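"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's neural components (multidimensional collaborative attention,
the lightweight detection network) are small enough to train on a CPU, so
they run on this self-contained engine rather than a full deep-learning
framework.  Tensors wrap float64 numpy arrays and record a backward closure;
``backward()`` walks the tape in reverse topological order.

Only the operations the package actually uses are implemented.  Convolutions
use a shift-and-accumulate scheme (one einsum per kernel offset) which is
fast for the small kernels (1/3/5 px) and feature maps (<= 160 px) used here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "exp",
    "log",
    "sqrt",
    "absolute",
    "maximum",
    "minimum",
    "clamp",
    "sigmoid",
    "hswish",
    "relu",
    "softmax",
    "conv2d",
    "conv1d_circularless",
    "maxpool2d",
    "avgpool2d",
    "upsample_nearest2d",
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray meets a Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autodiff plumbing ---------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __truediv__(self, other):
        other = tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def std(self, axis=None, keepdims: bool = False, eps: float = 1e-12):
        mu = self.mean(axis=axis, keepdims=True)
        var = ((self - mu) ** 2).mean(axis=axis, keepdims=keepdims)
        return sqrt(var + eps)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bwd
        return out

    def permute(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor"):
        other = tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# -- elementwise functions (dispatch on Tensor vs ndarray) ----------------

def exp(x):
    if not _is_t(x):
        return np.exp(x)
    x = tensor(x)
    out = Tensor(np.exp(x.data), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * out.data)

    out._backward = bwd
    return out


def log(x):
    if not _is_t(x):
        return np.log(x)
    x = tensor(x)
    out = Tensor(np.log(x.data), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g / x.data)

    out._backward = bwd
    return out


def sqrt(x):
    if not _is_t(x):
        return np.sqrt(x)
    return tensor(x) ** 0.5


def absolute(x):
    if not _is_t(x):
        return np.abs(x)
    x = tensor(x)
    out = Tensor(np.abs(x.data), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * np.sign(x.data))

    out._backward = bwd
    return out


def maximum(a, b):
    if not _is_t(a, b):
        return np.maximum(a, b)
    a, b = tensor(a), tensor(b)
    out = Tensor(np.maximum(a.data, b.data),
                 a.requires_grad or b.requires_grad, (a, b))
    amax = a.data >= b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * amax, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~amax), b.shape))

    out._backward = bwd
    return out


def minimum(a, b):
    if not _is_t(a, b):
        return np.minimum(a, b)
    a, b = tensor(a), tensor(b)
    out = Tensor(np.minimum(a.data, b.data),
                 a.requires_grad or b.requires_grad, (a, b))
    amin = a.data <= b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * amin, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~amin), b.shape))

    out._backward = bwd
    return out


def clamp(x, lo, hi):
    if not _is_t(x):
        return np.clip(x, lo, hi)
    x = tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), x.requires_grad, (x,))
    mask = (x.data >= lo) & (x.data <= hi)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = bwd
    return out


def sigmoid(x):
    if not _is_t(x):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))
    x = tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def hswish(x):
    """H-Swish activation: x * clip(x + 3, 0, 6) / 6."""
    if not _is_t(x):
        x = np.asarray(x, dtype=np.float64)
        return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0
    return tensor(x) * clamp(tensor(x) + 3.0, 0.0, 6.0) * (1.0 / 6.0)


def relu(x):
    return maximum(x, 0.0 if not _is_t(x) else Tensor(np.zeros(1)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = tensor(x) - np.max(tensor(x).data, axis=axis, keepdims=True)
    e = exp(shift)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


# -- spatial ops (NCHW) ---------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, grouped.

    Implemented as a sum over kernel offsets: for each (i, j) a strided slice
    of the padded input is contracted with w[..., i, j].  This keeps both the
    forward and backward passes as a handful of einsums, which is efficient
    for the small kernels used throughout the package.
    """
    x, w = tensor(x), tensor(w)
    n, cin, h, wd = x.shape
    cout, cin_g, kh, kw = w.shape
    if cin % groups or cout % groups or cin // groups != cin_g:
        raise ValueError("channel counts incompatible with groups")
    s, p = stride, padding
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    xg = xp.reshape(n, groups, cin_g, xp.shape[2], xp.shape[3])
    wg = w.data.reshape(groups, cout // groups, cin_g, kh, kw)
    out_data = np.zeros((n, groups, cout // groups, ho, wo))
    for i in range(kh):
        for j in range(kw):
            xs = xg[:, :, :, i:i + s * ho:s, j:j + s * wo:s]
            out_data += np.einsum("ngchw,goc->ngohw", xs, wg[:, :, :, i, j],
                                  optimize=True)
    out_data = out_data.reshape(n, cout, ho, wo)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        b = tensor(b)
        out_data = out_data + b.data.reshape(1, cout, 1, 1)
        parents = (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in parents), parents)

    def bwd(g):
        gg = g.reshape(n, groups, cout // groups, ho, wo)
        if w.requires_grad:
            dw = np.zeros_like(wg)
            for i in range(kh):
                for j in range(kw):
                    xs = xg[:, :, :, i:i + s * ho:s, j:j + s * wo:s]
                    dw[:, :, :, i, j] = np.einsum("ngchw,ngohw->goc", xs, gg,
                                                  optimize=True)
            w._accum(dw.reshape(w.shape))
        if x.requires_grad:
            dxp = np.zeros((n, groups, cin_g, xp.shape[2], xp.shape[3]))
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                        "ngohw,goc->ngchw", gg, wg[:, :, :, i, j], optimize=True)
            dxp = dxp.reshape(n, cin, xp.shape[2], xp.shape[3])
            if p:
                dxp = dxp[:, :, p:-p, p:-p]
            x._accum(dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def conv1d_circularless(x: Tensor, w: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution over the last axis of a (N, L) tensor with a shared
    kernel of odd width, zero-padded ("same" when padding = k // 2)."""
    x, w = tensor(x), tensor(w)
    x4 = x.reshape(x.shape[0], 1, 1, x.shape[1])
    w4 = w.reshape(1, 1, 1, w.shape[0])
    out = conv2d(x4, w4, padding=0, stride=1) if padding == 0 else None
    if padding:
        n, l = x.shape
        xp = concat([Tensor(np.zeros((n, padding))), x,
                     Tensor(np.zeros((n, padding)))], axis=1)
        x4 = xp.reshape(n, 1, 1, l + 2 * padding)
        out = conv2d(x4, w4)
    return out.reshape(out.shape[0], out.shape[3])


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    x = tensor(x)
    s = stride or kernel
    n, c, h, w = x.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding)), constant_values=-np.inf)
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // s + 1
    wo = (wp - kernel) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel),
                                                   axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((n, c, hp, wp))
        ni, ci, hi, wi = np.indices((n, c, ho, wo))
        rows = hi * s + idx // kernel
        cols = wi * s + idx % kernel
        np.add.at(dxp, (ni, ci, rows, cols), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    out._backward = bwd
    return out


def avgpool2d(x: Tensor, kernel: int | None = None) -> Tensor:
    """Global average pool when kernel is None."""
    x = tensor(x)
    if kernel is None:
        return x.mean(axis=(2, 3), keepdims=True)
    raise NotImplementedError("only global average pooling is used")


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    x = tensor(x)
    n, c, h, w = x.shape
    out = Tensor(x.data.repeat(factor, axis=2).repeat(factor, axis=3),
                 x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    out._backward = bwd
    return out


# -- modules ---------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: recursive parameter discovery, train/eval flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    out[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    out[f"{i}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in list(m.__dict__.items()):
                key = f"{i}.{k}"
                if key in state:
                    if isinstance(v, Parameter):
                        v.data[...] = state[key]
                    elif isinstance(v, np.ndarray):
                        m.__dict__[k] = state[key].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, groups=1,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * kernel * kernel
        bound = np.sqrt(2.0 / fan_in)  # He init for the piecewise-linear mix
        self.weight = Parameter(rng.normal(0.0, bound,
                                           (cout, cin // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            mu_t = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu_t
            var_t = (xc ** 2).mean(axis=(0, 2, 3), keepdims=True)
            xhat = xc / sqrt(var_t + self.eps)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - mu) / Tensor(sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class SGD:
    """SGD with momentum and decoupled weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=5e-4):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total: int, lr0: float = 0.01,
              lr1: float = 1e-5) -> float:
    """Cosine decay schedule from lr0 to lr1 over ``total`` steps."""
    if total <= 1:
        return lr1
    t = min(step, total - 1) / (total - 1)
    return lr1 + 0.5 * (lr0 - lr1) * (1.0 + np.cos(np.pi * t))
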