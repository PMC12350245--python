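"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network, the objective terms and the training loop are all
expressed in terms of :class:`Tensor` operations defined here.  The engine is
deliberately small: dense arrays only, a static tape built eagerly, and just
the operations the package needs (broadcast arithmetic, batched ``matmul``,
``conv2d`` via im2col, reductions, elementwise nonlinearities, shape ops).

Gradients follow the usual conventions: broadcasting in the forward pass is
undone by summation in the backward pass, and every op validates against a
central-difference check in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "sigmoid",
    "relu",
    "leaky_relu",
    "tanh",
    "exp",
    "log",
    "clip",
    "softmax",
    "log_softmax",
    "conv2d",
    "concat",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "__weakref__")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self._accumulate(np.broadcast_to(grad, self.data.shape))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(np.add(self.data, other.data), (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                gb = np.tensordot(g, a, axes=(range(g.ndim), range(a.ndim - 1)))
            elif a.ndim == 1:
                ga = np.matmul(g[..., None, :], np.swapaxes(b, -1, -2))[..., 0, :]
                ga = _unbroadcast(ga, a.shape)
                gb = np.multiply.outer(a, g) if g.ndim == 1 else np.matmul(
                    a[:, None], g[..., None, :]
                )
                gb = _unbroadcast(gb, b.shape)
            else:
                ga = _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape)
                gb = _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape)
            self._accumulate(ga)
            other._accumulate(gb)

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accumulate(np.broadcast_to(g, self.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'None'})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = True
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ------------------------------------------------

def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = _make(np.exp(t.data), (t,))
    val = out.data  # capture the array, not the tensor: keeps the graph acyclic
    out._backward = lambda g: t._accumulate(g * val)
    return out


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = _make(np.log(t.data), (t,))
    out._backward = lambda g: t._accumulate(g / t.data)
    return out


def tanh(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = _make(np.tanh(t.data), (t,))
    val = out.data
    out._backward = lambda g: t._accumulate(g * (1.0 - val**2))
    return out


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    s = 1.0 / (1.0 + np.exp(-t.data))
    out = _make(s, (t,))
    out._backward = lambda g: t._accumulate(g * s * (1.0 - s))
    return out


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = _make(np.maximum(t.data, 0.0), (t,))
    out._backward = lambda g: t._accumulate(g * (t.data > 0))
    return out


def leaky_relu(t: Tensor, alpha: float = 0.01) -> Tensor:
    t = as_tensor(t)
    out = _make(np.where(t.data > 0, t.data, alpha * t.data), (t,))
    out._backward = lambda g: t._accumulate(g * np.where(t.data > 0, 1.0, alpha))
    return out


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient passes only where no clamping occurred."""
    t = as_tensor(t)
    out = _make(np.clip(t.data, lo, hi), (t,))
    inside = (t.data > lo) & (t.data < hi)
    out._backward = lambda g: t._accumulate(g * inside)
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - np.max(t.data, axis=axis, keepdims=True)  # detached shift
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - np.max(t.data, axis=axis, keepdims=True)
    return shifted - log(exp(shifted).sum(axis=axis, keepdims=True))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


# -- 2-D convolution -----------------------------------------------------------

def _conv_geometry(h: int, w: int, kh: int, kw: int, stride: int):
    ho = -(-h // stride)  # ceil division: 'same' padding
    wo = -(-w // stride)
    ph = max((ho - 1) * stride + kh - h, 0)
    pw = max((wo - 1) * stride + kw - w, 0)
    return ho, wo, (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)


def conv2d(x: Tensor, weight: Tensor, stride: int = 1) -> Tensor:
    """'same'-padded 2-D convolution (cross-correlation).

    ``x``: (N, H, W, Cin); ``weight``: (kh, kw, Cin, Cout); output
    (N, ceil(H/s), ceil(W/s), Cout).  Bias is applied by the caller with a
    broadcast add so its gradient comes for free.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, h, w, cin = x.shape
    kh, kw, cin_w, cout = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    ho, wo, (pt, pb), (pl, pr) = _conv_geometry(h, w, kh, kw, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    ii = (np.arange(ho) * stride)[:, None] + np.arange(kh)[None, :]  # (ho, kh)
    jj = (np.arange(wo) * stride)[:, None] + np.arange(kw)[None, :]  # (wo, kw)
    patches = xp[:, ii[:, None, :, None], jj[None, :, None, :], :]  # (n,ho,wo,kh,kw,cin)
    cols = patches.reshape(n, ho, wo, kh * kw * cin)
    wmat = weight.data.reshape(kh * kw * cin, cout)
    out = _make(cols @ wmat, (x, weight))

    def bw(g):
        gcols = g @ wmat.T  # (n, ho, wo, kh*kw*cin)
        weight._accumulate(
            np.tensordot(cols, g, axes=([0, 1, 2], [0, 1, 2])).reshape(weight.shape)
        )
        gxp = np.zeros_like(xp)
        np.add.at(
            gxp,
            (slice(None), ii[:, None, :, None], jj[None, :, None, :], slice(None)),
            gcols.reshape(n, ho, wo, kh, kw, cin),
        )
        x._accumulate(gxp[:, pt : pt + h, pl : pl + w, :])

    out._backward = bw
    return out


# -- optimizer -----------------------------------------------------------------

class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
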