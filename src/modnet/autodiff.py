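"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Just the operations the differentiable plastic readout and the convolutional
embedding need: broadcasting arithmetic, (batched) matmul, sigmoid/relu/softmax,
reductions, 3x3 same-padding convolution via im2col, 2x2 max pooling, and
non-affine batch normalization.  Gradients flow through arbitrarily deep
compositions (e.g. a trace recursion unrolled over the support presentations of
an episode), and are validated against finite differences in the test suite.

Arrays keep their dtype: float64 for gradient checks, float32 for training
throughput.
"""

from __future__ import annotations

import ctypes

import numpy as np

_fast_alloc_done = False


def enable_fast_alloc() -> bool:
    """Keep large allocations on the heap instead of fresh mmaps.

    Reverse-mode training allocates and frees many multi-megabyte temporaries
    per step; with glibc's default mmap threshold every one of them pays page
    faults on first touch.  Raising the threshold (and the trim threshold, so
    freed blocks are retained) speeds the unrolled episode loop up severalfold.
    No-op on non-glibc platforms.  Returns whether tuning was applied.
    """
    global _fast_alloc_done
    if _fast_alloc_done:
        return True
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)   # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)   # M_TRIM_THRESHOLD
        _fast_alloc_done = True
    except OSError:
        return False
    return True


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
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
    """A node in the computation graph wrapping a NumPy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = _backward
        self._prev = _prev

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        # gradients are never mutated in place, so storing a view is safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node (defaults to d(self)/d(self) = 1;
        the node must be scalar in that case)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("divide by a Tensor via t * other**-1")
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, dtype=np.float64) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True)


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with NumPy's stacked-batch semantics and full
    broadcasting support in the backward pass."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))
    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    d = x.data
    y = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                 np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    y = y.astype(d.dtype)
    out = Tensor(y, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * y * (1 - y))
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.exp(x.data)
    out = Tensor(y, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * y)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g / x.data)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))
    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    y = shifted - lse
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))
    out._backward = bw
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``
    of shape (N, C)."""
    n, c = logits.shape
    onehot = np.zeros((n, c), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -(log_softmax(logits) * onehot).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# Convolutional ops
# ---------------------------------------------------------------------------

_OFFSETS3 = [(di, dj) for di in range(3) for dj in range(3)]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """3x3 convolution, stride 1, same (zero) padding, channels-last layout.

    ``x`` is (N, H, W, C) and ``weight`` is (3, 3, C, F); the result is
    (N, H, W, F).  Channels-last keeps every array contiguous through the
    im2col matmul, which is what makes the unrolled episode training loop
    fast on one core.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, H, W, C = x.shape
    F = weight.shape[-1]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((N, H, W, 9, C), dtype=x.data.dtype)
    for k, (di, dj) in enumerate(_OFFSETS3):
        cols[:, :, :, k, :] = xp[:, di:di + H, dj:dj + W, :]
    wmat = weight.data.reshape(9 * C, F)
    y = cols.reshape(N * H * W, 9 * C) @ wmat
    if bias is not None:
        y += bias.data
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y.reshape(N, H, W, F), _prev=prev)

    def bw(g):
        gmat = g.reshape(N * H * W, F)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if weight.requires_grad:
            # (F, M) @ (M, 9C) runs noticeably faster than the transposed
            # product for these skinny shapes; transpose back afterwards
            gw = np.ascontiguousarray(
                (gmat.T @ cols.reshape(N * H * W, 9 * C)).T)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = (gmat @ wmat.T).reshape(N, H, W, 9, C)
            gxp = np.zeros_like(xp)
            for k, (di, dj) in enumerate(_OFFSETS3):
                gxp[:, di:di + H, dj:dj + W, :] += gcols[:, :, :, k, :]
            x._accumulate(gxp[:, 1:1 + H, 1:1 + W, :])
    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 on (N, H, W, C); odd trailing rows/columns
    are dropped."""
    x = as_tensor(x)
    N, H, W, C = x.shape
    Ho, Wo = H // 2, W // 2
    blocks = x.data[:, :2 * Ho, :2 * Wo, :].reshape(N, Ho, 2, Wo, 2, C)
    y = blocks.max(axis=(2, 4))
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        mask = blocks == y[:, :, None, :, None, :]
        # distribute evenly across ties so the gradient stays consistent
        counts = mask.sum(axis=(2, 4), keepdims=True)
        gx = np.zeros_like(x.data)
        gx[:, :2 * Ho, :2 * Wo, :] = (
            mask * (g[:, :, None, :, None, :] / counts)
        ).reshape(N, 2 * Ho, 2 * Wo, C)
        x._accumulate(gx)
    out._backward = bw
    return out


def batchnorm2d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization of (N, H, W, C) over (N, H, W), without
    learnable affine parameters; statistics always come from the current batch."""
    x = as_tensor(x)
    axes = (0, 1, 2)
    mu = x.data.mean(axis=axes, keepdims=True)
    x2d = x.data.reshape(-1, x.shape[-1])
    msq = np.einsum("mc,mc->c", x2d, x2d) / x2d.shape[0]
    var = np.maximum(msq.reshape(mu.shape) - mu * mu, 0.0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat, _prev=(x,))
    m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def bw(g):
        if not x.requires_grad:
            return
        gsum = g.sum(axis=axes, keepdims=True)
        gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
        x._accumulate(inv * (g - gsum / m - xhat * gx_sum / m))
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
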