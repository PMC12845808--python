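"""Minimal reverse-mode autodiff layer library on NumPy.

Supports exactly the operations the dual-stream stem and the toy detector
need: 2D/3D convolution (im2col), SiLU/sigmoid, softmax, elementwise
arithmetic with broadcasting, depth stacking, max reductions, pooling,
concatenation, and the detector losses, plus seeded He initialization and
an Adam optimizer.  Everything is float32 and fully deterministic given a
seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "stack",
    "concat",
    "max_along",
    "maxpool2d",
    "Conv2d",
    "Conv3d",
    "Adam",
    "bce_with_logits",
]

_DT = np.float32


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=_DT)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph walk ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._prev if id(p) not in seen and p.requires_grad]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                stack_.pop()
                if node.requires_grad:
                    topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DT, copy=True)
        else:
            self.grad += grad

    # -- elementwise ops ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    __radd__ = __add__
    __rmul__ = __mul__

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        out._backward = bw
        return out

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))

        out._backward = bw
        return out

    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        out._backward = bw
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g) / n))

        out._backward = bw
        return out

    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        out._backward = bw
        return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def stack(tensors: list[Tensor], axis: int) -> Tensor:
    """Stack tensors along a new axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(part, axis=axis))

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, part in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(part)

    out._backward = bw
    return out


def max_along(x: Tensor, axis: int) -> Tensor:
    """Max reduction along one axis (ties: gradient to the first maximizer)."""
    idx = np.argmax(x.data, axis=axis)
    out_data = np.max(x.data, axis=axis)
    out = Tensor(out_data, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.put_along_axis(
                gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            x._accum(gx)

    out._backward = bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k spatial max pooling on (B, C, H, W)."""
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError("spatial dims must be divisible by the pooling size")
    r = x.data.reshape(B, C, H // k, k, W // k, k)
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // k, W // k, k * k)
    idx = flat.argmax(axis=-1)
    out = Tensor(flat.max(axis=-1), _prev=(x,))

    def bw(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = (
                gflat.reshape(B, C, H // k, W // k, k, k)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, H, W)
            )
            x._accum(gx)

    out._backward = bw
    return out


# ---------------------------------------------------------------------
# convolution layers
# ---------------------------------------------------------------------


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DT)


class Conv2d:
    """2D convolution (cross-correlation) with square-free kernel support."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int | tuple[int, int],
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.cin, self.cout = cin, cout
        self.kh, self.kw = kh, kw
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_he_init(rng, (cout, cin, kh, kw), cin * kh * kw), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=_DT), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        s, p = self.stride, self.padding
        kh, kw = self.kh, self.kw
        Ho = (H + 2 * p - kh) // s + 1
        Wo = (W + 2 * p - kw) // s + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((B, C, kh * kw, Ho * Wo), dtype=_DT)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
                cols[:, :, i * kw + j, :] = patch.reshape(B, C, -1)
        cols2 = cols.reshape(B, C * kh * kw, Ho * Wo)
        w2 = self.w.data.reshape(self.cout, -1)
        y = np.einsum("ok,bkl->bol", w2, cols2, optimize=True) + self.b.data[None, :, None]
        out = Tensor(y.reshape(B, self.cout, Ho, Wo), _prev=(x, self.w, self.b))

        def bw(g):
            g2 = g.reshape(B, self.cout, Ho * Wo)
            if self.w.requires_grad:
                gw = np.einsum("bol,bkl->ok", g2, cols2, optimize=True)
                self.w._accum(gw.reshape(self.w.data.shape))
            if self.b.requires_grad:
                self.b._accum(g2.sum(axis=(0, 2)))
            if x.requires_grad:
                gcols = np.einsum("ok,bol->bkl", w2, g2, optimize=True)
                gcols = gcols.reshape(B, C, kh * kw, Ho * Wo)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gcols[
                            :, :, i * kw + j, :
                        ].reshape(B, C, Ho, Wo)
                x._accum(gxp[:, :, p : p + H, p : p + W])

        out._backward = bw
        return out


class Conv3d:
    """3D convolution over (depth, height, width) on (B, C, D, H, W)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        stride: tuple[int, int, int] = (1, 2, 2),
        padding: tuple[int, int, int] = (1, 1, 1),
        rng: np.random.Generator | None = None,
    ):
        self.cin, self.cout = cin, cout
        self.kd, self.kh, self.kw = kernel
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = cin * self.kd * self.kh * self.kw
        self.w = Tensor(
            _he_init(rng, (cout, cin, self.kd, self.kh, self.kw), fan_in), requires_grad=True
        )
        self.b = Tensor(np.zeros(cout, dtype=_DT), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.data.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        kd, kh, kw = self.kd, self.kh, self.kw
        Do = (D + 2 * pd - kd) // sd + 1
        Ho = (H + 2 * ph - kh) // sh + 1
        Wo = (W + 2 * pw - kw) // sw + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        K = kd * kh * kw
        L = Do * Ho * Wo
        cols = np.empty((B, C, K, L), dtype=_DT)
        for d in range(kd):
            for i in range(kh):
                for j in range(kw):
                    patch = xp[
                        :,
                        :,
                        d : d + sd * Do : sd,
                        i : i + sh * Ho : sh,
                        j : j + sw * Wo : sw,
                    ]
                    cols[:, :, d * kh * kw + i * kw + j, :] = patch.reshape(B, C, -1)
        cols2 = cols.reshape(B, C * K, L)
        w2 = self.w.data.reshape(self.cout, -1)
        y = np.einsum("ok,bkl->bol", w2, cols2, optimize=True) + self.b.data[None, :, None]
        out = Tensor(y.reshape(B, self.cout, Do, Ho, Wo), _prev=(x, self.w, self.b))

        def bw(g):
            g2 = g.reshape(B, self.cout, L)
            if self.w.requires_grad:
                gw = np.einsum("bol,bkl->ok", g2, cols2, optimize=True)
                self.w._accum(gw.reshape(self.w.data.shape))
            if self.b.requires_grad:
                self.b._accum(g2.sum(axis=(0, 2)))
            if x.requires_grad:
                gcols = np.einsum("ok,bol->bkl", w2, g2, optimize=True)
                gcols = gcols.reshape(B, C, K, L)
                gxp = np.zeros_like(xp)
                for d in range(kd):
                    for i in range(kh):
                        for j in range(kw):
                            gxp[
                                :,
                                :,
                                d : d + sd * Do : sd,
                                i : i + sh * Ho : sh,
                                j : j + sw * Wo : sw,
                            ] += gcols[:, :, d * kh * kw + i * kw + j, :].reshape(
                                B, C, Do, Ho, Wo
                            )
                x._accum(gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W])

        out._backward = bw
        return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy from logits (mean-reduced)."""
    z = logits.data
    t = np.asarray(targets, dtype=_DT)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=_DT)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor((w * loss).sum() / w.size, _prev=(logits,))
    sig = 1.0 / (1.0 + np.exp(-z))

    def bw(g):
        if logits.requires_grad:
            logits._accum(float(g) * w * (sig - t) / w.size)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
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
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DT)
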