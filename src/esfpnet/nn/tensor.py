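"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is a plain dynamic tape: every operation returns a new
:class:`Tensor` holding a closure that propagates the upstream gradient to
its parents.  Only the operations required by the segmentation model are
implemented (dense/conv linear algebra, the usual activations, layer/batch
normalisation, bilinear and nearest resampling, and a fused
binary-cross-entropy-with-logits).  All arithmetic is float32.

A global MAC counter can be armed with :func:`count_macs`; while active,
convolutions and matrix products record one multiply-accumulate per scalar
product, and elementwise/normalisation/resampling ops record their output
element counts per op type so callers can apply a per-element costing
convention.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import special as _special

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "count_macs",
    "MacCounter",
    "concat",
]

_grad_enabled = True
_mac_counter = None


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class MacCounter:
    """Accumulates multiply-accumulate counts during forward passes.

    Elementwise/normalisation/resampling operations are tracked separately
    (output element counts per op type) so callers can apply whatever
    per-element costing convention their comparison tool uses.
    """

    def __init__(self) -> None:
        self.total = 0
        self.elem_ops: dict[str, int] = {}

    @property
    def uncounted_ops(self) -> set[str]:
        return set(self.elem_ops)

    def add(self, macs: int) -> None:
        self.total += int(macs)

    def skip(self, op_name: str, n_elems: int = 0) -> None:
        self.elem_ops[op_name] = self.elem_ops.get(op_name, 0) + int(n_elems)


@contextmanager
def count_macs():
    """Arm a MAC counter for the duration of the block and yield it."""
    global _mac_counter
    prev = _mac_counter
    counter = MacCounter()
    _mac_counter = counter
    try:
        yield counter
    finally:
        _mac_counter = prev


def _record_macs(n: int) -> None:
    if _mac_counter is not None:
        _mac_counter.add(n)


def _record_skip(name: str, n_elems: int = 0) -> None:
    if _mac_counter is not None:
        _mac_counter.skip(name, n_elems)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- factories
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.shape))

        return Tensor._make(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accumulate(g * e * self.data ** (e - 1))

        return Tensor._make(self.data**e, (self,), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(np.float32))

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        elif isinstance(axis, int):
            n = self.shape[axis]
        else:
            n = int(np.prod([self.shape[a] for a in axis]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        _record_skip("relu", self.size)
        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        # exact (erf) form
        x = self.data
        cdf = 0.5 * (1.0 + _special.erf(x / math.sqrt(2.0)))

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            self._accumulate((g * (cdf + x * pdf)).astype(np.float32))

        _record_skip("gelu", self.size)
        return Tensor._make(x * cdf, (self,), backward)

    def sigmoid(self):
        s = _special.expit(self.data)

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        _record_skip("sigmoid", self.size)
        return Tensor._make(s, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        _record_skip("softmax", self.size)
        return Tensor._make(s, (self,), backward)

    # ---------------------------------------------------------- linear algebra
    def matmul(self, other: "Tensor"):
        """Matrix product.

        Supports ``(..., M, K) @ (K, N)`` (dense layer weight) and batched
        ``(..., M, K) @ (..., K, N)`` with identical leading dimensions.
        """
        a, b = self, other
        ad, bd = a.data, b.data
        out_data = np.matmul(ad, bd)
        m, k = ad.shape[-2], ad.shape[-1]
        n = bd.shape[-1]
        batch = int(np.prod(out_data.shape[:-2])) if out_data.ndim > 2 else 1
        _record_macs(batch * m * k * n)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(bd, -1, -2))
                a._accumulate(_unbroadcast(ga, ad.shape))
            if b.requires_grad:
                if bd.ndim == 2 and ad.ndim > 2:
                    gb = np.matmul(
                        ad.reshape(-1, k).T, g.reshape(-1, n)
                    )
                else:
                    gb = np.matmul(np.swapaxes(ad, -1, -2), g)
                    gb = _unbroadcast(gb, bd.shape)
                b._accumulate(gb.astype(np.float32))

        return Tensor._make(out_data, (a, b), backward)

    def __matmul__(self, other):
        return self.matmul(other)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(out_data, tuple(tensors), backward)


# --------------------------------------------------------------- convolution
def _im2col_view(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Strided sliding-window view (B, C, kh, kw, Ho, Wo) of padded input."""
    b, c, hp, wp = xp.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    sb, sc, sy, sx = xp.strides
    view = as_strided(
        xp,
        shape=(b, c, kh, kw, ho, wo),
        strides=(sb, sc, sy, sx, sy * sh, sx * sw),
        writeable=False,
    )
    return view, ho, wo


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``groups`` must be 1 (dense) or equal to the channel count (depthwise).
    """
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    sh = sw = int(stride)
    ph = pw = int(padding)
    if groups not in (1, Cin):
        raise ValueError("conv2d supports groups=1 or depthwise groups only")
    if groups == 1 and Cin_g != Cin:
        raise ValueError(f"weight expects {Cin_g} input channels, got {Cin}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x.data
    view, Ho, Wo = _im2col_view(xp, kh, kw, sh, sw)

    if groups == 1:
        cols = view.reshape(B, Cin * kh * kw, Ho * Wo)
        wmat = w.data.reshape(Cout, Cin * kh * kw)
        out = np.matmul(wmat, cols).reshape(B, Cout, Ho, Wo)
        _record_macs(B * Ho * Wo * Cout * Cin * kh * kw)
    else:  # depthwise
        out = np.einsum("bcijhw,cij->bchw", view, w.data[:, 0], optimize=True)
        _record_macs(B * Ho * Wo * Cout * kh * kw)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def backward(g):
        g = g.reshape(B, Cout, Ho, Wo)
        if w.requires_grad:
            if groups == 1:
                gw = np.einsum(
                    "bnhw,bcijhw->ncij", g, view, optimize=True
                ).reshape(w.shape)
            else:
                gw = np.einsum("bchw,bcijhw->cij", g, view, optimize=True)[
                    :, None, :, :
                ]
            w._accumulate(gw.astype(np.float32))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            if groups == 1:
                wmat = w.data.reshape(Cout, Cin * kh * kw)
                gcols = np.matmul(wmat.T, g.reshape(B, Cout, Ho * Wo))
                gcols = gcols.reshape(B, Cin, kh, kw, Ho, Wo)
            else:
                gcols = np.einsum("bchw,cij->bcijhw", g, w.data[:, 0], optimize=True)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += gcols[
                        :, :, i, j
                    ]
            if ph or pw:
                gxp = gxp[:, :, ph : ph + H, pw : pw + W]
            x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out.astype(np.float32), parents, backward)


# ------------------------------------------------------------- normalisation
def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * weight.data + bias.data
    n = x.shape[-1]

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(
                (g * xhat).reshape(-1, n).sum(axis=0).astype(np.float32)
            )
        if bias.requires_grad:
            bias._accumulate(g.reshape(-1, n).sum(axis=0).astype(np.float32))
        if x.requires_grad:
            gx = g * weight.data
            a = gx.sum(axis=-1, keepdims=True)
            bsum = (gx * xhat).sum(axis=-1, keepdims=True)
            x._accumulate(((gx - a / n - xhat * bsum / n) * inv).astype(np.float32))

    _record_skip("layer_norm", x.size)
    return Tensor._make(out.astype(np.float32), (x, weight, bias), backward)


def batch_norm2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) for NCHW feature maps."""
    C = x.shape[1]
    if training:
        axes = (0, 2, 3)
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size // C
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
        n = x.data.size // C
    inv = 1.0 / np.sqrt(var + eps)
    shape = (1, C, 1, 1)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = xhat * weight.data.reshape(shape) + bias.data.reshape(shape)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate((g * xhat).sum(axis=(0, 2, 3)).astype(np.float32))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)).astype(np.float32))
        if x.requires_grad:
            gx = g * weight.data.reshape(shape)
            if training:
                a = gx.sum(axis=(0, 2, 3), keepdims=True)
                bsum = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accumulate(
                    (
                        (gx - a / n - xhat * bsum / n) * inv.reshape(shape)
                    ).astype(np.float32)
                )
            else:
                x._accumulate((gx * inv.reshape(shape)).astype(np.float32))

    _record_skip("batch_norm", x.size)
    return Tensor._make(out.astype(np.float32), (x, weight, bias), backward)


# ---------------------------------------------------------------- resampling
def _linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation matrix.

    Uses the half-pixel-centre convention (align_corners=False).
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - frac
        m[o, i1c] += frac
    return m


_resize_matrix_cache: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    key = (n_in, n_out)
    if key not in _resize_matrix_cache:
        _resize_matrix_cache[key] = _linear_resize_matrix(n_in, n_out)
    return _resize_matrix_cache[key]


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor (half-pixel centres)."""
    B, C, H, W = x.shape
    R = _resize_matrix(H, out_h)
    Ccol = _resize_matrix(W, out_w)
    out = np.matmul(np.matmul(R, x.data), Ccol.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(R.T, g), Ccol).astype(np.float32))

    _record_skip("resize_bilinear", out.size)
    return Tensor._make(out.astype(np.float32), (x,), backward)


def resize_nearest(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbour resize of the trailing two axes (no gradient)."""
    h, w = x.shape[-2], x.shape[-1]
    rows = np.minimum((np.arange(out_h) * h) // out_h, h - 1)
    cols = np.minimum((np.arange(out_w) * w) // out_w, w - 1)
    return x[..., rows[:, None], cols[None, :]]


# -------------------------------------------------------------------- losses
def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Per-element binary cross-entropy on raw logits (numerically stable)."""
    z = np.asarray(target, dtype=np.float32)
    x = logits.data
    loss = np.maximum(x, 0) - x * z + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        logits._accumulate((g * (_special.expit(x) - z)).astype(np.float32))

    return Tensor._make(loss.astype(np.float32), (logits,), backward)
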