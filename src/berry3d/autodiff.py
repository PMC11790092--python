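"""A compact reverse-mode automatic differentiation engine on numpy arrays.

The differentiable depth-image-based rendering loss needs gradients of a
photometric error with respect to depth maps, camera poses and network
weights.  This module provides exactly the tensor operations that pipeline
requires — elementwise arithmetic, reductions, matmul, 2D convolution,
nearest-neighbor upsampling, reflect padding, slicing/stacking, and a
bilinear grid sampler — each with an exact analytic backward pass.

Arrays are float64 by default; convolution-heavy network code may pass
float32 for speed.  Gradients are accumulated by a topological sweep over
the recorded graph; the engine is purely CPU/numpy and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "stack", "concat", "where", "grid_sample",
           "conv2d", "reflect_pad2d", "upsample_nearest2d", "gradcheck"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the local backward rules that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in parents)
        self._parents = tuple(parents) if self.requires_grad else ()

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def value(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -----------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative post-order to avoid recursion limits on deep graphs
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, done = visiting.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for parent, _ in node._parents:
                visiting.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = grad_fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contrib
                else:
                    grads[id(parent)] = contrib

    # -- elementwise arithmetic -------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(g, other.shape)),
        ))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(
            (self, lambda g: _unbroadcast(g * other.data, self.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.shape)),
        ))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(
            (self, lambda g: _unbroadcast(g / other.data, self.shape)),
            (other, lambda g: _unbroadcast(-g * self.data / other.data**2, other.shape)),
        ))
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor(self.data**e, parents=(
            (self, lambda g: g * e * self.data ** (e - 1.0)),
        ))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=((self, lambda g: g * out_data),))

    def log(self):
        return Tensor(np.log(self.data), parents=((self, lambda g: g / self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(out_data, parents=((self, lambda g: g * 0.5 / out_data),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out_data, parents=((self, lambda g: g * out_data * (1.0 - out_data)),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=((self, lambda g: g * mask),))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=((self, lambda g: g * sign),))

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor(np.clip(self.data, lo, hi), parents=((self, lambda g: g * mask),))

    def sin(self):
        return Tensor(np.sin(self.data), parents=((self, lambda g: g * np.cos(self.data)),))

    def cos(self):
        return Tensor(np.cos(self.data), parents=((self, lambda g: -g * np.sin(self.data)),))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy() if np.ndim(g) == 0 else np.full(self.shape, g)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return Tensor(out_data, parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), parents=((self, lambda g: g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), parents=((self, lambda g: g.transpose(inv)),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def grad_fn(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return gx

        return Tensor(out_data, parents=((self, grad_fn),))

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(
            (self, lambda g: g @ other.data.swapaxes(-1, -2)),
            (other, lambda g: self.data.swapaxes(-1, -2) @ g),
        ))
        return out


def constant(data) -> Tensor:
    return Tensor(np.asarray(data))


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        parents.append((t, lambda g, i=i: np.take(g, i, axis=axis)))
    return Tensor(out_data, parents=tuple(parents))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        n = t.shape[axis]
        sl = [slice(None)] * out_data.ndim
        sl[axis] = slice(offset, offset + n)
        parents.append((t, lambda g, sl=tuple(sl): g[sl]))
        offset += n
    return Tensor(out_data, parents=tuple(parents))


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where cond else b; cond is a plain boolean array (no gradient)."""
    cond = np.asarray(cond, dtype=bool)
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    out = Tensor(np.where(cond, a.data, b.data), parents=(
        (a, lambda g: _unbroadcast(np.where(cond, g, 0.0), a.shape)),
        (b, lambda g: _unbroadcast(np.where(cond, 0.0, g), b.shape)),
    ))
    return out


# -- structured ops -------------------------------------------------------

def reflect_pad2d(x: Tensor, pad: int) -> Tensor:
    """Reflect-pad the trailing two (H, W) axes of a (..., H, W) tensor."""
    h, w = x.shape[-2], x.shape[-1]
    ih = np.pad(np.arange(h), pad, mode="reflect")
    iw = np.pad(np.arange(w), pad, mode="reflect")
    out_data = x.data[..., ih[:, None], iw[None, :]]
    flat_idx = (ih[:, None] * w + iw[None, :]).ravel()

    def grad_fn(g):
        lead = x.data.shape[:-2]
        gx = np.zeros(lead + (h * w,), dtype=g.dtype)
        gflat = g.reshape(lead + (-1,))
        np.add.at(gx, (..., flat_idx), gflat)
        return gx.reshape(x.data.shape)

    return Tensor(out_data, parents=((x, grad_fn),))


def box_filter3(x: Tensor) -> Tensor:
    """3x3 mean filter with reflect padding on the trailing (H, W) axes."""
    h, w = x.shape[-2], x.shape[-1]
    xp = reflect_pad2d(x, 1)
    acc = None
    for di in range(3):
        for dj in range(3):
            sl = (Ellipsis, slice(di, di + h), slice(dj, dj + w))
            term = xp[sl]
            acc = term if acc is None else acc + term
    return acc * (1.0 / 9.0)


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbor upsampling of a (..., H, W) tensor by an integer factor."""
    f = int(factor)
    out_data = x.data.repeat(f, axis=-2).repeat(f, axis=-1)
    h, w = x.shape[-2], x.shape[-1]

    def grad_fn(g):
        lead = g.shape[:-2]
        return g.reshape(lead + (h, f, w, f)).sum(axis=(-3, -1))

    return Tensor(out_data, parents=((x, grad_fn),))


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    shape = (n, c, oh, ow, kh, kw)
    strides = (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3])
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    # (N, OH, OW, C*KH*KW)
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation) on NCHW input.

    weight: (C_out, C_in, KH, KW); bias: (C_out,).
    """
    n, c_in, h, w = x.shape
    c_out, c_in_w, kh, kw = weight.shape
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, weight expects {c_in_w}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(c_out, -1)
    out_data = cols @ wmat.T  # (N, OH, OW, C_out)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 3, 1, 2)

    def grad_x(g):
        gmat = g.transpose(0, 2, 3, 1)  # (N, OH, OW, C_out)
        gcols = gmat @ wmat  # (N, OH, OW, C_in*KH*KW)
        gcols = gcols.reshape(n, oh, ow, c_in, kh, kw)
        hp, wp = h + 2 * pad, w + 2 * pad
        gx = np.zeros((n, c_in, hp, wp), dtype=g.dtype)
        for di in range(kh):
            for dj in range(kw):
                gx[:, :, di:di + oh * stride:stride, dj:dj + ow * stride:stride] += \
                    gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        return gx

    def grad_w(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, c_out)  # (N*OH*OW, C_out)
        return (gmat.T @ cols.reshape(-1, c_in * kh * kw)).reshape(weight.shape)

    parents = [(x, grad_x), (weight, grad_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out_data, parents=tuple(parents))


def grid_sample(source: np.ndarray, u: Tensor, v: Tensor) -> Tensor:
    """Differentiable bilinear sampling of a fixed (C, H, W) image.

    ``u``/``v`` are continuous pixel coordinates of shape (H', W') (or any
    matching shape); the output has shape (C,) + u.shape.  Gradients flow to
    the coordinates, not to the source image (frames are data, not
    parameters).  Coordinates are clamped to the image for index safety; the
    caller masks out-of-bounds cells.
    """
    src = np.asarray(source, dtype=float)
    c, h, w = src.shape
    uu = np.clip(np.nan_to_num(u.data), 0.0, w - 1.0)
    vv = np.clip(np.nan_to_num(v.data), 0.0, h - 1.0)
    u0 = np.floor(uu).astype(int)
    v0 = np.floor(vv).astype(int)
    u0 = np.minimum(u0, w - 2) if w > 1 else u0 * 0
    v0 = np.minimum(v0, h - 2) if h > 1 else v0 * 0
    du = uu - u0
    dv = vv - v0
    i00 = src[:, v0, u0]
    i01 = src[:, v0, u0 + 1] if w > 1 else i00
    i10 = src[:, v0 + 1, u0] if h > 1 else i00
    i11 = src[:, v0 + 1, u0 + 1] if (h > 1 and w > 1) else i00
    out_data = (i00 * (1 - du) * (1 - dv) + i01 * du * (1 - dv)
                + i10 * (1 - du) * dv + i11 * du * dv)
    in_u = (u.data >= 0) & (u.data <= w - 1)
    in_v = (v.data >= 0) & (v.data <= h - 1)

    def grad_u(g):
        d = (i01 - i00) * (1 - dv) + (i11 - i10) * dv
        return (g * d).sum(axis=0) * in_u

    def grad_v(g):
        d = (i10 - i00) * (1 - du) + (i11 - i01) * du
        return (g * d).sum(axis=0) * in_v

    return Tensor(out_data, parents=((u, grad_u), (v, grad_v)))


def gradcheck(fn, inputs: list[Tensor], eps: float = 1e-6, rtol: float = 1e-4,
              atol: float = 1e-7) -> bool:
    """Compare analytic gradients of scalar fn(*inputs) to central differences."""
    for t in inputs:
        t.zero_grad()
    out = fn(*inputs)
    out.backward()
    for t in inputs:
        num = np.zeros_like(t.data, dtype=float)
        flat = t.data.reshape(-1)
        numf = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = fn(*inputs).item()
            flat[i] = orig - eps
            fm = fn(*inputs).item()
            flat[i] = orig
            numf[i] = (fp - fm) / (2 * eps)
        ana = t.grad if t.grad is not None else np.zeros_like(num)
        if not np.allclose(ana, num, rtol=rtol, atol=max(atol, eps * 10)):
            return False
    return True
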