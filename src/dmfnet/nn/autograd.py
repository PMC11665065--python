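"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network layer of this package (deformable convolutions, the balanced
pyramid, the grid head) is small enough that a compact tape-based autodiff
engine in float64 is both fast enough on CPU and easy to verify against
finite differences.  Only the primitives the model needs are provided;
everything else (batch norm, losses, attention) is composed from them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "maxpool2d",
    "interpolate_bilinear",
    "bilinear_gather",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g, a.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            a._accumulate(g * e * np.power(a.data, e - 1.0))

        return Tensor._make(np.power(a.data, e), (a,), backward)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask = mask * (a.data >= lo)
        if hi is not None:
            mask = mask * (a.data <= hi)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(out_data, (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the underlying data; used e.g. for softmax stabilisation."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = a.shape

        def backward(g):
            a._accumulate(g.reshape(old_shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_sum_to_shape(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_sum_to_shape(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.max_detached(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# ---------------------------------------------------------------------------
# Spatial primitives
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """View a padded (B,C,H,W) array as (B,C,kh,kw,Ho,Wo) patches."""
    b, c, h, w = xp.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sb, sc, sh, sw = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, ho, wo),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return cols, ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Standard 2-D cross-correlation, y(p0) = sum_n w(p_n) x(p0 + p_n)."""
    x, weight = as_tensor(x), as_tensor(weight)
    b, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    # (Cout, Cin*kh*kw) @ (B, Cin*kh*kw, Ho*Wo)
    w2 = weight.data.reshape(cout, -1)
    c2 = cols.reshape(b, cin * kh * kw, ho * wo)
    out_data = np.einsum("ok,bkp->bop", w2, c2).reshape(b, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(b, cout, ho * wo)
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", g2, c2).reshape(weight.shape)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("ok,bop->bkp", w2, g2).reshape(
                b, cin, kh, kw, ho, wo
            )
            gxp = np.zeros_like(xp)
            hs = np.arange(ho) * stride
            ws = np.arange(wo) * stride
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho * stride : stride,
                        j : j + wo * stride : stride] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial size {(h, w)} not divisible by {factor}")
    ho, wo = h // factor, w // factor
    blocks = x.data.reshape(b, c, ho, factor, wo, factor)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, factor * factor)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = (
            gflat.reshape(b, c, ho, wo, factor, factor)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def _resize_coords(n_out: int, n_in: int) -> np.ndarray:
    # pixel-centred (align_corners=False) source coordinates
    scale = n_in / n_out
    return (np.arange(n_out) + 0.5) * scale - 0.5


def interpolate_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize with pixel-centred coordinates and edge clamping."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    ys = np.clip(_resize_coords(out_h, h), 0, h - 1)
    xs = np.clip(_resize_coords(out_w, w), 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy1 = ys - y0
    wx1 = xs - x0
    wy0, wx0 = 1.0 - wy1, 1.0 - wx1

    d = x.data
    out_data = (
        d[:, :, y0[:, None], x0[None, :]] * (wy0[:, None] * wx0[None, :])
        + d[:, :, y0[:, None], x1[None, :]] * (wy0[:, None] * wx1[None, :])
        + d[:, :, y1[:, None], x0[None, :]] * (wy1[:, None] * wx0[None, :])
        + d[:, :, y1[:, None], x1[None, :]] * (wy1[:, None] * wx1[None, :])
    )

    def backward(g):
        gx = np.zeros_like(d)
        for yy, xx, wyy, wxx in (
            (y0, x0, wy0, wx0),
            (y0, x1, wy0, wx1),
            (y1, x0, wy1, wx0),
            (y1, x1, wy1, wx1),
        ):
            np.add.at(
                gx,
                (slice(None), slice(None), yy[:, None], xx[None, :]),
                g * (wyy[:, None] * wxx[None, :]),
            )
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def bilinear_gather(x: Tensor, coords: Tensor) -> Tensor:
    """Sample ``x`` (B,C,H,W) at fractional ``coords`` (B,N,Ho,Wo,2) = (y,x).

    Uses the separable bilinear kernel g(a,b) = max(0, 1-|a-b|) per axis and
    zero contribution for out-of-bounds integer neighbours, so sampling at an
    integer in-bounds point reproduces the array value exactly.  Returns
    (B,C,N,Ho,Wo).  Differentiable in both ``x`` and ``coords``.
    """
    x, coords = as_tensor(x), as_tensor(coords)
    b, c, h, w = x.shape
    bc, n, ho, wo, two = coords.shape
    if bc != b or two != 2:
        raise ValueError(f"coords shape {coords.shape} incompatible with input {x.shape}")
    py = coords.data[..., 0]
    px = coords.data[..., 1]
    y0 = np.floor(py).astype(int)
    x0 = np.floor(px).astype(int)
    fy = py - y0
    fx = px - x0

    xhw = np.moveaxis(x.data, 1, 3)  # (B,H,W,C)
    bidx = np.arange(b)[:, None, None, None]
    vals = np.zeros((b, n, ho, wo, c))
    corner_cache = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = y0 + dy
        xx = x0 + dx
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yc = np.clip(yy, 0, h - 1)
        xc = np.clip(xx, 0, w - 1)
        wy = (1.0 - fy) if dy == 0 else fy
        wx = (1.0 - fx) if dx == 0 else fx
        weight = wy * wx * valid
        v = xhw[bidx, yc, xc]  # (B,N,Ho,Wo,C)
        vals += weight[..., None] * v
        corner_cache.append((yc, xc, valid, v, dy, dx))
    out_data = np.moveaxis(vals, 4, 1).reshape(b, c, n, ho, wo)

    def backward(g):
        gv = np.moveaxis(g.reshape(b, c, n, ho, wo), 1, 4)  # (B,N,Ho,Wo,C)
        if x.requires_grad:
            gx_hw = np.zeros((b, h, w, c))
        gy = np.zeros((b, n, ho, wo))
        gxc = np.zeros((b, n, ho, wo))
        for yc, xc, valid, v, dy, dx in corner_cache:
            wy = (1.0 - fy) if dy == 0 else fy
            wx = (1.0 - fx) if dx == 0 else fx
            dwy = -1.0 if dy == 0 else 1.0
            dwx = -1.0 if dx == 0 else 1.0
            if x.requires_grad:
                np.add.at(
                    gx_hw,
                    (bidx, yc, xc),
                    gv * (wy * wx * valid)[..., None],
                )
            if coords.requires_grad:
                gdot = (gv * v).sum(axis=-1)  # (B,N,Ho,Wo)
                gy += gdot * (dwy * wx * valid)
                gxc += gdot * (wy * dwx * valid)
        if x.requires_grad:
            x._accumulate(np.moveaxis(gx_hw, 3, 1))
        if coords.requires_grad:
            coords._accumulate(np.stack([gy, gxc], axis=-1))

    return Tensor._make(out_data, (x, coords), backward)
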