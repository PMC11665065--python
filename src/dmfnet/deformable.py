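"""Deformable convolution: learned fractional sampling offsets.

A standard convolution samples the input on a fixed regular grid R around
each output position p0:

    y(p0) = sum_n w(p_n) * x(p0 + p_n),        p_n in R.

The deformable variant adds a learned, per-position fractional displacement
dp_n to every sampling point:

    y(p0) = sum_n w(p_n) * x(p0 + p_n + dp_n),

with x evaluated at fractional locations through the separable bilinear
kernel G(p, q) = g(q_x, p_x) * g(q_y, p_y), g(a, b) = max(0, 1 - |a - b|).
Gradients flow to the input, the kernel weights and the offsets through the
same kernel, so the offset field is trained end to end.  The offsets come
from a plain convolution over the same input, initialised to zero so that
training starts exactly at the standard-convolution behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, Tensor, as_tensor, bilinear_gather

__all__ = [
    "SamplingGrid",
    "regular_grid",
    "bilinear_sample",
    "deformable_conv2d",
    "OffsetBranch",
    "DeformableConv2d",
]


@dataclass(frozen=True)
class SamplingGrid:
    """The regular grid R: row-major displacements of a k x k kernel."""

    offsets: tuple[tuple[int, int], ...]
    kernel_size: int
    dilation: int

    def __len__(self) -> int:
        return len(self.offsets)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=np.float64)


def regular_grid(kernel_size: int, dilation: int = 1) -> SamplingGrid:
    """Enumerate the displacements of a centred odd kernel, row-major.

    regular_grid(3, 1) yields (-1,-1), (-1,0), ..., (0,1), (1,0), (1,1).
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    half = kernel_size // 2
    offsets = tuple(
        (dy * dilation, dx * dilation)
        for dy in range(-half, half + 1)
        for dx in range(-half, half + 1)
    )
    return SamplingGrid(offsets=offsets, kernel_size=kernel_size, dilation=dilation)


def bilinear_sample(values: np.ndarray, point) -> float:
    """Evaluate a single-channel map at a fractional point (y, x).

    Direct evaluation of x(p) = sum_q G(p, q) x(q) over the integral
    locations q; contributions outside the array are zero.  At integer
    in-bounds points this returns the array value exactly.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("bilinear_sample expects a 2-D single-channel map")
    py, px = float(point[0]), float(point[1])
    h, w = values.shape
    y0, x0 = int(np.floor(py)), int(np.floor(px))
    total = 0.0
    for qy in (y0, y0 + 1):
        gy = max(0.0, 1.0 - abs(qy - py))
        if gy == 0.0 or not (0 <= qy < h):
            continue
        for qx in (x0, x0 + 1):
            gx = max(0.0, 1.0 - abs(qx - px))
            if gx == 0.0 or not (0 <= qx < w):
                continue
            total += gy * gx * values[qy, qx]
    return total


def deformable_conv2d(x, weight, grid: SamplingGrid, offsets,
                      bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Deformable 2-D convolution.

    Parameters
    ----------
    x : Tensor (B, Cin, H, W)
    weight : Tensor (Cout, Cin, k, k)
    grid : the regular sampling grid R of the kernel
    offsets : Tensor (B, 2N, Ho, Wo) of (dy, dx) per sampling point,
        interleaved row-major over the grid (channel 2n is dy of point n)
    """
    x, weight, offsets = as_tensor(x), as_tensor(weight), as_tensor(offsets)
    b, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    n = len(grid)
    if kh * kw != n:
        raise ValueError(f"weight kernel {kh}x{kw} does not match grid of {n} points")
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    if offsets.shape[1] != 2 * n:
        raise ValueError(
            f"offset field has {offsets.shape[1]} channels, expected {2 * n}"
        )
    _, _, ho, wo = offsets.shape

    # base sampling coordinates p0 + p_n in input-frame pixels, where p0 is
    # the centre of the receptive field of output position (i, j)
    pn = grid.as_array()  # (N, 2)
    centre = (grid.kernel_size // 2) * grid.dilation
    ys = np.arange(ho) * stride - padding + centre
    xs = np.arange(wo) * stride - padding + centre
    base = np.zeros((n, ho, wo, 2))
    base[..., 0] = pn[:, 0, None, None] + ys[None, :, None]
    base[..., 1] = pn[:, 1, None, None] + xs[None, None, :]

    off = offsets.reshape(b, n, 2, ho, wo).transpose(0, 1, 3, 4, 2)
    coords = off + Tensor(base[None])  # (B, N, Ho, Wo, 2)
    sampled = bilinear_gather(x, coords)  # (B, Cin, N, Ho, Wo)

    w2 = weight.reshape(cout, cin * n)
    s2 = sampled.reshape(b, cin * n, ho * wo)
    out = (w2 @ s2).reshape(b, cout, ho, wo)
    if bias is not None:
        out = out + as_tensor(bias).reshape(1, cout, 1, 1)
    return out


class OffsetBranch(Module):
    """Convolutional layer predicting the 2N offset channels; zero-initialised."""

    def __init__(self, in_channels: int, grid: SamplingGrid,
                 stride: int = 1, padding: int = 1):
        super().__init__()
        self.grid = grid
        self.conv = Conv2d(
            in_channels, 2 * len(grid), grid.kernel_size,
            stride=stride, padding=padding, zero_init=True,
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class DeformableConv2d(Module):
    """3x3 (or k x k) convolution whose sampling grid deforms per location."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 1, dilation: int = 1,
                 bias: bool = True, rng=None):
        super().__init__()
        self.grid = regular_grid(kernel_size, dilation)
        self.stride = stride
        self.padding = padding
        self.conv = Conv2d(in_channels, out_channels, kernel_size,
                           stride=stride, padding=padding, bias=bias, rng=rng)
        self.offset_branch = OffsetBranch(in_channels, self.grid,
                                          stride=stride, padding=padding)

    def forward(self, x: Tensor) -> Tensor:
        offsets = self.offset_branch(x)
        return deformable_conv2d(
            x, self.conv.weight, self.grid, offsets,
            bias=self.conv.bias, stride=self.stride, padding=self.padding,
        )
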