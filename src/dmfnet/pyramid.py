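"""Balanced feature pyramid: rescale -> integrate -> refine -> strengthen.

All pyramid levels are brought to one intermediate resolution (finer levels
by max-pooling, coarser by bilinear interpolation), averaged into a single
balanced map

    Q_int = (1 / L) * sum_{l = l_min}^{l_max} Q_l,

refined by a non-local block

    U_i = (1 / C(v)) * sum_j f(v_i, v_j) g(v_j),

and redistributed: the refined map is resized back to each level and added
to the original feature, so every level receives the same aggregated
semantic information.
"""

from __future__ import annotations

from dataclasses import dataclass

from .backbone import BackbonePyramid, FeatureMap
from .nn import Conv2d, Module, Tensor, interpolate_bilinear, maxpool2d

__all__ = [
    "BalancedFeature",
    "NonLocalContext",
    "rescale_to_level",
    "integrate",
    "NonLocalBlock",
    "nonlocal_refine",
    "strengthen",
    "BalancedPyramid",
]


@dataclass
class BalancedFeature:
    values: Tensor
    level_index: int


@dataclass
class NonLocalContext:
    """Configuration of the non-local operator.

    pairwise: 'embedded_gaussian' (softmax over projected dot products) or
    'constant' (f == 1, so each output is the spatial mean of g(v)).
    """

    pairwise: str = "embedded_gaussian"
    block: "NonLocalBlock | None" = None
    residual: bool = True


def _resize(values: Tensor, src_stride: int, dst_stride: int) -> Tensor:
    """Max-pool when going coarser, bilinear-interpolate when going finer."""
    if src_stride == dst_stride:
        return values
    if dst_stride > src_stride:
        factor = dst_stride // src_stride
        if factor * src_stride != dst_stride:
            raise ValueError("strides must be power-of-two multiples")
        return maxpool2d(values, factor)
    _, _, h, w = values.shape
    factor = src_stride // dst_stride
    return interpolate_bilinear(values, h * factor, w * factor)


def rescale_to_level(pyramid: BackbonePyramid, target_level: int) -> list[Tensor]:
    """Resize every pyramid level to the target level's resolution."""
    if target_level not in pyramid:
        raise ValueError(f"target level {target_level} not in pyramid")
    dst = pyramid[target_level].stride
    return [
        _resize(pyramid[lv].values, pyramid[lv].stride, dst)
        for lv in pyramid.indices()
    ]


def integrate(rescaled: list[Tensor]) -> Tensor:
    """Element-wise arithmetic mean of the L rescaled levels."""
    shapes = {tuple(t.shape) for t in rescaled}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across levels: {sorted(shapes)}")
    total = rescaled[0]
    for t in rescaled[1:]:
        total = total + t
    return total * (1.0 / len(rescaled))


class NonLocalBlock(Module):
    """Embedded-Gaussian non-local block with a residual connection.

    f(v_i, v_j) = exp(theta(v_i) . phi(v_j)), C(v) = sum_j f(v_i, v_j)
    (i.e. a softmax over j), g and the output projection are 1x1 convs.
    """

    def __init__(self, channels: int, inner_channels: int | None = None):
        super().__init__()
        inner = inner_channels or max(1, channels // 2)
        self.inner = inner
        self.theta = Conv2d(channels, inner, 1)
        self.phi = Conv2d(channels, inner, 1)
        self.g = Conv2d(channels, inner, 1)
        self.out = Conv2d(inner, channels, 1, zero_init=True)

    def attend(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        p = h * w
        q = self.theta(x).reshape(b, self.inner, p).transpose(0, 2, 1)  # (B,P,I)
        k = self.phi(x).reshape(b, self.inner, p)                       # (B,I,P)
        v = self.g(x).reshape(b, self.inner, p).transpose(0, 2, 1)      # (B,P,I)
        attn = (q @ k).softmax(axis=-1)                                 # (B,P,P)
        y = (attn @ v).transpose(0, 2, 1).reshape(b, self.inner, h, w)
        return self.out(y)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.attend(x)


def nonlocal_refine(balanced: BalancedFeature, context: NonLocalContext) -> BalancedFeature:
    """Apply the configured non-local operator to the balanced map."""
    x = balanced.values
    if context.pairwise == "constant":
        # f == 1 and g identity: every position becomes the spatial mean
        refined = x.mean(axis=(2, 3), keepdims=True) + x * 0.0
        if context.residual:
            refined = refined + x
    elif context.pairwise == "embedded_gaussian":
        block = context.block
        if block is None:
            raise ValueError("embedded_gaussian refinement requires a NonLocalBlock")
        refined = block.attend(x)
        if context.residual:
            refined = refined + x
    else:
        raise ValueError(f"unknown pairwise function {context.pairwise!r}")
    return BalancedFeature(values=refined, level_index=balanced.level_index)


def strengthen(refined: BalancedFeature, pyramid: BackbonePyramid) -> BackbonePyramid:
    """Resize the refined map to each level and add it to the original."""
    dst_stride = pyramid[refined.level_index].stride
    out = BackbonePyramid()
    for lv in pyramid.indices():
        fm = pyramid[lv]
        resized = _resize(refined.values, dst_stride, fm.stride)
        out.levels[lv] = FeatureMap(fm.values + resized, fm.stride)
    return out


class BalancedPyramid(Module):
    """The full rescale/integrate/refine/strengthen pipeline as one module."""

    def __init__(self, channels: int, intermediate_level: int = 4):
        super().__init__()
        self.intermediate_level = intermediate_level
        self.nonlocal_block = NonLocalBlock(channels)

    def forward(self, pyramid: BackbonePyramid) -> BackbonePyramid:
        rescaled = rescale_to_level(pyramid, self.intermediate_level)
        balanced = BalancedFeature(integrate(rescaled), self.intermediate_level)
        ctx = NonLocalContext(pairwise="embedded_gaussian", block=self.nonlocal_block)
        refined = nonlocal_refine(balanced, ctx)
        return strengthen(refined, pyramid)
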