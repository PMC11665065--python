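"""Residual backbone with optionally deformable stages, plus an FPN.

The backbone follows the standard residual-network layout: a downsampling
stem, then four stages at strides 4/8/16/32 emitting C2..C5.  The 3x3
convolutions of selected stages are replaced by deformable convolutions so
the receptive field can adapt to the irregular outlines of nuclei.  The
feature pyramid attaches lateral 1x1 projections and a top-down pathway
with 2x upsampling, giving uniform-width maps Q2..Q5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .deformable import DeformableConv2d
from .nn import (
    BatchNorm2d,
    Conv2d,
    Identity,
    Module,
    ReLU,
    Sequential,
    Tensor,
    interpolate_bilinear,
    maxpool2d,
)

__all__ = ["FeatureMap", "BackbonePyramid", "ResidualBackbone", "build_backbone",
           "FPN", "fpn"]

STAGE_NAMES = ("stage2", "stage3", "stage4", "stage5")


@dataclass
class FeatureMap:
    """A (B, C, H, W) activation with its spatial stride vs the input image."""

    values: Tensor
    stride: int

    @property
    def shape(self):
        return self.values.shape


@dataclass
class BackbonePyramid:
    """Uniform-width multi-level features keyed by level index (2..5)."""

    levels: dict[int, FeatureMap] = field(default_factory=dict)

    def __getitem__(self, level: int) -> FeatureMap:
        return self.levels[level]

    def __contains__(self, level: int) -> bool:
        return level in self.levels

    def indices(self) -> list[int]:
        return sorted(self.levels)


def _conv3x3(cin: int, cout: int, stride: int, deformable: bool) -> Module:
    if deformable:
        return DeformableConv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
    return Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)


class BasicBlock(Module):
    """Two 3x3 convolutions with a shortcut; pre-activation is not used."""

    def __init__(self, cin: int, cout: int, stride: int = 1, deformable: bool = False):
        super().__init__()
        self.conv1 = _conv3x3(cin, cout, stride, deformable)
        self.bn1 = BatchNorm2d(cout)
        self.relu = ReLU()
        self.conv2 = _conv3x3(cout, cout, 1, deformable)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.shortcut = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False), BatchNorm2d(cout)
            )
        else:
            self.shortcut = Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return (out + self.shortcut(x)).relu()


class ResidualBackbone(Module):
    """Residual network emitting {C2..C5} at strides 4/8/16/32."""

    def __init__(self, stage_blocks=(3, 4, 6, 3), base_width: int = 64,
                 deformable_stages: frozenset[str] | set[str] = frozenset(),
                 in_channels: int = 3):
        super().__init__()
        unknown = set(deformable_stages) - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
        if len(stage_blocks) != 4:
            raise ValueError("stage_blocks must list four stages")
        self.stem = Sequential(
            Conv2d(in_channels, base_width, 3, stride=2, padding=1, bias=False),
            BatchNorm2d(base_width),
            ReLU(),
        )
        widths = [base_width * (2**i) for i in range(4)]
        self.widths = widths
        stages = []
        cin = base_width
        for i, (name, nblocks) in enumerate(zip(STAGE_NAMES, stage_blocks)):
            deform = name in deformable_stages
            # stage2 keeps stride (stem 2x + pool 2x = stride 4); later stages halve
            stride = 1 if i == 0 else 2
            blocks = [BasicBlock(cin, widths[i], stride=stride, deformable=deform)]
            for _ in range(nblocks - 1):
                blocks.append(BasicBlock(widths[i], widths[i], deformable=deform))
            stages.append(Sequential(*blocks))
            cin = widths[i]
        self.stage2, self.stage3, self.stage4, self.stage5 = stages

    def forward(self, x: Tensor) -> dict[int, FeatureMap]:
        x = self.stem(x)
        x = maxpool2d(x, 2)
        c2 = self.stage2(x)
        c3 = self.stage3(c2)
        c4 = self.stage4(c3)
        c5 = self.stage5(c4)
        return {
            2: FeatureMap(c2, 4),
            3: FeatureMap(c3, 8),
            4: FeatureMap(c4, 16),
            5: FeatureMap(c5, 32),
        }


def build_backbone(stage_blocks=(3, 4, 6, 3), base_width: int = 64,
                   deformable_stages=("stage3", "stage4", "stage5")) -> ResidualBackbone:
    """Construct the backbone; deformable 3x3 convs in the named stages."""
    return ResidualBackbone(
        stage_blocks=tuple(stage_blocks),
        base_width=base_width,
        deformable_stages=frozenset(deformable_stages),
    )


class FPN(Module):
    """Lateral 1x1 + top-down 2x upsampling + 3x3 smoothing, uniform width."""

    def __init__(self, in_channels: dict[int, int], out_channels: int = 256):
        super().__init__()
        self.out_channels = out_channels
        self.levels = sorted(in_channels)
        for lv in self.levels:
            setattr(self, f"lateral{lv}", Conv2d(in_channels[lv], out_channels, 1))
            setattr(self, f"smooth{lv}", Conv2d(out_channels, out_channels, 3, padding=1))

    def forward(self, feats: dict[int, FeatureMap]) -> BackbonePyramid:
        strides = [feats[lv].stride for lv in self.levels]
        if any(b <= a for a, b in zip(strides, strides[1:])):
            raise ValueError("input strides must be strictly increasing")
        laterals = {
            lv: getattr(self, f"lateral{lv}")(feats[lv].values) for lv in self.levels
        }
        out = BackbonePyramid()
        top = None
        for lv in reversed(self.levels):
            cur = laterals[lv]
            if top is not None:
                _, _, h, w = cur.shape
                cur = cur + interpolate_bilinear(top, h, w)
            top = cur
            out.levels[lv] = FeatureMap(
                getattr(self, f"smooth{lv}")(cur), feats[lv].stride
            )
        return out


def fpn(feats: dict[int, FeatureMap], out_channels: int = 256) -> BackbonePyramid:
    """One-shot FPN over given features (module construction + forward)."""
    module = FPN({lv: f.values.shape[1] for lv, f in feats.items()}, out_channels)
    return module(feats)
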