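"""The assembled network: deformable backbone -> FPN -> balanced pyramid -> grid head."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import FPN, ResidualBackbone
from .head import GridSpec, SoloHead, decode, nms
from .instances import InstanceSet
from .nn import Module, Tensor
from .pyramid import BalancedPyramid

__all__ = ["ModelConfig", "DMFNet"]


@dataclass
class ModelConfig:
    stage_blocks: tuple[int, int, int, int] = (3, 4, 6, 3)
    base_width: int = 64
    deformable_stages: tuple[str, ...] = ("stage3", "stage4", "stage5")
    fpn_channels: int = 256
    intermediate_level: int = 4
    grid: GridSpec = field(default_factory=GridSpec)
    head_width: int = 64
    head_convs: int = 2
    score_thresh: float = 0.1
    mask_bin_thresh: float = 0.5
    nms_iou: float = 0.5
    max_instances: int = 100

    @staticmethod
    def desk() -> "ModelConfig":
        """Reduced-width profile for CPU-scale experiments on 128x128 patches."""
        return ModelConfig(
            stage_blocks=(1, 1, 1, 1),
            base_width=8,
            fpn_channels=16,
            grid=GridSpec(S=8, C=1, feature_level=3, mask_level=2),
            head_width=16,
            head_convs=2,
        )


class DMFNet(Module):
    """One-stage nucleus instance segmentation network."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        self.backbone = ResidualBackbone(
            stage_blocks=cfg.stage_blocks,
            base_width=cfg.base_width,
            deformable_stages=frozenset(cfg.deformable_stages),
        )
        widths = {2 + i: w for i, w in enumerate(self.backbone.widths)}
        self.fpn = FPN(widths, cfg.fpn_channels)
        self.bfp = BalancedPyramid(cfg.fpn_channels, cfg.intermediate_level)
        self.head = SoloHead(cfg.fpn_channels, cfg.grid,
                             head_width=cfg.head_width, num_convs=cfg.head_convs)

    @staticmethod
    def normalise(images: np.ndarray) -> Tensor:
        """uint8 (B, H, W, 3) or (B, 3, H, W) -> zero-centred float tensor."""
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[-1] == 3:
            arr = arr.transpose(0, 3, 1, 2)
        return Tensor(arr / 255.0 - 0.5)

    def forward(self, images) -> tuple[Tensor, Tensor]:
        x = images if isinstance(images, Tensor) else self.normalise(images)
        _, _, h, w = x.shape
        feats = self.backbone(x)
        pyramid = self.fpn(feats)
        strengthened = self.bfp(pyramid)
        return self.head(strengthened, (h, w))

    def predict_image(self, image: np.ndarray) -> InstanceSet:
        """Inference on one image: forward -> decode -> mask NMS."""
        was_training = self.training
        self.eval()
        cate, mask = self.forward(image[None] if image.ndim == 3 else image)
        cfg = self.config
        preds = decode(cate.data[0], mask.data[0],
                       score_thresh=cfg.score_thresh,
                       mask_bin_thresh=cfg.mask_bin_thresh)
        kept = nms(preds, iou_thresh=cfg.nms_iou, max_instances=cfg.max_instances)
        if was_training:
            self.train()
        return InstanceSet.from_predictions(kept)
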