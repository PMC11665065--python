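"""Location-based one-stage mask head.

The image is divided into an S x S grid.  The classification branch scores
each cell (S x S x C, sigmoid); the mask branch carries one channel per
cell (H x W x S^2), and cell (i, j) owns channel k = i*S + j.  An instance
whose centre of mass falls in cell (i, j) is predicted by that cell's class
score and mask channel; each cell is responsible for at most one instance.

Training combines a focal loss over the category grid with a dice loss over
the positive mask channels:

    L = L_focal + gamma * L_m,
    L_m = (1 / N) * sum_k 1{cell k positive} * L_dice(mask_k, gt_k),

where N is the number of positive cells.  Decoding thresholds the category
scores, binarises the owned mask channels, rescores by average foreground
confidence (maskness) and finishes with greedy mask NMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackbonePyramid
from .instances import InstancePrediction, InstanceSet
from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    as_tensor,
    concatenate,
    interpolate_bilinear,
)

__all__ = [
    "GridSpec",
    "GridTarget",
    "LossReport",
    "cell_to_channel",
    "channel_to_cell",
    "assign_targets",
    "SoloHead",
    "focal_loss",
    "dice_loss",
    "total_loss",
    "decode",
    "mask_iou_matrix",
    "nms",
]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry: S cells per side, C categories."""

    S: int = 24
    C: int = 1
    feature_level: int = 3  # pyramid level feeding the category branch
    mask_level: int = 2     # finest level feeding the mask branch

    def __post_init__(self):
        if self.S < 1 or self.C < 1:
            raise ValueError("S and C must be >= 1")


@dataclass
class GridTarget:
    """A training image encoded onto the grid."""

    category_grid: np.ndarray          # (S, S) int, 0 = background, else class id
    mask_bank: np.ndarray              # (S^2, H, W) uint8
    positive_indices: set[int] = field(default_factory=set)

    @property
    def S(self) -> int:
        return self.category_grid.shape[0]


def cell_to_channel(i: int, j: int, S: int) -> int:
    """k = i*S + j."""
    return i * S + j


def channel_to_cell(k: int, S: int) -> tuple[int, int]:
    return k // S, k % S


def assign_targets(instances: InstanceSet, spec: GridSpec,
                   image_size: tuple[int, int]) -> GridTarget:
    """Encode ground-truth instances onto the S x S grid.

    The centre of mass of each mask selects the owning cell; when two
    instances land in one cell the larger one wins (ties broken by the
    earlier instance index).
    """
    h, w = image_size
    S = spec.S
    category_grid = np.zeros((S, S), dtype=np.int64)
    mask_bank = np.zeros((S * S, h, w), dtype=np.uint8)
    owner_area = np.full(S * S, -1, dtype=np.int64)
    positives: set[int] = set()
    for idx, inst in enumerate(instances):
        ys, xs = np.nonzero(inst.mask)
        if ys.size == 0:
            continue
        cy, cx = ys.mean(), xs.mean()
        i = min(int(cy * S / h), S - 1)
        j = min(int(cx * S / w), S - 1)
        k = cell_to_channel(i, j, S)
        area = ys.size
        if area <= owner_area[k]:
            continue
        owner_area[k] = area
        category_grid[i, j] = inst.category
        mask_bank[k] = inst.mask.astype(np.uint8)
        positives.add(k)
    return GridTarget(category_grid=category_grid, mask_bank=mask_bank,
                      positive_indices=positives)


def _coord_maps(h: int, w: int) -> np.ndarray:
    """Two channels of normalised coordinates in [-1, 1]."""
    ys = np.linspace(-1.0, 1.0, h)
    xs = np.linspace(-1.0, 1.0, w)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([yy, xx])[None]  # (1, 2, H, W)


def _conv_bn_relu(cin: int, cout: int) -> Sequential:
    return Sequential(Conv2d(cin, cout, 3, padding=1, bias=False),
                      BatchNorm2d(cout), ReLU())


class SoloHead(Module):
    """Category and mask branches over the strengthened pyramid."""

    def __init__(self, in_channels: int, spec: GridSpec,
                 head_width: int = 64, num_convs: int = 2):
        super().__init__()
        self.spec = spec
        self.cate_tower = Sequential(
            *[_conv_bn_relu(in_channels if i == 0 else head_width, head_width)
              for i in range(num_convs)]
        )
        self.cate_out = Conv2d(head_width, spec.C, 3, padding=1)
        self.mask_tower = Sequential(
            *[_conv_bn_relu((in_channels + 2) if i == 0 else head_width, head_width)
              for i in range(num_convs)]
        )
        self.mask_out = Conv2d(head_width, spec.S * spec.S, 1)

    def forward(self, pyramid: BackbonePyramid,
                image_size: tuple[int, int]) -> tuple[Tensor, Tensor]:
        """Return (category scores (B,C,S,S), mask scores (B,S^2,H,W)), both sigmoid."""
        spec = self.spec
        cate_feat = pyramid[spec.feature_level].values
        cate = interpolate_bilinear(cate_feat, spec.S, spec.S)
        cate = self.cate_out(self.cate_tower(cate)).sigmoid()

        mask_feat = pyramid[spec.mask_level].values
        b, _, h, w = mask_feat.shape
        coords = Tensor(np.broadcast_to(_coord_maps(h, w), (b, 2, h, w)).copy())
        mask = concatenate([mask_feat, coords], axis=1)
        mask = self.mask_out(self.mask_tower(mask))
        mask = interpolate_bilinear(mask, image_size[0], image_size[1]).sigmoid()
        return cate, mask


def forward_heads(head: SoloHead, pyramid: BackbonePyramid,
                  image_size: tuple[int, int]) -> tuple[Tensor, Tensor]:
    """Functional alias for running the two head branches."""
    return head(pyramid, image_size)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS = 1e-12


def focal_loss(pred_scores, target_grid: np.ndarray,
               alpha: float = 0.25, gamma_f: float = 2.0) -> Tensor:
    """Sigmoid focal loss over the category grid, normalised by positives.

    ``pred_scores``: (S, S) or (C, S, S) probabilities in (0, 1);
    ``target_grid``: (S, S) int labels, 0 = background.
    """
    p = as_tensor(pred_scores)
    if np.any(p.data <= 0.0) or np.any(p.data >= 1.0):
        raise ValueError("focal_loss expects probabilities strictly in (0, 1)")
    if p.ndim == 2:
        p = p.reshape(1, *p.shape)
    c = p.shape[0]
    onehot = np.zeros(p.shape)
    for cls in range(1, c + 1):
        onehot[cls - 1] = target_grid == cls
    t = Tensor(onehot)
    pt = p * t + (1.0 - p) * (1.0 - t)
    alpha_t = alpha * onehot + (1.0 - alpha) * (1.0 - onehot)
    loss = -(Tensor(alpha_t) * (1.0 - pt) ** gamma_f * (pt + _EPS).log()).sum()
    n_pos = max(int(onehot.sum()), 1)
    return loss * (1.0 / n_pos)


def dice_loss(pred_mask, gt_mask) -> Tensor:
    """1 - 2*sum(p q) / (sum(p^2) + sum(q^2)); 0 for equal binary masks."""
    p = as_tensor(pred_mask)
    q = as_tensor(np.asarray(gt_mask.data if isinstance(gt_mask, Tensor) else gt_mask,
                             dtype=np.float64))
    if p.shape != q.shape:
        raise ValueError(f"mask shape mismatch: {p.shape} vs {q.shape}")
    num = (p * q).sum() * 2.0
    den = (p**2).sum() + (q**2).sum()
    return 1.0 - num / (den + _EPS)


@dataclass
class LossReport:
    total: Tensor
    category_term: Tensor
    mask_term: Tensor
    gamma: float
    n_positive: int


def total_loss(cate_pred, mask_pred, target: GridTarget, gamma: float = 3.0,
               alpha: float = 0.25, gamma_f: float = 2.0) -> LossReport:
    """L = L_focal + gamma * (1/N) sum over positive cells of L_dice."""
    cate_pred = as_tensor(cate_pred)
    mask_pred = as_tensor(mask_pred)
    category_term = focal_loss(cate_pred, target.category_grid,
                               alpha=alpha, gamma_f=gamma_f)
    positives = sorted(target.positive_indices)
    if positives:
        s2, h, w = mask_pred.shape
        sel = np.zeros((len(positives), s2))
        for row, k in enumerate(positives):
            sel[row, k] = 1.0
        p = Tensor(sel) @ mask_pred.reshape(s2, h * w)   # (N_pos, H*W)
        q = Tensor(target.mask_bank[positives].reshape(len(positives), -1)
                   .astype(np.float64))
        num = (p * q).sum(axis=1) * 2.0
        den = (p**2).sum(axis=1) + (q**2).sum(axis=1)
        dices = 1.0 - num / (den + _EPS)
        mask_term = dices.sum() * (1.0 / len(positives))
    else:
        mask_term = Tensor(0.0)
    total = category_term + mask_term * gamma
    return LossReport(total=total, category_term=category_term,
                      mask_term=mask_term, gamma=gamma, n_positive=len(positives))


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def decode(cate_pred, mask_pred, score_thresh: float = 0.1,
           mask_bin_thresh: float = 0.5) -> list[InstancePrediction]:
    """Turn raw branch outputs into instances.

    ``cate_pred``: (C, S, S) or (S, S) probabilities; ``mask_pred``:
    (S^2, H, W) soft masks.  Cells above the score threshold emit their
    channel's binarised mask; the cell score is multiplied by the mean
    soft-mask value over the binarised foreground (maskness).
    """
    if not (0.0 < score_thresh < 1.0) or not (0.0 < mask_bin_thresh < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    cate = np.asarray(cate_pred.data if isinstance(cate_pred, Tensor) else cate_pred)
    masks = np.asarray(mask_pred.data if isinstance(mask_pred, Tensor) else mask_pred)
    if cate.ndim == 2:
        cate = cate[None]
    c, S, _ = cate.shape
    out: list[InstancePrediction] = []
    for cls in range(c):
        for i in range(S):
            for j in range(S):
                score = float(cate[cls, i, j])
                if score < score_thresh:
                    continue
                k = cell_to_channel(i, j, S)
                soft = masks[k]
                binary = soft >= mask_bin_thresh
                if not binary.any():
                    continue
                maskness = float(soft[binary].mean())
                out.append(InstancePrediction(
                    mask=binary, score=score * maskness, category=cls + 1))
    out.sort(key=lambda p: -p.score)
    return out


def mask_iou_matrix(masks_a: list[np.ndarray], masks_b: list[np.ndarray]) -> np.ndarray:
    a = np.stack([m.astype(bool).ravel() for m in masks_a]).astype(np.float64)
    b = np.stack([m.astype(bool).ravel() for m in masks_b]).astype(np.float64)
    inter = a @ b.T
    union = a.sum(1)[:, None] + b.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def nms(predictions: list[InstancePrediction], iou_thresh: float = 0.5,
        max_instances: int = 100) -> list[InstancePrediction]:
    """Greedy mask-IoU suppression in descending score order."""
    if not predictions:
        return []
    order = sorted(predictions, key=lambda p: -p.score)
    kept: list[InstancePrediction] = []
    for cand in order:
        ok = True
        for k in kept:
            iou = mask_iou_matrix([cand.mask], [k.mask])[0, 0]
            if iou > iou_thresh:
                ok = False
                break
        if ok:
            kept.append(cand)
            if len(kept) >= max_instances:
                break
    return kept
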