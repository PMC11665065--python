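"""Mask-level AP/AR evaluation over the IoU ladder 0.50:0.05:0.95.

Matching follows the standard COCO protocol: within each image,
predictions are taken in descending score order and greedily matched to
the unmatched ground truth of highest mask IoU at or above the threshold;
matched predictions are true positives, the rest false positives, and
unmatched ground truths are false negatives.  AP at a threshold is the
101-point interpolated average precision

    AP = (1/101) * sum_{r in {0, 0.01, ..., 1}} max_{r~ >= r} p(r~),

AR at a threshold is the recall attained with at most 100 predictions per
image, and mAP / mAR average the ten thresholds.  With a single category,
AR at a threshold equals the recall of the matching at that threshold.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .instances import InstanceSet

__all__ = [
    "IOU_THRESHOLDS",
    "MatchResult",
    "EvalSummary",
    "mask_iou",
    "match_predictions",
    "precision_recall",
    "ap_at_iou",
    "summarize",
]

IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_GRID = np.linspace(0.0, 1.0, 101)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; 0 when the union is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class MatchResult:
    """Score-sorted TP/FP flags for one image at one IoU threshold."""

    scores: np.ndarray        # descending
    tp: np.ndarray            # bool per prediction
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


def match_predictions(preds: InstanceSet, gts: InstanceSet,
                      iou_thresh: float, max_dets: int | None = None) -> MatchResult:
    """Greedy score-ordered matching with per-ground-truth exclusivity."""
    plist = sorted(preds, key=lambda p: -p.score)
    if max_dets is not None:
        plist = plist[:max_dets]
    glist = list(gts)
    used = np.zeros(len(glist), dtype=bool)
    scores = np.array([p.score for p in plist])
    tp = np.zeros(len(plist), dtype=bool)
    for pi, p in enumerate(plist):
        best_iou, best_gi = iou_thresh, -1
        for gi, g in enumerate(glist):
            if used[gi] or g.category != p.category:
                continue
            iou = mask_iou(p.mask, g.mask)
            if iou >= best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0:
            used[best_gi] = True
            tp[pi] = True
    return MatchResult(scores=scores, tp=tp, n_gt=len(glist))


def precision_recall(match: MatchResult) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)); both 0 by convention when undefined."""
    n_pred = match.tp.size
    precision = match.n_tp / n_pred if n_pred else 0.0
    recall = match.n_tp / match.n_gt if match.n_gt else 0.0
    return precision, recall


def _pr_curve(matches: list[MatchResult]) -> tuple[np.ndarray, np.ndarray, int]:
    """Dataset-level precision/recall sequence over score-ranked predictions."""
    scores = np.concatenate([m.scores for m in matches]) if matches else np.empty(0)
    tps = np.concatenate([m.tp for m in matches]) if matches else np.empty(0, bool)
    n_gt = sum(m.n_gt for m in matches)
    order = np.argsort(-scores, kind="stable")
    tps = tps[order]
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    recall = tp_cum / n_gt if n_gt else np.zeros_like(tp_cum, dtype=float)
    return precision, recall, n_gt


def _interp_precision(precision: np.ndarray, recall: np.ndarray) -> np.ndarray:
    """Interpolated precision max_{r~ >= r} p(r~) on the 101-point grid."""
    if precision.size == 0:
        return np.zeros_like(RECALL_GRID)
    # non-increasing envelope of the raw curve
    env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    out = np.zeros_like(RECALL_GRID)
    valid = idx < recall.size
    out[valid] = env[idx[valid]]
    return out


def ap_at_iou(matches: list[MatchResult]) -> float:
    """101-point interpolated AP over the aggregated dataset matches."""
    precision, recall, n_gt = _pr_curve(matches)
    if n_gt == 0:
        return 0.0
    return float(_interp_precision(precision, recall).mean())


@dataclass
class EvalSummary:
    """AP/AR per IoU threshold plus their means and P-R curves."""

    ap: dict[float, float] = field(default_factory=dict)
    ar: dict[float, float] = field(default_factory=dict)
    pr_curves: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def mAP(self) -> float:
        return float(np.mean(list(self.ap.values())))

    @property
    def mAR(self) -> float:
        return float(np.mean(list(self.ar.values())))

    @property
    def AP50(self) -> float:
        return self.ap[0.5]

    @property
    def AP75(self) -> float:
        return self.ap[0.75]

    @property
    def AR50(self) -> float:
        return self.ar[0.5]

    @property
    def AR75(self) -> float:
        return self.ar[0.75]

    def to_dict(self, percent: bool = False) -> dict:
        f = (lambda x: round(100.0 * x, 2)) if percent else float
        return {
            "mAP": f(self.mAP), "mAR": f(self.mAR),
            "AP50": f(self.AP50), "AP75": f(self.AP75),
            "AR50": f(self.AR50), "AR75": f(self.AR75),
            "AP": {f"{t:.2f}": f(v) for t, v in self.ap.items()},
            "AR": {f"{t:.2f}": f(v) for t, v in self.ar.items()},
        }

    def to_json(self, path: str | Path, percent: bool = True) -> None:
        Path(path).write_text(json.dumps(self.to_dict(percent=percent), indent=1))

    def export_pr_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iou_threshold", "recall", "precision"])
            for t, curve in self.pr_curves.items():
                for r, p in zip(RECALL_GRID, curve):
                    writer.writerow([t, round(float(r), 2), float(p)])

    def plot_pr(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for t, curve in self.pr_curves.items():
            ax.plot(RECALL_GRID, curve, label=f"IoU {t:.2f}")
        ax.set_xlabel("recall")
        ax.set_ylabel("interpolated precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def summarize(preds_per_image: list[InstanceSet], gts_per_image: list[InstanceSet],
              iou_thresholds=IOU_THRESHOLDS, max_dets: int = 100) -> EvalSummary:
    """Full evaluation: AP and AR at each threshold, means, and P-R curves."""
    if len(preds_per_image) != len(gts_per_image):
        raise ValueError("predictions and ground truths must align per image")
    summary = EvalSummary()
    for t in iou_thresholds:
        matches = [
            match_predictions(p, g, t, max_dets=max_dets)
            for p, g in zip(preds_per_image, gts_per_image)
        ]
        precision, recall, n_gt = _pr_curve(matches)
        summary.ap[t] = float(_interp_precision(precision, recall).mean()) if n_gt else 0.0
        total_tp = sum(m.n_tp for m in matches)
        summary.ar[t] = total_tp / n_gt if n_gt else 0.0
        summary.pr_curves[t] = _interp_precision(precision, recall)
    return summary
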