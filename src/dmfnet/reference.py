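"""Slow, direct reference implementations used as independent oracles.

Each function here re-derives a quantity with explicit loops and no shared
code with the vectorised implementations, so that the two routes can be
compared in tests: the deformable convolution as a literal quadruple loop
over output positions and kernel points, the non-local operator as a double
loop over positions, and the detection metrics as a second, per-threshold
scan implementation of the COCO mask protocol.
"""

from __future__ import annotations

import numpy as np

from .deformable import SamplingGrid, bilinear_sample
from .instances import InstanceSet

__all__ = [
    "deformable_conv2d_reference",
    "nonlocal_reference",
    "integrate_reference",
    "evaluate_reference",
]


def deformable_conv2d_reference(x: np.ndarray, weight: np.ndarray,
                                grid: SamplingGrid, offsets: np.ndarray,
                                bias: np.ndarray | None = None,
                                stride: int = 1, padding: int = 0) -> np.ndarray:
    """y(p0) = sum_n w(p_n) x(p0 + p_n + dp_n), evaluated point by point."""
    x = np.asarray(x, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    offsets = np.asarray(offsets, dtype=np.float64)
    b, cin, h, w = x.shape
    cout = weight.shape[0]
    n = len(grid)
    _, _, ho, wo = offsets.shape
    wflat = weight.reshape(cout, cin, n)
    out = np.zeros((b, cout, ho, wo))
    centre = (grid.kernel_size // 2) * grid.dilation
    for bi in range(b):
        for i in range(ho):
            for j in range(wo):
                p0 = (i * stride - padding + centre,
                      j * stride - padding + centre)
                for ni, (dy, dx) in enumerate(grid.offsets):
                    oy = offsets[bi, 2 * ni, i, j]
                    ox = offsets[bi, 2 * ni + 1, i, j]
                    p = (p0[0] + dy + oy, p0[1] + dx + ox)
                    for ci in range(cin):
                        val = bilinear_sample(x[bi, ci], p)
                        for co in range(cout):
                            out[bi, co, i, j] += wflat[co, ci, ni] * val
    if bias is not None:
        out += np.asarray(bias).reshape(1, cout, 1, 1)
    return out


def nonlocal_reference(v: np.ndarray, mode: str = "embedded_gaussian",
                       theta: np.ndarray | None = None,
                       phi: np.ndarray | None = None,
                       g: np.ndarray | None = None,
                       out_proj: np.ndarray | None = None,
                       biases: dict | None = None) -> np.ndarray:
    """U_i = (1/C(v)) sum_j f(v_i, v_j) g(v_j) as an explicit double loop.

    ``v`` is (C, H, W).  For 'embedded_gaussian', theta/phi/g/out_proj are
    the 1x1 projection matrices (rows = output channels) and C(v) is the
    softmax denominator.  For 'constant', f == 1, g is the identity and
    C(v) is the number of positions.
    """
    c, h, w = v.shape
    pts = [(i, j) for i in range(h) for j in range(w)]
    p = len(pts)
    feats = np.array([v[:, i, j] for i, j in pts])  # (P, C)
    biases = biases or {}
    if mode == "constant":
        u = np.zeros((p, c))
        for i in range(p):
            acc = np.zeros(c)
            for j in range(p):
                acc += feats[j]          # f == 1, g identity
            u[i] = acc / p               # C(v) = number of positions
    elif mode == "embedded_gaussian":
        q = feats @ theta.T + biases.get("theta", 0.0)
        k = feats @ phi.T + biases.get("phi", 0.0)
        gv = feats @ g.T + biases.get("g", 0.0)
        inner = np.zeros((p, gv.shape[1]))
        for i in range(p):
            logits = np.array([q[i] @ k[j] for j in range(p)])
            logits -= logits.max()
            fij = np.exp(logits)
            cv = fij.sum()               # softmax normalisation C(v)
            acc = np.zeros(gv.shape[1])
            for j in range(p):
                acc += fij[j] * gv[j]
            inner[i] = acc / cv
        u = inner @ out_proj.T + biases.get("out", 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros((u.shape[1], h, w))
    for pi, (i, j) in enumerate(pts):
        out[:, i, j] = u[pi]
    return out


def integrate_reference(levels: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of L feature maps via an explicit accumulation loop."""
    acc = np.zeros_like(np.asarray(levels[0], dtype=np.float64))
    for lv in levels:
        acc += lv
    return acc / len(levels)


# ---------------------------------------------------------------------------
# Independent COCO-protocol mask evaluation
# ---------------------------------------------------------------------------


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.logical_and(a, b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    return inter / union if union else 0.0


def evaluate_reference(preds_per_image: list[InstanceSet],
                       gts_per_image: list[InstanceSet],
                       iou_thresholds, max_dets: int = 100) -> dict:
    """Second-route mask AP/AR: per-image greedy matching, then a direct
    scan of the 101 recall points taking max precision at recall >= r."""
    results = {"ap": {}, "ar": {}}
    for t in iou_thresholds:
        flagged: list[tuple[float, bool]] = []
        n_gt = 0
        n_tp_total = 0
        for preds, gts in zip(preds_per_image, gts_per_image):
            plist = sorted(preds, key=lambda q: -q.score)[:max_dets]
            glist = list(gts)
            n_gt += len(glist)
            taken = [False] * len(glist)
            for p in plist:
                best, best_g = -1.0, -1
                for gi, gt in enumerate(glist):
                    if taken[gi] or gt.category != p.category:
                        continue
                    val = _iou(p.mask, gt.mask)
                    if val > best:
                        best, best_g = val, gi
                if best_g >= 0 and best >= t:
                    taken[best_g] = True
                    flagged.append((p.score, True))
                    n_tp_total += 1
                else:
                    flagged.append((p.score, False))
        flagged.sort(key=lambda sf: -sf[0])
        precisions, recalls = [], []
        tp = fp = 0
        for _score, is_tp in flagged:
            tp += is_tp
            fp += not is_tp
            precisions.append(tp / (tp + fp))
            recalls.append(tp / n_gt if n_gt else 0.0)
        ap_sum = 0.0
        for ri in range(101):
            r = ri / 100.0
            best_p = 0.0
            for p_val, r_val in zip(precisions, recalls):
                if r_val >= r - 1e-12 and p_val > best_p:
                    best_p = p_val
            ap_sum += best_p
        results["ap"][t] = ap_sum / 101.0 if n_gt else 0.0
        results["ar"][t] = n_tp_total / n_gt if n_gt else 0.0
    results["mAP"] = float(np.mean(list(results["ap"].values())))
    results["mAR"] = float(np.mean(list(results["ar"].values())))
    return results
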