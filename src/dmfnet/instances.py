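"""Per-image instance containers shared by the head, the synthesiser and the evaluator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["InstanceSet", "InstancePrediction"]


@dataclass
class InstancePrediction:
    """One decoded instance: a binary mask, a confidence and a class label."""

    mask: np.ndarray
    score: float
    category: int = 1

    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class InstanceSet:
    """All instances on one image (ground truth or predictions)."""

    masks: list[np.ndarray] = field(default_factory=list)
    scores: list[float] | None = None
    categories: list[int] | None = None

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        n = len(self.masks)
        scores = self.scores if self.scores is not None else [1.0] * n
        cats = self.categories if self.categories is not None else [1] * n
        for m, s, c in zip(self.masks, scores, cats):
            yield InstancePrediction(mask=m, score=float(s), category=int(c))

    @staticmethod
    def from_predictions(preds: list[InstancePrediction]) -> "InstanceSet":
        return InstanceSet(
            masks=[p.mask for p in preds],
            scores=[p.score for p in preds],
            categories=[p.category for p in preds],
        )
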