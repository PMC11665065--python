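"""Training, inference and evaluation orchestration.

Training follows the protocol the network was designed around: SGD with
momentum 0.9, weight decay 1e-4 and learning rate 0.0025, mini-batches of
two images, batch normalisation active, per-epoch shuffling with dropped
partial batches, and validation after every epoch with the best checkpoint
kept by validation mAP.  All randomness (initialisation, shuffling,
augmentation) derives from the config seed, so a run is reproducible
bit-for-bit on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import nn
from .evaluation import EvalSummary, summarize
from .head import assign_targets, total_loss
from .instances import InstanceSet
from .model import DMFNet, ModelConfig
from .synthetic import (
    AugmentationSpec,
    DatasetManifest,
    SyntheticScene,
    augment,
    read_annotations,
    rle_decode,
    rle_encode,
)

__all__ = ["TrainConfig", "TrainState", "iterations_per_epoch", "total_iterations",
           "train", "predict", "load_checkpoint", "write_results", "read_results",
           "evaluate", "load_split", "run_desk_smoke"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.0025
    weight_decay: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 2
    epochs: int = 200
    seed: int = 0
    gamma: float = 3.0            # mask-loss weight
    val_interval: int = 1
    augment_train: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0 or \
                not (0.0 <= self.momentum < 1.0) or self.batch_size < 1:
            raise ValueError("invalid optimiser hyperparameters")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @staticmethod
    def desk(seed: int = 0, epochs: int = 50) -> "TrainConfig":
        """CPU-scale profile: 128x128 patches, thin network, larger step size."""
        return TrainConfig(model=ModelConfig.desk(), epochs=epochs, seed=seed,
                           learning_rate=0.01, augment_train=False)

    def to_yaml(self, path: str | Path) -> None:
        # json round-trip turns tuples into plain lists for safe_dump
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(asdict(self)))))

    @staticmethod
    def from_yaml(path: str | Path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text())
        model_raw = raw.pop("model", {})
        aug_raw = raw.pop("augmentation", {})
        grid_raw = model_raw.pop("grid", {})
        from .head import GridSpec
        from .synthetic import OperatorSpec
        model = ModelConfig(**{
            **model_raw,
            "stage_blocks": tuple(model_raw.get("stage_blocks", (3, 4, 6, 3))),
            "deformable_stages": tuple(
                model_raw.get("deformable_stages", ("stage3", "stage4", "stage5"))),
            "grid": GridSpec(**grid_raw) if grid_raw else GridSpec(),
        })
        aug = AugmentationSpec(**{
            k: OperatorSpec(v["probability"], tuple(v["factor_range"]))
            for k, v in aug_raw.items()
        }) if aug_raw else AugmentationSpec()
        return TrainConfig(**raw, model=model, augmentation=aug)


@dataclass
class TrainState:
    epoch: int = 0
    iteration: int = 0
    loss_history: list[float] = field(default_factory=list)
    val_map_history: list[float] = field(default_factory=list)
    best_val_map: float = -1.0
    checkpoint_path: str | None = None


def iterations_per_epoch(n_train: int, batch_size: int) -> int:
    """Partial final batches are dropped."""
    return n_train // batch_size


def total_iterations(n_train: int, batch_size: int, epochs: int) -> int:
    return epochs * iterations_per_epoch(n_train, batch_size)


def _scene_targets(scene: SyntheticScene, grid):
    gt = InstanceSet(masks=[m for m in scene.instances])
    return assign_targets(gt, grid, scene.shape)


def train(train_scenes: list[SyntheticScene], config: TrainConfig,
          val_scenes: list[SyntheticScene] | None = None,
          out_dir: str | Path | None = None,
          log_fn=None) -> tuple[DMFNet, TrainState]:
    """Run the full training loop; returns the model and its state."""
    if not train_scenes:
        raise ValueError("training split is empty")
    ipe = iterations_per_epoch(len(train_scenes), config.batch_size)
    if ipe == 0:
        raise ValueError(
            f"batch size {config.batch_size} exceeds training set "
            f"size {len(train_scenes)}")
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    nn.seed_all(config.seed)
    model = DMFNet(config.model)
    opt = nn.SGD(model.parameters(), lr=config.learning_rate,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    grid = config.model.grid
    targets = [_scene_targets(s, grid) for s in train_scenes]
    state = TrainState()
    log_lines = []
    rng = np.random.default_rng(config.seed + 1)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_scenes))
        for step in range(ipe):
            idx = order[step * config.batch_size:(step + 1) * config.batch_size]
            batch_scenes = [train_scenes[i] for i in idx]
            if config.augment_train:
                batch_scenes = [
                    augment(s, config.augmentation,
                            seed=int(rng.integers(2**31)))
                    for s in batch_scenes
                ]
            images = np.stack([s.image for s in batch_scenes])
            cate, mask = model(images)
            loss = None
            for b, i in enumerate(idx):
                rep = total_loss(_slice_batch(cate, b), _slice_batch(mask, b),
                                 targets[i], gamma=config.gamma)
                loss = rep.total if loss is None else loss + rep.total
            loss = loss * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.iteration += 1
            state.loss_history.append(float(loss.data))
            line = {"epoch": epoch, "iteration": state.iteration,
                    "loss": float(loss.data)}
            log_lines.append(line)
            if log_fn:
                log_fn(line)
        state.epoch = epoch + 1
        if val_scenes and (epoch + 1) % config.val_interval == 0:
            val_map = _validate(model, val_scenes)
            state.val_map_history.append(val_map)
            if val_map >= state.best_val_map:
                state.best_val_map = val_map
                if out:
                    state.checkpoint_path = str(out / "best.npz")
                    save_checkpoint(model, config, state.checkpoint_path)
    if out:
        final = out / "last.npz"
        save_checkpoint(model, config, final)
        if state.checkpoint_path is None:
            state.checkpoint_path = str(final)
        (out / "train_log.jsonl").write_text(
            "\n".join(json.dumps(rec) for rec in log_lines))
    return model, state


def _slice_batch(t: nn.Tensor, b: int) -> nn.Tensor:
    """Differentiable selection of batch element b."""
    n = t.shape[0]
    sel = np.zeros((1, n))
    sel[0, b] = 1.0
    rest = t.shape[1:]
    flat = t.reshape(n, int(np.prod(rest)))
    return (nn.Tensor(sel) @ flat).reshape(*rest)


def _validate(model: DMFNet, scenes: list[SyntheticScene]) -> float:
    preds, gts = [], []
    for s in scenes:
        preds.append(model.predict_image(s.image))
        gts.append(InstanceSet(masks=list(s.instances)))
    return summarize(preds, gts).mAP


def save_checkpoint(model: DMFNet, config: TrainConfig, path: str | Path) -> None:
    state = model.named_state()
    state["__config__"] = np.frombuffer(
        json.dumps(_config_dict(config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d


def load_checkpoint(path: str | Path) -> tuple[DMFNet, TrainConfig]:
    with np.load(path) as data:
        raw = {k: data[k] for k in data.files}
    cfg_raw = json.loads(bytes(raw.pop("__config__")).decode())
    from .head import GridSpec
    from .synthetic import OperatorSpec
    model_raw = cfg_raw.pop("model")
    aug_raw = cfg_raw.pop("augmentation")
    grid_raw = model_raw.pop("grid")
    config = TrainConfig(
        **cfg_raw,
        model=ModelConfig(**{
            **model_raw,
            "stage_blocks": tuple(model_raw["stage_blocks"]),
            "deformable_stages": tuple(model_raw["deformable_stages"]),
            "grid": GridSpec(**grid_raw),
        }),
        augmentation=AugmentationSpec(**{
            k: OperatorSpec(v["probability"], tuple(v["factor_range"]))
            for k, v in aug_raw.items()
        }),
    )
    model = DMFNet(config.model)
    model.load_state(raw)
    return model, config


# ---------------------------------------------------------------------------
# Inference and evaluation entry points
# ---------------------------------------------------------------------------


def predict(model: DMFNet, images: list[np.ndarray]) -> list[InstanceSet]:
    """Order-preserving per-image inference."""
    return [model.predict_image(img) for img in images]


def write_results(preds_per_image: list[InstanceSet], image_ids: list[int],
                  path: str | Path) -> None:
    """COCO-style result records with RLE masks and scores."""
    records = []
    for img_id, inst in zip(image_ids, preds_per_image):
        for p in inst:
            records.append({
                "image_id": img_id, "category_id": p.category,
                "segmentation": rle_encode(p.mask), "score": p.score,
            })
    Path(path).write_text(json.dumps(records))


def read_results(path: str | Path) -> dict[int, InstanceSet]:
    raw = json.loads(Path(path).read_text())
    out: dict[int, InstanceSet] = {}
    for rec in raw:
        inst = out.setdefault(rec["image_id"],
                              InstanceSet(masks=[], scores=[], categories=[]))
        inst.masks.append(rle_decode(rec["segmentation"]))
        inst.scores.append(float(rec["score"]))
        inst.categories.append(int(rec["category_id"]))
    return out


def evaluate(result_path: str | Path, gt_path: str | Path) -> EvalSummary:
    """Score a result file against a COCO-dialect ground-truth file."""
    gt_doc = json.loads(Path(gt_path).read_text())
    gts_by_id: dict[int, InstanceSet] = {
        rec["id"]: InstanceSet(masks=[], categories=[]) for rec in gt_doc["images"]
    }
    for ann in gt_doc["annotations"]:
        inst = gts_by_id[ann["image_id"]]
        inst.masks.append(rle_decode(ann["segmentation"]))
        inst.categories.append(int(ann["category_id"]))
    results = read_results(result_path)
    preds, gts = [], []
    for img_id in sorted(gts_by_id):
        gts.append(gts_by_id[img_id])
        preds.append(results.get(img_id, InstanceSet(masks=[], scores=[])))
    return summarize(preds, gts)


def run_desk_smoke(seed: int = 0, n_train: int = 16, n_val: int = 4,
                   epochs: int = 50, n_nuclei: int = 8,
                   image_size: int = 128) -> dict:
    """End-to-end desk-scale run on synthetic patches.

    Generates small scenes, trains the thin desk model, and reports the
    training-loss decrease and the held-out AP50 before and after training.
    Scene content and all training randomness derive from ``seed``.
    """
    from .synthetic import ShapeRanges, generate_scene

    base = (seed % 100_000) * 1000
    ranges = ShapeRanges(semi_axis=(8.0, 14.0))
    train_scenes = [
        generate_scene(image_size, image_size, n_nuclei, ranges,
                       seed=base + 100 + i, scene_id=i)
        for i in range(n_train)
    ]
    val_scenes = [
        generate_scene(image_size, image_size, n_nuclei, ranges,
                       seed=base + 500 + i, scene_id=1000 + i)
        for i in range(n_val)
    ]
    config = TrainConfig.desk(seed=seed, epochs=epochs)
    gts = [InstanceSet(masks=list(s.instances)) for s in val_scenes]

    nn.seed_all(config.seed)
    untrained = DMFNet(config.model)
    summary0 = summarize([untrained.predict_image(s.image) for s in val_scenes], gts)

    model, state = train(train_scenes, config)
    summary1 = summarize([model.predict_image(s.image) for s in val_scenes], gts)

    losses = state.loss_history
    k = min(10, len(losses))
    first, last = float(np.mean(losses[:k])), float(np.mean(losses[-k:]))
    return {
        "n_iterations": state.iteration,
        "loss_first": first,
        "loss_last": last,
        "loss_ratio": last / first,
        "ap50_untrained": summary0.AP50,
        "ap50_trained": summary1.AP50,
        "map_trained": summary1.mAP,
        "mar_trained": summary1.mAR,
    }


def load_split(data_dir: str | Path, manifest: DatasetManifest,
               split: str) -> list[SyntheticScene]:
    """Materialise one manifest split as in-memory scenes."""
    data_dir = Path(data_dir)
    ann = read_annotations(data_dir / "annotations.json")
    scenes = []
    for rec in manifest.split(split):
        img = np.asarray(Image.open(data_dir / rec.image_path).convert("RGB"))
        inst = ann.get(rec.image_path, InstanceSet(masks=[]))
        scenes.append(SyntheticScene(
            image=img, instances=[m for m in inst.masks], nucleus_params=[],
            seed=0, scene_id=rec.scene_id, grid_pos=rec.grid_pos))
    return scenes
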