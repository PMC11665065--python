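"""Synthetic H&E-style nucleus scenes with exact instance ground truth.

Real H&E tissue patches show hundreds of roughly elliptical, frequently
touching nuclei (hematoxylin, purple) over pink eosin-stained stroma.  The
generator emulates those gross statistics — not the histology — so that
every downstream stage (training, decoding, evaluation) can be exercised
without external data.  Each nucleus is a rotated ellipse whose boundary is
modulated by a low-frequency radial Fourier perturbation; overlaps are
resolved by draw order (later nuclei overwrite earlier ones), so the
per-pixel instance labelling is exclusive.  Everything is a pure function
of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .instances import InstanceSet

__all__ = [
    "ShapeRanges",
    "NucleusParams",
    "SyntheticScene",
    "OperatorSpec",
    "AugmentationSpec",
    "DatasetManifest",
    "ManifestRecord",
    "generate_scene",
    "nucleus_membership",
    "augment",
    "tile",
    "make_manifest",
    "write_annotations",
    "read_annotations",
    "rle_encode",
    "rle_decode",
]


# ---------------------------------------------------------------------------
# Scene model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeRanges:
    """Sampling ranges for nucleus geometry and stain."""

    semi_axis: tuple[float, float] = (6.0, 16.0)
    rotation: tuple[float, float] = (0.0, np.pi)
    perturb_amplitude: tuple[float, float] = (0.05, 0.25)
    stain_intensity: tuple[float, float] = (0.55, 1.0)
    n_harmonics: int = 4


@dataclass(frozen=True)
class NucleusParams:
    """Everything needed to re-evaluate one nucleus's region analytically."""

    center: tuple[float, float]          # (cy, cx), pixels
    axes: tuple[float, float]            # semi-axes (a, b), pixels
    rotation: float                      # radians
    amplitude: float                     # radial perturbation amplitude
    harmonics: tuple[float, ...]         # cos/sin coefficients, unit-normalised
    intensity: float                     # stain darkness in (0, 1]


@dataclass
class SyntheticScene:
    image: np.ndarray                    # (H, W, 3) uint8
    instances: list[np.ndarray]          # list of (H, W) bool masks
    nucleus_params: list[NucleusParams]
    seed: int
    scene_id: int = 0
    grid_pos: tuple[int, int] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def _radial_profile(theta: np.ndarray, params: NucleusParams) -> np.ndarray:
    """rho(theta) = 1 + amplitude * f(theta) with |f| <= 1."""
    coefs = np.asarray(params.harmonics)
    n = coefs.size // 2
    f = np.zeros_like(theta)
    for m in range(n):
        f += coefs[2 * m] * np.cos((m + 2) * theta)
        f += coefs[2 * m + 1] * np.sin((m + 2) * theta)
    return 1.0 + params.amplitude * f


def nucleus_membership(params: NucleusParams, height: int, width: int) -> np.ndarray:
    """Boolean mask of the perturbed ellipse on an image of the given size."""
    cy, cx = params.center
    a, b = params.axes
    rmax = max(a, b) * (1.0 + params.amplitude) + 1.0
    y0 = max(int(np.floor(cy - rmax)), 0)
    y1 = min(int(np.ceil(cy + rmax)) + 1, height)
    x0 = max(int(np.floor(cx - rmax)), 0)
    x1 = min(int(np.ceil(cx + rmax)) + 1, width)
    mask = np.zeros((height, width), dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    c, s = np.cos(params.rotation), np.sin(params.rotation)
    u = c * dx + s * dy          # along semi-axis a
    v = -s * dx + c * dy         # along semi-axis b
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    theta = np.arctan2(v, u)
    mask[y0:y1, x0:x1] = r <= _radial_profile(theta, params)
    return mask


def _sample_nucleus(rng: np.random.Generator, height: int, width: int,
                    ranges: ShapeRanges) -> NucleusParams:
    a = rng.uniform(*ranges.semi_axis)
    b = rng.uniform(*ranges.semi_axis)
    margin = max(a, b)
    cy = rng.uniform(margin, height - margin) if height > 2 * margin else height / 2
    cx = rng.uniform(margin, width - margin) if width > 2 * margin else width / 2
    coefs = rng.normal(0.0, 1.0, 2 * ranges.n_harmonics)
    norm = np.abs(coefs).sum()
    if norm > 0:
        coefs = coefs / norm
    return NucleusParams(
        center=(float(cy), float(cx)),
        axes=(float(a), float(b)),
        rotation=float(rng.uniform(*ranges.rotation)),
        amplitude=float(rng.uniform(*ranges.perturb_amplitude)),
        harmonics=tuple(float(c) for c in coefs),
        intensity=float(rng.uniform(*ranges.stain_intensity)),
    )


_BACKGROUND = np.array([0.91, 0.78, 0.85])   # eosin-pink stroma
_NUCLEUS = np.array([0.42, 0.22, 0.55])      # hematoxylin purple


def generate_scene(width: int, height: int, n_nuclei: int,
                   shape_ranges: ShapeRanges | None = None,
                   seed: int = 0, scene_id: int = 0) -> SyntheticScene:
    """Render a scene of perturbed-ellipse nuclei over textured background.

    Overlapping nuclei are resolved by draw order: a later nucleus
    overwrites earlier ones where they intersect, so each pixel carries at
    most one instance id.  A placement that would erase an already-drawn
    nucleus entirely is resampled (bounded retries), keeping every returned
    mask non-empty.
    """
    if width < 64 or height < 64:
        raise ValueError(f"image dimensions must be >= 64, got {width}x{height}")
    if n_nuclei < 0:
        raise ValueError(f"n_nuclei must be >= 0, got {n_nuclei}")
    ranges = shape_ranges or ShapeRanges()
    rng = np.random.default_rng(seed)

    label = np.full((height, width), -1, dtype=np.int32)
    counts: list[int] = []
    params: list[NucleusParams] = []
    for idx in range(n_nuclei):
        for _attempt in range(100):
            cand = _sample_nucleus(rng, height, width, ranges)
            region = nucleus_membership(cand, height, width)
            if not region.any():
                continue
            covered = label[region]
            covered = covered[covered >= 0]
            if covered.size:
                lost = np.bincount(covered, minlength=len(counts))
                if any(counts[i] - lost[i] <= 0 for i in np.nonzero(lost)[0]):
                    continue
            break
        else:
            raise RuntimeError("could not place a nucleus without erasing another")
        prev = label[region]
        for i in np.unique(prev[prev >= 0]):
            counts[i] -= int((prev == i).sum())
        label[region] = idx
        counts.append(int(region.sum()))
        params.append(cand)

    # background: eosin tone with low-frequency texture
    tex = gaussian_filter(rng.normal(0.0, 1.0, (height, width)), sigma=12)
    if tex.std() > 0:
        tex = tex / (6.0 * tex.std())
    img = _BACKGROUND[None, None, :] + tex[..., None] * np.array([0.05, 0.06, 0.04])

    # nuclei: hematoxylin tone scaled by per-nucleus stain intensity
    for idx, p in enumerate(params):
        sel = label == idx
        shade = _NUCLEUS * p.intensity + _BACKGROUND * (1.0 - p.intensity) * 0.35
        img[sel] = shade[None, :]
    grain = rng.normal(0.0, 0.015, (height, width, 1))
    img = np.clip(img + grain, 0.0, 1.0)
    image = (img * 255.0 + 0.5).astype(np.uint8)

    instances = [label == i for i in range(len(params))]
    return SyntheticScene(image=image, instances=instances,
                          nucleus_params=params, seed=seed, scene_id=scene_id)


# ---------------------------------------------------------------------------
# Photometric augmentation channel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperatorSpec:
    probability: float
    factor_range: tuple[float, float]

    def validate(self, name: str) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"{name}: probability {self.probability} not in [0, 1]")
        lo, hi = self.factor_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError(f"{name}: invalid factor range {self.factor_range}")


@dataclass(frozen=True)
class AugmentationSpec:
    """Five photometric operators, each applied independently with its probability."""

    brightness_enhancement: OperatorSpec = OperatorSpec(0.3, (1.1, 1.4))
    contrast_reduction: OperatorSpec = OperatorSpec(0.3, (0.5, 0.9))
    gaussian_noise: OperatorSpec = OperatorSpec(0.3, (4.0, 12.0))
    impulse_noise: OperatorSpec = OperatorSpec(0.3, (0.002, 0.02))
    poisson_noise: OperatorSpec = OperatorSpec(0.3, (30.0, 90.0))

    def validate(self) -> None:
        for name in ("brightness_enhancement", "contrast_reduction",
                     "gaussian_noise", "impulse_noise", "poisson_noise"):
            getattr(self, name).validate(name)

    @staticmethod
    def disabled() -> "AugmentationSpec":
        z = OperatorSpec(0.0, (1.0, 1.0))
        return AugmentationSpec(z, z, z, z, z)


def augment(scene: SyntheticScene, spec: AugmentationSpec, seed: int) -> SyntheticScene:
    """Apply the photometric channel; instance masks are untouched.

    brightness: multiplicative gain then clip; contrast reduction: blend
    toward the image mean; gaussian noise: additive, sigma in 8-bit units;
    impulse noise: salt and pepper at a sampled pixel fraction; poisson
    noise: photon shot noise in linear intensity at a sampled photon scale.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    img = scene.image.astype(np.float64)

    op = spec.brightness_enhancement
    if rng.uniform() < op.probability:
        img = img * rng.uniform(*op.factor_range)

    op = spec.contrast_reduction
    if rng.uniform() < op.probability:
        f = rng.uniform(*op.factor_range)
        img = img.mean() + f * (img - img.mean())

    op = spec.gaussian_noise
    if rng.uniform() < op.probability:
        img = img + rng.normal(0.0, rng.uniform(*op.factor_range), img.shape)

    op = spec.impulse_noise
    if rng.uniform() < op.probability:
        frac = rng.uniform(*op.factor_range)
        h, w, _ = img.shape
        hits = rng.uniform(size=(h, w)) < frac
        salt = rng.uniform(size=(h, w)) < 0.5
        img[hits & salt] = 255.0
        img[hits & ~salt] = 0.0

    op = spec.poisson_noise
    if rng.uniform() < op.probability:
        lam = rng.uniform(*op.factor_range)
        img = rng.poisson(np.clip(img, 0, 255) / 255.0 * lam) / lam * 255.0

    image = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return SyntheticScene(image=image,
                          instances=[m.copy() for m in scene.instances],
                          nucleus_params=list(scene.nucleus_params),
                          seed=scene.seed, scene_id=scene.scene_id,
                          grid_pos=scene.grid_pos)


# ---------------------------------------------------------------------------
# Tiling and dataset bookkeeping
# ---------------------------------------------------------------------------


def tile(scene: SyntheticScene, patch_size: int,
         min_fragment_area: int = 10) -> list[SyntheticScene]:
    """Cut a scene into non-overlapping patches, row-major.

    Instance masks are clipped to each patch; clipped fragments smaller
    than ``min_fragment_area`` pixels are dropped.
    """
    h, w = scene.shape
    if h % patch_size:
        raise ValueError(f"height {h} not divisible by patch size {patch_size}")
    if w % patch_size:
        raise ValueError(f"width {w} not divisible by patch size {patch_size}")
    patches: list[SyntheticScene] = []
    for r in range(h // patch_size):
        for c in range(w // patch_size):
            ys = slice(r * patch_size, (r + 1) * patch_size)
            xs = slice(c * patch_size, (c + 1) * patch_size)
            masks, params = [], []
            for m, p in zip(scene.instances, scene.nucleus_params):
                frag = m[ys, xs]
                if frag.sum() < min_fragment_area:
                    continue
                masks.append(frag.copy())
                params.append(NucleusParams(
                    center=(p.center[0] - r * patch_size,
                            p.center[1] - c * patch_size),
                    axes=p.axes, rotation=p.rotation, amplitude=p.amplitude,
                    harmonics=p.harmonics, intensity=p.intensity))
            patches.append(SyntheticScene(
                image=scene.image[ys, xs].copy(), instances=masks,
                nucleus_params=params, seed=scene.seed,
                scene_id=scene.scene_id, grid_pos=(r, c)))
    return patches


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    annotation: str
    split: str
    scene_id: int
    grid_pos: tuple[int, int]


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def split(self, name: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == name]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            [asdict(r) for r in self.records], indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "DatasetManifest":
        raw = json.loads(Path(path).read_text())
        return DatasetManifest(records=[
            ManifestRecord(image_path=r["image_path"], annotation=r["annotation"],
                           split=r["split"], scene_id=r["scene_id"],
                           grid_pos=tuple(r["grid_pos"]))
            for r in raw
        ])


def patch_name(patch: SyntheticScene) -> str:
    r, c = patch.grid_pos if patch.grid_pos is not None else (0, 0)
    return f"scene{patch.scene_id:04d}_r{r}_c{c}.png"


def make_manifest(patches: list[SyntheticScene],
                  split_scene_counts: tuple[int, int, int],
                  seed: int = 0) -> DatasetManifest:
    """Assign whole source scenes to train/val/test splits.

    Scenes are shuffled by the seed and assigned to splits by count; every
    patch of a scene inherits the scene's split, so no scene straddles a
    split boundary.
    """
    scene_ids = sorted({p.scene_id for p in patches})
    n_train, n_val, n_test = split_scene_counts
    if n_train + n_val + n_test != len(scene_ids):
        raise ValueError(
            f"split counts {split_scene_counts} do not sum to "
            f"{len(scene_ids)} source scenes")
    order = list(scene_ids)
    np.random.default_rng(seed).shuffle(order)
    split_of: dict[int, str] = {}
    for i, sid in enumerate(order):
        if i < n_train:
            split_of[sid] = "train"
        elif i < n_train + n_val:
            split_of[sid] = "val"
        else:
            split_of[sid] = "test"
    records = [
        ManifestRecord(
            image_path=patch_name(p),
            annotation="annotations.json",
            split=split_of[p.scene_id],
            scene_id=p.scene_id,
            grid_pos=p.grid_pos or (0, 0),
        )
        for p in patches
    ]
    return DatasetManifest(records=records)


# ---------------------------------------------------------------------------
# COCO-dialect annotations (uncompressed RLE, column-major)
# ---------------------------------------------------------------------------


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO run-length encoding (column-major, zero-run first)."""
    m = np.asarray(mask, dtype=np.uint8).flatten(order="F")
    if m.size == 0:
        counts = [0]
    else:
        boundaries = np.nonzero(np.diff(m))[0] + 1
        idx = np.concatenate([[0], boundaries, [m.size]])
        runs = np.diff(idx).tolist()
        counts = ([0] + runs) if m[0] == 1 else runs
    return {"size": [int(mask.shape[0]), int(mask.shape[1])],
            "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    total = int(np.sum(counts))
    if total != h * w:
        raise ValueError(f"RLE counts sum to {total}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def write_annotations(patches: list[SyntheticScene], out_dir: str | Path) -> Path:
    """Write patch PNGs plus a COCO-dialect ``annotations.json``.

    Masks are stored as uncompressed RLE; the single category is "nucleus".
    Returns the annotation file path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    ann_id = 1
    for img_id, patch in enumerate(patches, start=1):
        name = patch_name(patch)
        Image.fromarray(patch.image).save(out / name)
        h, w = patch.shape
        images.append({"id": img_id, "file_name": name, "width": w, "height": h})
        for mask in patch.instances:
            ys, xs = np.nonzero(mask)
            bbox = [int(xs.min()), int(ys.min()),
                    int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)] \
                if ys.size else [0, 0, 0, 0]
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": 1,
                "segmentation": rle_encode(mask),
                "area": int(mask.sum()), "bbox": bbox, "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "nucleus"}],
    }
    path = out / "annotations.json"
    path.write_text(json.dumps(doc))
    return path


def read_annotations(path: str | Path) -> dict[str, InstanceSet]:
    """Read a COCO-dialect file back into per-image instance sets."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed annotation file {path}: {e}") from e
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"annotation file {path} missing '{key}' section")
    by_image: dict[int, InstanceSet] = {}
    names: dict[int, str] = {}
    for rec in doc["images"]:
        by_image[rec["id"]] = InstanceSet(masks=[], categories=[])
        names[rec["id"]] = rec["file_name"]
    for i, ann in enumerate(doc["annotations"]):
        try:
            inst = by_image[ann["image_id"]]
            inst.masks.append(rle_decode(ann["segmentation"]))
            inst.categories.append(int(ann["category_id"]))
        except (KeyError, ValueError) as e:
            raise ValueError(f"bad annotation record {i} in {path}: {e}") from e
    return {names[i]: s for i, s in by_image.items()}
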