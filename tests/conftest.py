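import numpy as np
import pytest

from dmfnet.instances import InstanceSet
from dmfnet.synthetic import ShapeRanges, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 128x128 scene with a handful of mid-sized nuclei."""
    return generate_scene(
        128, 128, 8, ShapeRanges(semi_axis=(8.0, 14.0)), seed=7, scene_id=0
    )


@pytest.fixture(scope="session")
def tiled_scene():
    """A 500x500 scene for tiling checks (divisible by 125 and 250)."""
    return generate_scene(
        500, 500, 40, ShapeRanges(semi_axis=(7.0, 14.0)), seed=11, scene_id=3
    )


def as_instance_set(scene) -> InstanceSet:
    return InstanceSet(masks=list(scene.instances))


def random_instance_fixture(rng, shape=(48, 48), n_gt=4, n_pred=6):
    """A random (predictions, ground truths) pair of blob masks with scores."""
    h, w = shape
    def blob():
        cy, cx = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
        r = rng.uniform(3, 7)
        yy, xx = np.mgrid[0:h, 0:w]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    gts = InstanceSet(masks=[blob() for _ in range(n_gt)])
    preds = InstanceSet(masks=[], scores=[])
    for _ in range(n_pred):
        if rng.uniform() < 0.6 and len(gts.masks) > 0:
            # jittered copy of a ground truth
            base = gts.masks[rng.integers(len(gts.masks))]
            shift = rng.integers(-3, 4, size=2)
            m = np.roll(np.roll(base, shift[0], axis=0), shift[1], axis=1)
        else:
            m = blob()
        preds.masks.append(m)
        preds.scores.append(float(rng.uniform(0.05, 1.0)))
    return preds, gts
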