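"""Synthetic scene generation, augmentation, tiling and annotation round trips."""

import numpy as np
import pytest

from dmfnet.synthetic import (
    AugmentationSpec,
    DatasetManifest,
    OperatorSpec,
    ShapeRanges,
    SyntheticScene,
    augment,
    generate_scene,
    make_manifest,
    nucleus_membership,
    read_annotations,
    rle_decode,
    rle_encode,
    tile,
    write_annotations,
)


def independent_membership(p, h, w):
    """Pixel-by-pixel re-derivation of a nucleus region from its parameters."""
    mask = np.zeros((h, w), dtype=bool)
    cy, cx = p.center
    a, b = p.axes
    for y in range(h):
        for x in range(w):
            dy, dx = y - cy, x - cx
            if dy * dy + dx * dx > (max(a, b) * (1 + p.amplitude) + 1) ** 2:
                continue
            u = np.cos(p.rotation) * dx + np.sin(p.rotation) * dy
            v = -np.sin(p.rotation) * dx + np.cos(p.rotation) * dy
            r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
            theta = np.arctan2(v, u)
            rho = 1.0
            for m in range(len(p.harmonics) // 2):
                rho += p.amplitude * (
                    p.harmonics[2 * m] * np.cos((m + 2) * theta)
                    + p.harmonics[2 * m + 1] * np.sin((m + 2) * theta)
                )
            if r <= rho:
                mask[y, x] = True
    return mask


class TestGenerateScene:
    def test_zero_instances(self):
        scene = generate_scene(256, 256, 0, seed=7)
        assert scene.instances == []
        assert scene.image.shape == (256, 256, 3)

    def test_bit_identical_under_fixed_seed(self):
        a = generate_scene(256, 256, 30, seed=7)
        b = generate_scene(256, 256, 30, seed=7)
        assert np.array_equal(a.image, b.image)
        assert len(a.instances) == len(b.instances)
        for ma, mb in zip(a.instances, b.instances):
            assert np.array_equal(ma, mb)
        assert a.nucleus_params == b.nucleus_params

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_scene(32, 256, 5)
        with pytest.raises(ValueError):
            generate_scene(256, 256, -1)

    def test_masks_match_analytic_regions_minus_occlusion(self):
        """Each mask equals its analytically recomputed region minus the
        union of later-drawn regions (draw-order overlap resolution)."""
        scene = generate_scene(128, 128, 10,
                               ShapeRanges(semi_axis=(6.0, 12.0)), seed=3)
        h, w = scene.shape
        regions = [independent_membership(p, h, w) for p in scene.nucleus_params]
        for i, mask in enumerate(scene.instances):
            expected = regions[i].copy()
            for later in regions[i + 1:]:
                expected &= ~later
            assert np.array_equal(mask, expected)

    def test_mask_area_close_to_ellipse_area(self):
        scene = generate_scene(256, 256, 6,
                               ShapeRanges(semi_axis=(8.0, 14.0)), seed=5)
        for mask, p in zip(scene.instances, scene.nucleus_params):
            a, b = p.axes
            ellipse = np.pi * a * b
            hi = ellipse * (1 + p.amplitude) ** 2 + 4 * np.pi * max(a, b)
            assert mask.sum() <= hi

    def test_pixel_exclusivity(self, small_scene):
        total = np.zeros(small_scene.shape, dtype=int)
        for m in small_scene.instances:
            assert m.sum() > 0
            total += m.astype(int)
        assert total.max() <= 1
        fg = sum(int(m.sum()) for m in small_scene.instances)
        assert fg == int((total > 0).sum())


class TestAugment:
    def test_zero_probability_is_identity(self, small_scene):
        out = augment(small_scene, AugmentationSpec.disabled(), seed=1)
        assert np.array_equal(out.image, small_scene.image)

    def test_brightness_factor_per_pixel(self, small_scene):
        f = 1.3
        spec = AugmentationSpec.disabled()
        spec = AugmentationSpec(
            brightness_enhancement=OperatorSpec(1.0, (f, f)),
            contrast_reduction=spec.contrast_reduction,
            gaussian_noise=spec.gaussian_noise,
            impulse_noise=spec.impulse_noise,
            poisson_noise=spec.poisson_noise,
        )
        out = augment(small_scene, spec, seed=4)
        expected = np.clip(small_scene.image.astype(float) * f, 0, 255).astype(np.uint8)
        assert np.array_equal(out.image, expected)

    def test_masks_never_change(self, small_scene):
        spec = AugmentationSpec(
            brightness_enhancement=OperatorSpec(1.0, (1.1, 1.4)),
            contrast_reduction=OperatorSpec(1.0, (0.5, 0.9)),
            gaussian_noise=OperatorSpec(1.0, (4.0, 12.0)),
            impulse_noise=OperatorSpec(1.0, (0.002, 0.02)),
            poisson_noise=OperatorSpec(1.0, (30.0, 90.0)),
        )
        out = augment(small_scene, spec, seed=2)
        assert not np.array_equal(out.image, small_scene.image)
        for a, b in zip(out.instances, small_scene.instances):
            assert np.array_equal(a, b)

    def test_invalid_spec_rejected(self, small_scene):
        bad = AugmentationSpec(
            brightness_enhancement=OperatorSpec(1.5, (1.0, 1.2)),
            contrast_reduction=OperatorSpec(0.0, (1.0, 1.0)),
            gaussian_noise=OperatorSpec(0.0, (1.0, 1.0)),
            impulse_noise=OperatorSpec(0.0, (1.0, 1.0)),
            poisson_noise=OperatorSpec(0.0, (1.0, 1.0)),
        )
        with pytest.raises(ValueError):
            augment(small_scene, bad, seed=0)


class TestTile:
    def test_patch_count_and_order(self, tiled_scene):
        patches = tile(tiled_scene, 125)
        assert len(patches) == 16
        assert [p.grid_pos for p in patches[:5]] == [
            (0, 0), (0, 1), (0, 2), (0, 3), (1, 0)
        ]

    def test_identity_tiling(self, small_scene):
        patches = tile(small_scene, 128)
        assert len(patches) == 1
        assert np.array_equal(patches[0].image, small_scene.image)
        for a, b in zip(patches[0].instances, small_scene.instances):
            assert np.array_equal(a, b)

    def test_non_divisible_error_names_dimension(self, small_scene):
        with pytest.raises(ValueError, match="height 128"):
            tile(small_scene, 100)

    def test_fragment_dropping_and_conservation(self, tiled_scene):
        min_area = 10
        patches = tile(tiled_scene, 125, min_fragment_area=min_area)
        kept = sum(int(m.sum()) for p in patches for m in p.instances)
        scene_fg = sum(int(m.sum()) for m in tiled_scene.instances)
        dropped = scene_fg - kept
        assert dropped >= 0
        for p in patches:
            for m in p.instances:
                assert m.sum() >= min_area
        # every dropped pixel belongs to a fragment below the threshold
        max_possible_drop = 0
        for m in tiled_scene.instances:
            for r in range(4):
                for c in range(4):
                    frag = m[r * 125:(r + 1) * 125, c * 125:(c + 1) * 125]
                    if 0 < frag.sum() < min_area:
                        max_possible_drop += int(frag.sum())
        assert dropped == max_possible_drop


class TestManifest:
    @staticmethod
    def fake_patches(n_scenes, per_scene=16):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        out = []
        for sid in range(n_scenes):
            for k in range(per_scene):
                out.append(SyntheticScene(
                    image=img, instances=[], nucleus_params=[], seed=0,
                    scene_id=sid, grid_pos=(k // 4, k % 4)))
        return out

    def test_patch_split_counts(self):
        patches = self.fake_patches(30)
        manifest = make_manifest(patches, (22, 2, 6), seed=9)
        assert len(manifest.split("train")) == 352
        assert len(manifest.split("val")) == 32
        assert len(manifest.split("test")) == 96

    def test_scene_never_straddles_splits(self):
        manifest = make_manifest(self.fake_patches(10), (6, 2, 2), seed=1)
        seen: dict[int, str] = {}
        for rec in manifest.records:
            assert seen.setdefault(rec.scene_id, rec.split) == rec.split

    def test_single_scene_all_train(self):
        manifest = make_manifest(self.fake_patches(1), (1, 0, 0), seed=0)
        assert {r.split for r in manifest.records} == {"train"}

    def test_deterministic_under_seed(self):
        a = make_manifest(self.fake_patches(8), (5, 1, 2), seed=3)
        b = make_manifest(self.fake_patches(8), (5, 1, 2), seed=3)
        assert a.records == b.records

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            make_manifest(self.fake_patches(5), (3, 1, 3), seed=0)

    def test_json_round_trip(self, tmp_path):
        manifest = make_manifest(self.fake_patches(4), (2, 1, 1), seed=2)
        manifest.to_json(tmp_path / "m.json")
        back = DatasetManifest.from_json(tmp_path / "m.json")
        assert back.records == manifest.records


class TestAnnotations:
    def test_rle_round_trip_with_hole(self):
        yy, xx = np.mgrid[0:40, 0:40]
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        annulus = (r2 <= 15**2) & (r2 >= 7**2)
        assert np.array_equal(rle_decode(rle_encode(annulus)), annulus)

    def test_rle_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            rle_decode({"size": [4, 4], "counts": [3]})

    def test_write_read_round_trip(self, tmp_path, small_scene):
        patches = tile(small_scene, 64, min_fragment_area=5)
        path = write_annotations(patches, tmp_path)
        back = read_annotations(path)
        assert len(back) == len(patches)
        for p in patches:
            from dmfnet.synthetic import patch_name
            inst = back[patch_name(p)]
            assert len(inst) == len(p.instances)
            for a, b in zip(inst.masks, p.instances):
                assert np.array_equal(a, b)

    def test_empty_patch_list(self, tmp_path):
        path = write_annotations([], tmp_path)
        assert read_annotations(path) == {}

    def test_malformed_file_reports_context(self, tmp_path):
        bad = tmp_path / "annotations.json"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_annotations(bad)
        bad.write_text('{"images": []}')
        with pytest.raises(ValueError, match="missing"):
            read_annotations(bad)
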