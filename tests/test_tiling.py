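"""Tiling geometry, half-overlap subsampling, augmentation, manifests."""

import numpy as np
import pytest

from pdacwsi import synthetic, tiling
from pdacwsi.tiling import (augment, build_balanced_manifest,
                            subsample_half_overlap, tile_slide)


def _img(h, w, seed=0):
    return np.random.default_rng(seed).integers(0, 255, (h, w, 3), dtype=np.uint8)


class TestTileSlide:
    def test_grid_count_4096x2048(self):
        recs = tile_slide(_img(2048, 4096), 1024, 1024)
        assert len(recs) == 8  # 4 x 2

    def test_identity_case(self):
        recs = tile_slide(_img(1024, 1024), 1024, 1024)
        assert len(recs) == 1 and recs[0].x == recs[0].y == 0

    def test_overlapping_stride_offset_enumeration(self):
        """stride 512 on 4096^2: offsets 0,512,...,3072 per axis -> 49."""
        recs = tile_slide(_img(4096, 4096, 1), 1024, 512)
        expected = [(x, y) for y in range(0, 3073, 512)
                    for x in range(0, 3073, 512)]
        assert [(r.x, r.y) for r in recs] == expected
        assert len(recs) == 49

    def test_small_slide_drop_gives_empty(self):
        assert tile_slide(_img(100, 100), 1024, 1024, "drop") == []

    def test_pad_policy_covers_edges(self):
        recs = tile_slide(_img(300, 300), 256, 256, edge_policy="pad")
        assert len(recs) == 4
        assert all(r.image.shape == (256, 256, 3) for r in recs)

    def test_round_trip_recrops_exactly(self, small_slide):
        recs = tile_slide(small_slide, 256, 256)
        for r in recs:
            assert np.array_equal(
                r.image, small_slide.image[r.y:r.y + 256, r.x:r.x + 256])

    def test_labels_follow_tumor_fraction(self, small_slide, normal_slide):
        recs = tile_slide(small_slide, 256, 256)
        assert any(r.label == "carcinoma" for r in recs)
        lo, hi = tiling.LABEL_THRESHOLDS
        for r in recs:
            if r.label == "carcinoma":
                assert r.tumor_fraction >= hi
            elif r.label == "normal":
                assert r.tumor_fraction <= lo
        assert all(r.label == "normal" for r in tile_slide(normal_slide, 256, 256))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            tile_slide(_img(512, 512), 0, 1)
        with pytest.raises(ValueError):
            tile_slide(_img(512, 512), 256, 256, edge_policy="wrap")


class TestSubsampleHalfOverlap:
    def test_1024_patch_yields_64_tiles(self):
        tiles, offs = subsample_half_overlap(_img(1024, 1024))
        assert len(tiles) == 64
        assert offs == [(x, y) for y in range(0, 1024, 128)
                        for x in range(0, 1024, 128)]
        assert all(t.shape == (256, 256, 3) for t in tiles)

    def test_256_input_yields_4_tiles(self):
        tiles, offs = subsample_half_overlap(_img(256, 256))
        assert len(tiles) == 4
        assert offs == [(0, 0), (128, 0), (0, 128), (128, 128)]

    def test_first_tile_is_topleft_crop(self):
        img = _img(1024, 1024, 3)
        tiles, _ = subsample_half_overlap(img)
        assert np.array_equal(tiles[0], img[:256, :256])

    def test_overhang_is_reflection_padded(self):
        img = _img(256, 256, 4)
        tiles, offs = subsample_half_overlap(img)
        last = tiles[-1]  # offset (128,128): right/bottom halves mirrored
        assert np.array_equal(last[:128, :128], img[128:, 128:])
        assert np.array_equal(last[:128, 128:], img[128:, :127:-1])

    def test_mask_geometry_identical(self):
        mask = (np.random.default_rng(0).random((1024, 1024)) > 0.5).astype(np.uint8)
        tiles, offs = subsample_half_overlap(mask)
        assert len(tiles) == 64 and tiles[0].shape == (256, 256)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            subsample_half_overlap(_img(256, 512))
        with pytest.raises(ValueError):
            subsample_half_overlap(_img(200, 200))


class TestAugment:
    def _rec(self, seed=0, n=8):
        return tiling.PatchRecord("s", 0, 0, n, _img(n, n, seed), label="carcinoma")

    def test_five_ops_give_five_records(self):
        out = augment(self._rec())
        assert len(out) == 5
        assert {r.augmentation_tag for r in out} == set(tiling.AUG_OPS)
        assert all(r.label == "carcinoma" for r in out)

    def test_rot180_is_involution(self):
        r = self._rec(1)
        once = augment(r, ["rot180"])[0]
        twice = augment(once, ["rot180"])[0]
        assert np.array_equal(twice.image, r.image)

    def test_fliph_then_flipv_equals_rot180(self):
        r = self._rec(2)
        a = augment(augment(r, ["fliph"])[0], ["flipv"])[0]
        b = augment(r, ["rot180"])[0]
        assert np.array_equal(a.image, b.image)

    def test_parent_id_preserved(self):
        r = self._rec(3)
        assert all(c.parent_id == r.parent_id for c in augment(r))

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            augment(self._rec(), ["rot45"])


def _parents(n_per_class, size=16):
    recs = []
    for label in ("normal", "carcinoma"):
        for i in range(n_per_class):
            recs.append(tiling.PatchRecord(f"{label[:1]}{i % 7}", i * size, 0,
                                           size, _img(size, size, i), label=label))
    return recs


class TestBalancedManifest:
    def test_target_reached_by_augmentation(self):
        man = build_balanced_manifest(_parents(100), {"training": 500},
                                      seed=0, split_fractions=(1.0, 0.0, 0.0))
        counts = man.counts()
        assert counts.loc["normal", "training"] == 500
        assert counts.loc["carcinoma", "training"] == 500

    def test_table_like_proportions(self):
        """train ~ 8x val ~ 8x test, balanced across classes."""
        man = build_balanced_manifest(
            _parents(50), {"training": 160, "validation": 20, "testing": 20},
            seed=1)
        c = man.counts()
        for label in ("normal", "carcinoma"):
            assert c.loc[label, "training"] == 8 * c.loc[label, "validation"]
            assert c.loc[label, "validation"] == c.loc[label, "testing"]

    def test_no_parent_leaks_across_splits(self):
        man = build_balanced_manifest(
            _parents(50), {"training": 200, "validation": 25, "testing": 25},
            seed=2)
        ids = {s: {r.parent_id for r in man.subset(s)} for s in tiling.SPLITS}
        assert not (ids["training"] & ids["validation"])
        assert not (ids["training"] & ids["testing"])
        assert not (ids["validation"] & ids["testing"])

    def test_deterministic_given_seed(self):
        a = build_balanced_manifest(_parents(30), {"training": 100}, seed=3)
        b = build_balanced_manifest(_parents(30), {"training": 100}, seed=3)
        assert a.to_frame().equals(b.to_frame())

    def test_unachievable_target_names_deficit(self):
        with pytest.raises(ValueError, match="deficit"):
            build_balanced_manifest(_parents(10), {"training": 100}, seed=0,
                                    split_fractions=(1.0, 0.0, 0.0))

    def test_background_patches_excluded(self):
        recs = _parents(10)
        white = np.full((16, 16, 3), 255, dtype=np.uint8)
        recs.append(tiling.PatchRecord("bg", 999, 0, 16, white,
                                       label="normal", background_flag=True))
        man = build_balanced_manifest(recs, {"training": 30}, seed=0,
                                      split_fractions=(1.0, 0.0, 0.0))
        assert not any(r.slide_id == "bg" for r in man.records)


def test_background_flag_detection():
    white = np.full((64, 64, 3), 240, dtype=np.uint8)
    assert tiling.is_background(white)
    assert not tiling.is_background(np.full((64, 64, 3), 200, dtype=np.uint8))


def test_stitched_half_overlap_reconstructs_constant_image():
    """Cutting a constant patch into half-overlap tiles and averaging them
    back must reproduce the constant exactly."""
    from pdacwsi.segmentation import stitch

    img = np.full((512, 512), 0.7)
    tiles, offs = subsample_half_overlap(img)
    out = stitch(tiles, offs, (512, 512))
    assert np.allclose(out, 0.7)
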