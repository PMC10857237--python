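"""Annotation rasterization (vs a shapely oracle) and augmentation-pipeline
contracts: geometry applied identically to image and mask, photometry never
touching the mask, and exact plan bookkeeping."""

import numpy as np
import pytest

from seamseg.dataset_prep import (AugmentationOp, AugmentationPlan,
                                  PolygonAnnotation, add_gaussian_noise,
                                  build_augmented_dataset, crop_tiles,
                                  labelme_to_mask, load_labelme, mirror,
                                  paper_plan, raise_gray, rotate)
from seamseg.synthetic import ImageMaskPair

from conftest import checkerboard_pair


def shapely_mask_oracle(polygons, shape):
    """Independent fill oracle: pixel centers tested with shapely."""
    from shapely.geometry import Point, Polygon

    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    polys = [Polygon([(c, r) for r, c in poly]) for poly in polygons]
    for r in range(h):
        for c in range(w):
            p = Point(c + 0.5, r + 0.5)
            if any(poly.contains(p) for poly in polys):
                mask[r, c] = 1
    return mask


class TestLabelmeToMask:
    def test_axis_aligned_square_area(self):
        ann = PolygonAnnotation(image_size=(16, 16),
                                polygons=[np.array([(0, 0), (0, 10), (10, 10), (10, 0)])])
        mask = labelme_to_mask(ann)
        assert int(mask.sum()) == 100

    def test_matches_shapely_oracle(self, rng):
        polys = [np.array([(2.2, 3.1), (2.5, 14.8), (12.3, 13.0), (9.7, 2.4)]),
                 np.array([(20.0, 20.0), (20.0, 28.0), (27.5, 24.0)])]
        ann = PolygonAnnotation(image_size=(32, 32), polygons=polys)
        assert np.array_equal(labelme_to_mask(ann), shapely_mask_oracle(polys, (32, 32)))

    def test_disjoint_polygons_areas_add(self):
        p1 = np.array([(1, 1), (1, 6), (6, 6), (6, 1)])
        p2 = np.array([(10, 10), (10, 14), (14, 14), (14, 10)])
        both = labelme_to_mask(PolygonAnnotation((20, 20), [p1, p2]))
        a1 = labelme_to_mask(PolygonAnnotation((20, 20), [p1])).sum()
        a2 = labelme_to_mask(PolygonAnnotation((20, 20), [p2])).sum()
        assert both.sum() == a1 + a2

    def test_empty_and_degenerate_polygons(self, caplog):
        assert not labelme_to_mask(PolygonAnnotation((8, 8), [])).any()
        import logging
        with caplog.at_level(logging.WARNING, logger="seamseg.dataset_prep"):
            mask = labelme_to_mask(PolygonAnnotation(
                (8, 8), [np.array([(1.0, 1.0), (2.0, 2.0)])]))
        assert not mask.any()
        assert "degenerate" in caplog.text

    def test_load_labelme_transposes_xy(self):
        data = {"imageHeight": 10, "imageWidth": 20,
                "shapes": [{"label": "cell",
                            "points": [[3, 1], [5, 1], [5, 4]]}]}  # (x, y)
        ann = load_labelme(data)
        assert ann.image_size == (10, 20)
        np.testing.assert_allclose(ann.polygons[0],
                                   [[1, 3], [1, 5], [4, 5]])  # (row, col)

    def test_out_of_bounds_points_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            ann = PolygonAnnotation((8, 8), [np.array([(-1, 0), (0, 12), (5, 5)])])
        assert ann.polygons[0].min() >= 0


class TestCropTiles:
    def test_identity_tile(self, sample_pair):
        tiles = crop_tiles(sample_pair, tile=sample_pair.mask.shape)
        assert len(tiles) == 1
        assert np.array_equal(tiles[0].image, sample_pair.image)

    def test_hd_image_tiling_count(self):
        pair = ImageMaskPair(image=np.zeros((1080, 1920, 3), dtype=np.float32),
                             mask=np.zeros((1080, 1920), dtype=np.uint8))
        tiles = crop_tiles(pair, tile=(256, 256), stride=(256, 256))
        assert len(tiles) == 5 * 8  # ceil(1080/256) x ceil(1920/256)
        assert all(t.mask.shape == (256, 256) for t in tiles)

    def test_flush_anchoring_covers_image(self):
        pair = checkerboard_pair(40, 50)
        tiles = crop_tiles(pair, tile=(32, 32), stride=(32, 32))
        origins = {tuple(t.meta["history"][-1]["origin"]) for t in tiles}
        assert origins == {(0, 0), (0, 18), (8, 0), (8, 18)}

    def test_tile_larger_than_image_raises(self, sample_pair):
        with pytest.raises(ValueError, match="larger than image"):
            crop_tiles(sample_pair, tile=(4096, 4096))


class TestGeometricOps:
    def test_rotate_involution_and_area(self, sample_pair):
        r180 = rotate(rotate(sample_pair, 180), 180)
        assert np.array_equal(r180.image, sample_pair.image)
        for angle in (90, 180, 270):
            assert rotate(sample_pair, angle).mask.sum() == sample_pair.mask.sum()

    def test_rotate_90_ccw_index_mapping(self):
        pair = checkerboard_pair(8, 12)
        rot = rotate(pair, 90)
        h, w = pair.mask.shape
        # output (0, 0) comes from input (0, W-1)
        assert np.array_equal(rot.image[0, 0], pair.image[0, w - 1])
        for r, c in [(0, 3), (5, 1), (7, 11)]:
            assert np.array_equal(rot.image[w - 1 - c, r], pair.image[r, c])

    def test_rotate_rejects_oblique_angles(self, sample_pair):
        with pytest.raises(ValueError, match="right-angle"):
            rotate(sample_pair, 45)

    def test_mirror_involution_and_index_mapping(self):
        pair = checkerboard_pair(8, 12)
        assert np.array_equal(mirror(mirror(pair, "horizontal"), "horizontal").image,
                              pair.image)
        m = mirror(pair, "horizontal")
        w = pair.mask.shape[1]
        for j in range(w):
            assert np.array_equal(m.image[:, j], pair.image[:, w - 1 - j])
        v = mirror(pair, "vertical")
        assert np.array_equal(v.image[0], pair.image[-1])
        assert m.mask.sum() == pair.mask.sum()

    def test_geometric_ops_transform_image_and_mask_identically(self):
        """Encode the mask in an image channel; transforms must agree."""
        pair = checkerboard_pair(16, 16)
        for op in (lambda p: rotate(p, 90), lambda p: mirror(p, "vertical")):
            out = op(pair)
            assert np.array_equal(out.image[..., 2].astype(np.uint8), out.mask)


class TestPhotometricOps:
    def test_raise_gray_identity_and_analytic(self, sample_pair):
        assert np.array_equal(raise_gray(sample_pair, 1.0).image, sample_pair.image)
        pair = ImageMaskPair(image=np.full((4, 4, 3), 0.25, dtype=np.float32),
                             mask=np.zeros((4, 4), dtype=np.uint8))
        assert np.allclose(raise_gray(pair, 0.5).image, 0.5)

    def test_raise_gray_monotone_and_brightening(self, rng):
        img = rng.random((8, 8, 3)).astype(np.float32)
        pair = ImageMaskPair(image=img, mask=np.zeros((8, 8), dtype=np.uint8))
        out = raise_gray(pair, 0.7).image
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-7).all()  # order preserved
        interior = (flat_in > 0) & (flat_in < 1)
        assert (flat_out[interior] > flat_in[interior]).all()

    def test_raise_gray_rejects_bad_gamma(self, sample_pair):
        for gamma in (0.0, -0.3, 1.5):
            with pytest.raises(ValueError, match="gamma"):
                raise_gray(sample_pair, gamma)

    def test_noise_zero_sigma_identity(self, sample_pair):
        out = add_gaussian_noise(sample_pair, 0.0, seed=1)
        assert np.array_equal(out.image, sample_pair.image)

    def test_noise_statistics_and_mask_untouched(self):
        pair = ImageMaskPair(image=np.full((64, 64, 3), 0.5, dtype=np.float32),
                             mask=np.ones((64, 64), dtype=np.uint8))
        sigma = 0.05
        out = add_gaussian_noise(pair, sigma, seed=42)
        delta = out.image.astype(np.float64) - 0.5
        n = delta.size
        assert abs(delta.mean()) < 3 * sigma / np.sqrt(n)
        assert abs(delta.std() - sigma) < 0.1 * sigma
        assert np.array_equal(out.mask, pair.mask)

    def test_photometric_ops_never_touch_mask(self, sample_pair):
        for op in (lambda p: raise_gray(p, 0.6),
                   lambda p: add_gaussian_noise(p, 0.05, seed=3)):
            assert np.array_equal(op(sample_pair).mask, sample_pair.mask)


class TestAugmentationPlan:
    def test_counts_exact(self, small_dataset):
        plan = AugmentationPlan(ops=[
            AugmentationOp("crop", 3, {"tile": (64, 64)}),
            AugmentationOp("rotate", 2),
            AugmentationOp("gaussian_noise", 4),
        ], seed=5)
        out, manifest = build_augmented_dataset(small_dataset, plan)
        assert len(out) == plan.total == 9
        assert [m["kind"] for m in manifest] == ["crop"] * 3 + ["rotate"] * 2 \
            + ["gaussian_noise"] * 4

    def test_zero_counts_empty_output(self, small_dataset):
        plan = AugmentationPlan(ops=[AugmentationOp("mirror", 0)], seed=0)
        out, manifest = build_augmented_dataset(small_dataset, plan)
        assert out == [] and manifest == []

    def test_deterministic_manifests(self, small_dataset):
        plan = AugmentationPlan(ops=[AugmentationOp("raise_gray", 5),
                                     AugmentationOp("mirror", 5)], seed=77)
        _, m1 = build_augmented_dataset(small_dataset, plan)
        _, m2 = build_augmented_dataset(small_dataset, plan)
        assert m1 == m2

    def test_empty_source_raises(self):
        plan = AugmentationPlan(ops=[AugmentationOp("mirror", 1)], seed=0)
        with pytest.raises(ValueError, match="empty source"):
            build_augmented_dataset([], plan)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown augmentation kind"):
            AugmentationOp("elastic", 1)

    def test_paper_plan_counts(self):
        plan = paper_plan()
        assert [op.count for op in plan.ops] == [371, 199, 199, 769, 769]
        assert plan.total == 2307
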