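"""Segmentation pipeline: per-stage contracts, morphology properties, and
bit-exact agreement with naive set-definition oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from neolungseg import lungseg
from neolungseg.lungseg import SegConfig, StructuringElement

from oracles import (
    exhaustive_otsu,
    naive_close,
    naive_components,
    naive_dilate,
    naive_remove_small,
)

masks_8x8 = hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1))


class TestBinarize:
    def test_threshold_is_strict(self):
        x = np.array([[100, 101]], dtype=np.uint8)
        assert lungseg.binarize(x, 100).tolist() == [[0, 1]]

    def test_all_zero_image_at_zero_threshold(self):
        assert not lungseg.binarize(np.zeros((3, 3), dtype=np.uint8), 0).any()

    def test_hand_case(self):
        x = np.array([[10, 200], [128, 129]], dtype=np.uint8)
        assert lungseg.binarize(x, 128).tolist() == [[0, 1], [0, 1]]

    def test_invert_selects_complement(self):
        x = np.array([[10, 200], [128, 129]], dtype=np.uint8)
        inv = lungseg.binarize(x, 128, invert=True)
        assert (inv + lungseg.binarize(x, 128) == 1).all()

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lungseg.binarize(np.zeros((2, 2), dtype=np.uint8), 256)


class TestOtsu:
    def test_two_level_images_split_exactly(self, rng):
        for lo, hi in [(0, 255), (50, 200), (120, 121)]:
            x = rng.choice([lo, hi], size=(20, 20)).astype(np.uint8)
            if len(np.unique(x)) < 2:
                continue
            t = lungseg.otsu_threshold(x)
            assert ((x > t) == (x == hi)).all()

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 256, (12, 12)).astype(np.uint8)
            assert lungseg.otsu_threshold(x) == exhaustive_otsu(x)

    def test_close_to_skimage_on_bimodal_images(self, rng):
        from skimage.filters import threshold_otsu

        x = np.concatenate([rng.normal(60, 10, 300), rng.normal(190, 12, 500)])
        x = np.clip(np.round(x), 0, 255).astype(np.uint8).reshape(20, 40)
        assert abs(lungseg.otsu_threshold(x) - threshold_otsu(x)) <= 1

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            lungseg.otsu_threshold(np.full((5, 5), 7, dtype=np.uint8))


class TestStructuringElement:
    def test_footprint_contains_origin(self):
        for shape in ("disk", "square", "cross"):
            for r in (1, 2, 5):
                fp = StructuringElement(shape, r).footprint()
                assert fp[r, r]
                assert fp.any()

    def test_invalid_shape_and_radius_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement("ball", 1)
        with pytest.raises(ValueError):
            StructuringElement("disk", 0)


class TestDilate:
    def test_empty_mask_stays_empty(self):
        se = StructuringElement("square", 1)
        assert not lungseg.dilate(np.zeros((5, 5), dtype=np.uint8), se).any()

    def test_center_pixel_with_3x3_square(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        out = lungseg.dilate(m, StructuringElement("square", 1))
        expected = np.zeros((5, 5), dtype=np.uint8)
        expected[1:4, 1:4] = 1
        assert (out == expected).all()

    @given(masks_8x8)
    @settings(max_examples=50, deadline=None)
    def test_extensive_and_monotone(self, m):
        se = StructuringElement("disk", 1)
        d = lungseg.dilate(m, se)
        assert (d >= m).all()  # extensivity
        sub = m.copy()
        sub[0] = 0
        assert (lungseg.dilate(sub, se) <= d).all()  # monotonicity


class TestRemoveSmall:
    def test_area_exactly_at_threshold_is_removed(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[0, 0:3] = 1  # area 3
        assert not lungseg.remove_small(m, 3).any()
        assert lungseg.remove_small(m, 2).sum() == 3

    def test_zero_threshold_is_identity(self, random_mask):
        m = random_mask((10, 10))
        assert (lungseg.remove_small(m, 0) == m).all()

    def test_two_components_flood_fill_oracle(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[0, 0:3] = 1          # area 3
        m[4:6, 2:7] = 1        # area 10
        out = lungseg.remove_small(m, 5, connectivity=8)
        assert out.sum() == 10
        assert (out[4:6, 2:7] == 1).all()

    def test_idempotent_and_only_large_components_survive(self, random_mask):
        m = random_mask((14, 14), p=0.4)
        out = lungseg.remove_small(m, 3)
        assert (lungseg.remove_small(out, 3) == out).all()
        for comp in naive_components(out, 8):
            assert len(comp) > 3


class TestRoiMask:
    def test_union_of_two_largest(self):
        m = np.zeros((30, 30), dtype=np.uint8)
        m[0:10, 0:10] = 1       # area 100
        m[15:24, 15:25] = 1     # area 90
        m[28, 0:5] = 1          # area 5
        q = lungseg.make_roi_mask(m, SegConfig(roi_k=2))
        assert q.sum() == 190
        assert q[28, 0] == 0

    def test_roi_k_saturates_at_component_count(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[0, 0] = m[5, 5] = 1
        q = lungseg.make_roi_mask(m, SegConfig(roi_k=7, area_threshold=0))
        assert (q == m).all()

    def test_empty_mask_raises_under_auto_policy(self):
        with pytest.raises(ValueError, match="no candidate"):
            lungseg.make_roi_mask(np.zeros((5, 5), dtype=np.uint8), SegConfig())

    def test_area_ties_broken_by_row_major_label_order(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[0, 0:4] = 1   # first-encountered area-4 component
        m[5, 0:4] = 1   # second area-4 component
        q = lungseg.make_roi_mask(m, SegConfig(roi_k=1))
        assert q[0, 0] == 1 and q[5, 0] == 0

    def test_external_file_policy(self, tmp_path):
        from neolungseg import raster_io

        q_true = np.zeros((6, 6), dtype=np.uint8)
        q_true[2:5, 2:5] = 1
        p = tmp_path / "roi.png"
        raster_io.write_mask(q_true, p)
        cfg = SegConfig(roi_policy="external_file", roi_path=str(p))
        m = np.ones((6, 6), dtype=np.uint8)
        assert (lungseg.make_roi_mask(m, cfg) == q_true).all()
        with pytest.raises(ValueError, match="shape"):
            lungseg.make_roi_mask(np.ones((4, 4), dtype=np.uint8), cfg)


class TestApplyMask:
    def test_identity_annihilator_and_hand_case(self):
        w = np.array([[1, 1], [0, 1]], dtype=np.uint8)
        assert (lungseg.apply_mask(w, np.ones_like(w)) == w).all()
        assert not lungseg.apply_mask(w, np.zeros_like(w)).any()
        q = np.array([[1, 0], [1, 1]], dtype=np.uint8)
        assert lungseg.apply_mask(w, q).tolist() == [[1, 0], [0, 1]]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lungseg.apply_mask(np.ones((2, 2), dtype=np.uint8), np.ones((3, 3), dtype=np.uint8))


class TestCloseMask:
    def test_empty_stays_empty(self):
        se = StructuringElement("square", 1)
        assert not lungseg.close_mask(np.zeros((6, 6), dtype=np.uint8), se).any()

    def test_one_pixel_gap_in_line_is_filled(self):
        m = np.zeros((7, 9), dtype=np.uint8)
        m[3, 1:4] = 1
        m[3, 5:8] = 1  # gap at column 4
        out = lungseg.close_mask(m, StructuringElement("square", 1))
        assert out[3, 4] == 1

    def test_idempotent_and_extensive_away_from_border(self, rng):
        se = StructuringElement("disk", 1)
        for _ in range(10):
            m = np.zeros((14, 14), dtype=np.uint8)
            m[3:11, 3:11] = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            c = lungseg.close_mask(m, se)
            assert (c >= m).all()
            assert (lungseg.close_mask(c, se) == c).all()


class TestOracleEquivalence:
    """Bit-exact agreement with naive triple-loop set-definition oracles on
    50 random 12x12 masks."""

    def test_dilate_close_remove_small_match_naive(self, rng):
        ses = [StructuringElement("disk", 1), StructuringElement("square", 1),
               StructuringElement("cross", 2)]
        for i in range(50):
            m = (rng.random((12, 12)) < rng.uniform(0.2, 0.7)).astype(np.uint8)
            se = ses[i % len(ses)]
            fp = se.footprint()
            assert (lungseg.dilate(m, se) == naive_dilate(m, fp)).all()
            assert (lungseg.close_mask(m, se) == naive_close(m, fp)).all()
            u = int(rng.integers(0, 6))
            conn = 4 if i % 2 else 8
            assert (lungseg.remove_small(m, u, conn) == naive_remove_small(m, u, conn)).all()


class TestOverlay:
    def test_empty_mask_renders_plain_grayscale(self, rng):
        x = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        o = lungseg.overlay(x, np.zeros_like(x), (255, 0, 0))
        assert (o == x[..., None]).all()

    def test_full_mask_product_equals_image(self, rng):
        x = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        assert (lungseg.masked_product(x, np.ones_like(x)) == x).all()
        assert not lungseg.masked_product(x, np.zeros_like(x)).any()

    def test_blend_formula_half_weight(self):
        x = np.full((2, 2), 100, dtype=np.uint8)
        o = lungseg.overlay(x, np.ones_like(x), (255, 0, 0))
        assert tuple(o[0, 0]) == (178, 50, 50)  # round(0.5*100 + 0.5*c)


class TestSegmentPipeline:
    def test_grade1_phantom_dice_above_080(self):
        from neolungseg import evaluate_pair, grade_default_spec, make_phantom

        sample = make_phantom(grade_default_spec(1, seed=3))
        result = lungseg.segment(sample.image)
        report = evaluate_pair(sample.gt_mask, result.closed)
        assert report.dice >= 0.80

    def test_closed_subset_of_roi(self, rng):
        from neolungseg import grade_default_spec, make_phantom

        sample = make_phantom(grade_default_spec(2, seed=1))
        result = lungseg.segment(sample.image)
        assert (result.closed <= result.roi).all()
        assert (result.masked <= result.cleaned).all()

    def test_uniform_image_fixed_threshold_gives_empty_result(self):
        x = np.full((32, 32), 128, dtype=np.uint8)
        cfg = SegConfig(threshold_mode="fixed", threshold_value=128, invert_polarity=False)
        result = lungseg.segment(x, cfg)
        for stage in (result.binary, result.dilated, result.cleaned,
                      result.roi, result.masked, result.closed):
            assert not stage.any()

    def test_constant_image_under_otsu_raises(self):
        with pytest.raises(ValueError):
            lungseg.segment(np.full((16, 16), 9, dtype=np.uint8))

    def test_pipeline_is_deterministic(self):
        from neolungseg import grade_default_spec, make_phantom

        sample = make_phantom(grade_default_spec(3, seed=5))
        r1 = lungseg.segment(sample.image)
        r2 = lungseg.segment(sample.image)
        assert r1.threshold_used == r2.threshold_used
        assert (r1.closed == r2.closed).all()
        assert (r1.overlay == r2.overlay).all()

    def test_threshold_used_recorded(self):
        from neolungseg import grade_default_spec, make_phantom

        sample = make_phantom(grade_default_spec(1, seed=0))
        fixed = lungseg.segment(sample.image, SegConfig(threshold_mode="fixed", threshold_value=90))
        assert fixed.threshold_used == 90
        auto = lungseg.segment(sample.image)
        assert auto.threshold_used == lungseg.otsu_threshold(sample.image)
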