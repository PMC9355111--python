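"""Segmentation pipeline stages and their invariants."""

import math
import warnings

import numpy as np
import pytest

from steatoquant import (
    ChannelThresholds,
    NoTissueError,
    SegmentationConfig,
    binarize_image,
    classify_fat_first_pass,
    detect_vignette_border,
    dilate_restore,
    erode_binary,
    filter_nontissue_background,
    refine_second_pass,
    regions_from_labels,
    segment_image,
    watershed_separate,
)
from steatoquant.geometry import LabeledRegion

from conftest import disk_mask, he_tissue_image, paint_white_disk

THR = ChannelThresholds(green=190, blue=190)


def region_stub(ca, c1=0.5, c2=0.9):
    return LabeledRegion(ca=ca, meca=ca / c1, perimeter=1.0, c1=c1, c2=c2)


class TestBinarize:
    def test_pure_white_image_is_all_white(self):
        img = np.full((40, 40, 3), 255, np.uint8)
        binary = binarize_image(img, ChannelThresholds(green=255, blue=255))
        assert binary.white.all()

    def test_uniform_tissue_is_all_black(self):
        binary = binarize_image(he_tissue_image((40, 40)), THR)
        assert not binary.white.any()

    def test_white_disk_on_tissue_recovers_analytic_area(self):
        img = he_tissue_image((100, 100))
        paint_white_disk(img, (50, 50), 10)
        binary = binarize_image(img, THR)
        assert binary.white.sum() == pytest.approx(math.pi * 100, rel=0.05)

    def test_or_variant_is_more_permissive(self):
        img = he_tissue_image((40, 40))
        img[:10, :, 1] = 250  # high green only
        assert not binarize_image(img, THR, combine="and").white.any()
        assert binarize_image(img, THR, combine="or").white.sum() == 400

    def test_border_pixels_never_white(self):
        img = np.full((40, 40, 3), 255, np.uint8)
        border = np.zeros((40, 40), bool)
        border[:5] = True
        binary = binarize_image(img, ChannelThresholds(green=255, blue=255), border)
        assert not (binary.white & binary.border).any()
        assert binary.white.sum() == 35 * 40


class TestVignetteBorder:
    def test_no_dark_pixels_gives_empty_set(self):
        assert not detect_vignette_border(he_tissue_image((50, 50))).any()

    def test_circular_field_border_matches_analytic_complement(self):
        h, w, r = 200, 200, 90
        field = disk_mask((h, w), (100, 100), r)
        img = np.zeros((h, w, 3), np.uint8)
        img[field] = (200, 130, 150)
        border = detect_vignette_border(img, darkness_cutoff=50)
        # disagreement confined to a 2-px ring around the analytic circle
        yy, xx = np.mgrid[:h, :w]
        dist = np.sqrt((yy - 100) ** 2 + (xx - 100) ** 2)
        mismatch = border != ~field
        assert not (mismatch & (np.abs(dist - r) > 2)).any()

    def test_interior_dark_ring_enclosing_center_is_border(self):
        h = w = 200
        img = np.full((h, w, 3), 180, np.uint8)
        ring = disk_mask((h, w), (100, 100), 80) & ~disk_mask((h, w), (100, 100), 72)
        img[ring] = 0
        border = detect_vignette_border(img, darkness_cutoff=50)
        assert (border & ring).sum() == ring.sum()

    def test_small_dark_nuclei_are_not_border(self):
        img = he_tissue_image((100, 100))
        img[50:53, 50:53] = 10
        assert not detect_vignette_border(img).any()

    def test_fully_black_image_is_all_border_and_raises_downstream(self):
        img = np.zeros((60, 60, 3), np.uint8)
        assert detect_vignette_border(img).all()
        with pytest.raises(NoTissueError):
            segment_image(img)


class TestMorphology:
    def test_isolated_white_pixel_is_noise_killed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert not erode_binary(mask).any()

    def test_erosion_of_disk_removes_one_boundary_ring(self):
        mask = disk_mask((60, 60), (30, 30), 20)
        lost = mask.sum() - erode_binary(mask).sum()
        ring = 2 * math.pi * 20
        assert 0.5 * ring <= lost <= 1.8 * ring

    def test_erosion_of_empty_mask_is_identity(self):
        assert not erode_binary(np.zeros((20, 20), bool)).any()

    def test_dilate_restore_recovers_eroded_disk(self):
        original = disk_mask((60, 60), (30, 30), 20)
        eroded = erode_binary(original)
        restored = dilate_restore(eroded, original)
        assert restored.sum() == pytest.approx(original.sum(), rel=0.05)
        assert not (restored & ~original).any()

    def test_dilate_restore_of_empty_mask_is_empty(self):
        empty = np.zeros((20, 20), bool)
        assert not dilate_restore(empty, np.ones((20, 20), bool)).any()

    def test_dilate_restore_never_escapes_pre_erosion_set(self, rng):
        pre = rng.random((50, 50)) < 0.4
        mask = pre & (rng.random((50, 50)) < 0.5)
        restored = dilate_restore(mask, pre)
        assert not (restored & ~pre).any()
        assert (restored & mask).sum() == mask.sum()  # output contains input


class TestWatershed:
    def test_two_merged_disks_split_into_two_even_halves(self):
        mask = disk_mask((60, 80), (30, 30), 10) | disk_mask((60, 80), (30, 45), 10)
        labels = watershed_separate(mask)
        areas = np.bincount(labels.ravel())[1:]
        areas = areas[areas > 0]
        assert len(areas) == 2
        assert all(abs(a - math.pi * 100) / (math.pi * 100) < 0.2 for a in areas)
        assert (labels > 0).sum() == mask.sum()  # no pixel created or destroyed

    def test_single_disk_untouched(self):
        mask = disk_mask((40, 40), (20, 20), 10)
        labels = watershed_separate(mask)
        assert labels.max() == 1
        assert (labels == 1).sum() == mask.sum()

    def test_chain_of_three_overlapping_disks_splits_into_three(self):
        mask = np.zeros((60, 100), bool)
        for c in (25, 40, 55):
            mask |= disk_mask((60, 100), (30, c), 10)
        labels = watershed_separate(mask)
        assert labels.max() == 3
        assert (labels > 0).sum() == mask.sum()


class TestFilterRules:
    def test_background_hard_size_rule(self):
        assert filter_nontissue_background([region_stub(2500, c1=0.9)]) == []

    def test_background_joint_rule(self):
        removed = region_stub(700, c1=0.2)
        retained = region_stub(700, c1=0.5)
        assert filter_nontissue_background([removed, retained]) == [retained]

    def test_small_noncircular_region_survives_background_filter(self):
        r = region_stub(100, c1=0.1)
        assert filter_nontissue_background([r]) == [r]

    def test_background_filter_is_idempotent(self, rng):
        regions = [
            region_stub(int(rng.integers(1, 3000)), c1=float(rng.uniform(0.01, 1)))
            for _ in range(200)
        ]
        once = filter_nontissue_background(regions)
        assert filter_nontissue_background(once) == once

    def test_first_pass_area_band_is_inclusive(self):
        assert classify_fat_first_pass([region_stub(2, c1=0.5)]) != []
        assert classify_fat_first_pass([region_stub(1999, c1=0.5)]) != []
        assert classify_fat_first_pass([region_stub(1, c1=0.5)]) == []
        assert classify_fat_first_pass([region_stub(2000, c1=0.5)]) == []

    def test_first_pass_circularity_is_strict(self):
        assert classify_fat_first_pass([region_stub(500, c1=0.2)]) == []
        assert classify_fat_first_pass([region_stub(500, c1=0.2 + 1e-9)]) != []


class TestSecondPass:
    def test_round_disk_kept(self):
        mask = disk_mask((40, 40), (20, 20), 9)  # area ~254
        final, regions = refine_second_pass(mask)
        assert len(regions) == 1
        assert final.sum() == mask.sum()

    def test_elongated_rectangle_rejected_by_c2(self):
        mask = np.zeros((20, 80), bool)
        mask[5:10, 5:65] = True  # area 300, C2 ~ 0.47
        # thin bars are split by the watershed; every fragment must still
        # be rejected or the final mask would leak lumen pixels
        final, regions = refine_second_pass(mask, min_marker_distance=100)
        assert regions == []
        assert not final.any()

    def test_large_disk_rejected_by_area_cap(self):
        mask = disk_mask((60, 60), (30, 30), 14)  # area ~616 > 499
        final, regions = refine_second_pass(mask)
        assert regions == []
        assert not final.any()


class TestSegmentImage:
    def test_all_tissue_phantom_scores_zero(self):
        from steatoquant import PhantomSpec, generate_he_phantom

        img, _ = generate_he_phantom(PhantomSpec(droplet_count=0, seed=1))
        res = segment_image(img)
        assert res.fat_pixel_count == 0
        assert res.tissue_pixel_count > 0.4 * 480 * 640

    def test_thirty_isolated_droplets_all_accepted(self):
        img = he_tissue_image()
        rng = np.random.default_rng(3)
        centers = [(40 + 44 * (i // 6), 60 + 90 * (i % 6)) for i in range(30)]
        total = 0
        for c in centers:
            total += paint_white_disk(img, c, 8).sum()
        img = np.clip(
            img.astype(int) + rng.integers(-4, 5, img.shape), 0, 255
        ).astype(np.uint8)
        res = segment_image(img)
        assert len(res.regions) == 30
        assert res.fat_pixel_count == pytest.approx(total, rel=0.05)

    def test_large_tear_excluded_but_droplets_kept(self):
        img = he_tissue_image()
        img[100:160, 100:160] = 252  # 3600-px tear
        kept = 0
        for i in range(10):
            kept += paint_white_disk(img, (300 + 30 * (i // 5), 200 + 40 * (i % 5)), 7).sum()
        res = segment_image(img, keep_stages=True)
        assert len(res.regions) == 10
        assert res.fat_pixel_count == pytest.approx(kept, rel=0.05)
        # denominator = stained pixels + accepted fat; the 3600-px tear and
        # any rejected white pixels stay out of it
        white = int(res.stages["binarized"].sum())
        assert res.tissue_pixel_count == 480 * 640 - white + res.fat_pixel_count
        assert white >= 3600

    def test_pixel_conservation_across_stages(self):
        img = he_tissue_image()
        for i in range(8):
            paint_white_disk(img, (100 + 40 * i % 400, 80 + 70 * i % 560), 9)
        res = segment_image(img, keep_stages=True)
        stages = res.stages
        pre = stages["binarized"]
        for name in ("eroded", "background_filtered", "first_pass", "restored", "final"):
            assert not (stages[name] & ~pre).any(), name

    def test_adding_one_disjoint_droplet_increments_count(self):
        img = he_tissue_image()
        for i in range(5):
            paint_white_disk(img, (100, 80 + 100 * i), 9)
        base = segment_image(img)
        paint_white_disk(img, (350, 350), 9)  # area ~254 in [50, 400]
        more = segment_image(img)
        assert len(more.regions) == len(base.regions) + 1
        assert more.fat_pixel_count >= base.fat_pixel_count

    def test_determinism_bit_identical_masks(self):
        from steatoquant import PhantomSpec, generate_he_phantom

        img, _ = generate_he_phantom(PhantomSpec(droplet_count=25, tear_count=1, seed=5))
        a = segment_image(img)
        b = segment_image(img)
        assert np.array_equal(a.final_mask, b.final_mask)
        assert a.fat_pixel_count == b.fat_pixel_count

    def test_non_reference_frame_warns_and_rescales(self):
        img = he_tissue_image((240, 320))
        paint_white_disk(img, (120, 160), 8)
        with pytest.warns(UserWarning, match="rescaled"):
            res = segment_image(img)
        assert res.area_scale == pytest.approx(0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = segment_image(img, SegmentationConfig(rescale_thresholds=False))
        assert res.area_scale == 1.0

    def test_grayscale_input_promoted_with_note(self):
        img = np.full((480, 640), 140, np.uint8)
        img[100:110, 100:110] = 250
        res = segment_image(img)
        assert any("grayscale" in w for w in res.warnings)

    def test_config_thresholds_are_live_not_hardcoded(self):
        img = he_tissue_image()
        paint_white_disk(img, (240, 320), 9)
        assert len(segment_image(img).regions) == 1
        # area cap below the droplet size must reject it
        strangled = SegmentationConfig(second_pass_area_max=100)
        assert segment_image(img, strangled).fat_pixel_count == 0
        # C2 floor above 1 rejects everything
        assert segment_image(img, SegmentationConfig(second_pass_c2_min=1.2)).fat_pixel_count == 0

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SegmentationConfig.from_dict({"lower_bound": 100, "bogus_key": 1})
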