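"""Auto-labeling: threshold predicate, cleanup operators vs brute-force
morphology oracles, and end-to-end fidelity against generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from fruitseg import (
    AutolabelConfig,
    autolabel,
    discard_stems,
    fill_holes,
    measure_components,
    remove_small_components,
    threshold_fruit_pixels,
)

CFG = AutolabelConfig()

mask_arrays = hnp.arrays(np.uint8, (24, 24), elements=st.integers(0, 1))


def disk_mask(h, w, cy, cx, r):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.uint8)


class TestThreshold:
    def test_uniform_gray_yields_empty_mask(self):
        img = np.full((16, 16, 3), 120, dtype=np.uint8)
        assert threshold_fruit_pixels(img, CFG).sum() == 0

    def test_single_red_pixel(self):
        img = np.full((8, 8, 3), 120, dtype=np.uint8)
        img[3, 4] = (200, 50, 50)
        m = threshold_fruit_pixels(img, CFG)
        assert m[3, 4] == 1 and m.sum() == 1

    def test_matches_per_pixel_loop_on_scene(self, set1_scene):
        m = threshold_fruit_pixels(set1_scene.image, CFG)
        oracle = oracles.threshold_loop(
            set1_scene.image, CFG.red_min, CFG.red_green_margin, CFG.red_blue_margin
        )
        assert np.array_equal(m, oracle)

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ValueError):
            threshold_fruit_pixels(np.zeros((8, 8), dtype=np.uint8), CFG)


class TestRemoveSmallComponents:
    def test_empty_mask_unchanged(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        assert remove_small_components(m, 5).sum() == 0

    def test_area_filtering_against_flood_fill_oracle(self):
        m = np.zeros((32, 32), dtype=np.uint8)
        m[2:7, 2:3] = 1            # area 5
        m[10:20, 10:15] = 1        # area 50
        out = remove_small_components(m, 10)
        assert np.array_equal(out, oracles.remove_small_loop(m, 10))
        assert out.sum() == 50

    def test_component_at_exact_threshold_survives(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[4:6, 4:9] = 1  # area 10
        assert np.array_equal(remove_small_components(m, 10), m)

    def test_invalid_min_area(self):
        with pytest.raises(ValueError):
            remove_small_components(np.zeros((4, 4), dtype=np.uint8), 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(mask_arrays, st.integers(1, 12))
    def test_random_masks_match_oracle_and_never_add_pixels(self, m, min_area):
        out = remove_small_components(m, min_area)
        assert np.array_equal(out, oracles.remove_small_loop(m, min_area))
        assert np.all(out <= m)
        # idempotence
        assert np.array_equal(remove_small_components(out, min_area), out)


class TestMeasureComponents:
    def test_circle_has_near_zero_eccentricity(self):
        m = disk_mask(64, 64, 32, 32, 20)
        (shape,) = measure_components(m)
        assert shape.eccentricity < 0.1

    def test_ellipse_eccentricity_matches_closed_form(self):
        yy, xx = np.mgrid[0:128, 0:128]
        m = (((xx - 64) / 50.0) ** 2 + ((yy - 64) / 30.0) ** 2 <= 1).astype(np.uint8)
        (shape,) = measure_components(m)
        assert shape.eccentricity == pytest.approx(0.8, rel=0.02)
        assert shape.ellipse_semi_major == pytest.approx(50, rel=0.02)
        assert shape.ellipse_semi_minor == pytest.approx(30, rel=0.02)
        assert shape.eccentricity == pytest.approx(
            np.sqrt(1 - (shape.ellipse_semi_minor / shape.ellipse_semi_major) ** 2),
            abs=1e-9,
        )

    def test_two_blobs_two_shapes(self):
        m = np.zeros((32, 32), dtype=np.uint8)
        m[2:8, 2:8] = 1
        m[20:28, 20:28] = 1
        assert len(measure_components(m)) == 2

    def test_empty_mask_gives_empty_list(self):
        assert measure_components(np.zeros((8, 8), dtype=np.uint8)) == []

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(mask_arrays)
    def test_eccentricity_matches_moment_oracle(self, m):
        from skimage import measure as skmeasure

        labels = skmeasure.label(m, connectivity=2)
        shapes = measure_components(m)
        assert len(shapes) == labels.max()
        for shape, rp in zip(shapes, skmeasure.regionprops(labels)):
            if rp.area < 2:
                continue
            expected = oracles.component_eccentricity(rp.coords)
            assert shape.eccentricity == pytest.approx(expected, abs=1e-6)


class TestDiscardStems:
    def test_circle_survives_erode_dilate_round_trip(self):
        m = disk_mask(64, 64, 32, 32, 15)
        out = discard_stems(m, CFG)
        retained = np.logical_and(out, m).sum() / m.sum()
        assert retained >= 0.95
        assert np.array_equal(
            out,
            oracles.discard_stems_loop(
                m, CFG.erosion_radius, CFG.dilation_radius, CFG.eccentricity_max
            ),
        )

    def test_attached_stem_removed_body_kept(self):
        m = disk_mask(64, 64, 32, 24, 12)
        m[30:33, 36:52] = 1  # 3-px-wide protruding stem
        out = discard_stems(m, CFG)
        oracle = oracles.discard_stems_loop(
            m, CFG.erosion_radius, CFG.dilation_radius, CFG.eccentricity_max
        )
        assert np.array_equal(out, oracle)
        assert out[30:33, 44:52].sum() == 0       # stem tip gone
        assert out[28:36, 20:28].sum() > 0        # body center kept
        for c in measure_components(out):
            assert c.eccentricity <= CFG.eccentricity_max

    def test_empty_mask_passthrough(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        assert discard_stems(m, CFG).sum() == 0


class TestFillHoles:
    def test_ring_becomes_disk(self):
        outer = disk_mask(40, 40, 20, 20, 12)
        inner = disk_mask(40, 40, 20, 20, 6)
        ring = (outer & ~inner.astype(bool)).astype(np.uint8)
        assert np.array_equal(fill_holes(ring), outer)

    def test_idempotent_without_holes(self):
        m = disk_mask(20, 20, 10, 10, 5)
        assert np.array_equal(fill_holes(m), m)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, (32, 32), elements=st.integers(0, 1)))
    def test_random_masks_match_border_flood_oracle(self, m):
        out = fill_holes(m)
        assert np.array_equal(out, oracles.fill_holes_loop(m))
        assert np.all(out >= m)  # never removes pixels
        assert np.array_equal(fill_holes(out), out)  # idempotent


class TestAutolabelPipeline:
    def test_high_iou_against_generator_ground_truth(self, set1_batch):
        ious = []
        for s in set1_batch:
            m = autolabel(s.image, CFG)
            inter = np.logical_and(m, s.mask).sum()
            union = np.logical_or(m, s.mask).sum()
            ious.append(inter / union if union else 1.0)
        assert np.mean(ious) >= 0.9

    def test_no_stem_like_components_survive(self, set1_batch):
        for s in set1_batch:
            for c in measure_components(autolabel(s.image, CFG)):
                assert c.eccentricity <= CFG.eccentricity_max

    def test_background_image_yields_empty_mask(self):
        img = np.full((64, 64, 3), 120, dtype=np.uint8)
        assert autolabel(img, CFG).sum() == 0

    def test_noise_speckles_are_removed(self):
        rng = np.random.default_rng(0)
        img = np.full((64, 64, 3), 120, dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        fruit = ((yy - 32) ** 2 + (xx - 32) ** 2) <= 12**2
        img[fruit] = (180, 50, 50)
        for _ in range(3):  # 3-px red speckles far from the fruit
            i, j = rng.integers(0, 10, size=2)
            img[i : i + 3, j] = (200, 40, 40)
        out = autolabel(img, CFG)
        labels, n = __import__("oracles").flood_fill_label(out)
        assert n == 1
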