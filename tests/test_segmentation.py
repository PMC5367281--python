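"""Segmentation: thresholding, rescaling, cropping and the two recipes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegmorph import (
    BinaryPattern,
    BiomassGrid,
    GrayImage,
    SegmentationConfig,
    binarize_biomass,
    binarize_intensity,
    crop_window,
    rescale_bilinear,
    rgb_to_gray,
    segment_model_image,
    segment_satellite_image,
)


class TestBinarizeBiomass:
    def test_threshold_at_5_g(self):
        grid = BiomassGrid(np.array([[0.0, 10.0], [10.0, 0.0]]))
        mask = binarize_biomass(grid, 5.0).mask
        assert mask.tolist() == [[False, True], [True, False]]

    def test_all_zero_grid_gives_empty_mask(self):
        grid = BiomassGrid(np.zeros((4, 4)))
        assert not binarize_biomass(grid, 5.0).mask.any()

    def test_boundary_value_is_inclusive(self):
        grid = BiomassGrid(np.array([[5.0, 4.999], [0.0, 5.001]]))
        mask = binarize_biomass(grid, 5.0).mask
        assert mask.tolist() == [[True, False], [False, True]]

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            BiomassGrid(np.array([[1.0, np.nan], [0.0, 0.0]]))

    @given(threshold_lo=st.floats(0.5, 20), delta=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_adds_pixels(self, threshold_lo, delta):
        rng = np.random.default_rng(4)
        grid = BiomassGrid(rng.uniform(0, 25, (8, 8)))
        lo = binarize_biomass(grid, threshold_lo).mask.sum()
        hi = binarize_biomass(grid, threshold_lo + delta).mask.sum()
        assert hi <= lo


class TestRescaleBilinear:
    def test_constant_image_stays_constant(self):
        img = GrayImage(np.full((100, 100), 0.42))
        out = rescale_bilinear(img, 0.17)
        assert out.shape == (17, 17)
        assert np.allclose(out.values, 0.42)

    def test_half_scale_matches_hand_bilinear(self, rng):
        values = rng.random((4, 4))
        out = rescale_bilinear(GrayImage(values), 0.5).values
        # centered-pixel bilinear at exactly half scale = 2x2 block means
        expected = values.reshape(2, 2, 2, 2).mean(axis=(1, 3))
        assert np.allclose(out, expected)

    def test_identity_factor(self, rng):
        values = rng.random((7, 5))
        out = rescale_bilinear(GrayImage(values), 1.0)
        assert np.array_equal(out.values, values)

    def test_empty_output_rejected(self):
        with pytest.raises(ValueError):
            rescale_bilinear(GrayImage(np.ones((3, 3)) * 0.5), 0.01)


class TestCropWindow:
    def test_top_left_block(self, rng):
        values = rng.random((100, 100))
        out = crop_window(GrayImage(values), (0, 0), (50, 50))
        assert np.array_equal(out.values, values[:50, :50])

    def test_out_of_bounds_named_in_error(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            crop_window(GrayImage(rng.random((100, 100))), (60, 60), (50, 50))

    def test_zero_based_half_open_indexing(self, rng):
        values = rng.random((100, 100))
        out = crop_window(GrayImage(values), (25, 25), (50, 50))
        assert out.values[0, 0] == values[25, 25]
        assert out.values[-1, -1] == values[74, 74]

    def test_crop_binary_pattern_preserves_type(self):
        p = BinaryPattern(np.eye(6, dtype=bool))
        out = crop_window(p, (1, 1), (3, 3))
        assert isinstance(out, BinaryPattern)
        assert out.mask.tolist() == np.eye(3, dtype=bool).tolist()


class TestBinarizeIntensity:
    def test_fixed_threshold_dark_polarity(self):
        img = GrayImage(np.array([[0.1, 0.9], [0.9, 0.1]]))
        mask = binarize_intensity(img, "fixed", 0.5, "dark-is-vegetation").mask
        assert mask.tolist() == [[True, False], [False, True]]

    def test_otsu_splits_two_level_histogram(self, rng):
        values = np.where(rng.random((20, 20)) < 0.6, 0.2, 0.8)
        bright = binarize_intensity(GrayImage(values), "otsu",
                                    polarity_hint="bright-is-vegetation").mask
        assert np.array_equal(bright, values == 0.8)

    def test_constant_image_under_otsu_errors(self):
        with pytest.raises(ValueError, match="constant"):
            binarize_intensity(GrayImage(np.full((5, 5), 0.3)), "otsu")

    def test_all_below_fixed_threshold_bright(self):
        img = GrayImage(np.full((5, 5), 0.3))
        assert not binarize_intensity(img, "fixed", 0.5, "bright-is-vegetation").mask.any()

    def test_polarity_flip_complements_exactly(self, rng):
        img = GrayImage(rng.random((12, 12)))
        bright = binarize_intensity(img, "fixed", 0.4, "bright-is-vegetation").mask
        dark = binarize_intensity(img, "fixed", 0.4, "dark-is-vegetation").mask
        assert np.array_equal(bright, ~dark)

    def test_idempotent_on_binary_image(self, rng):
        binary = (rng.random((10, 10)) < 0.5).astype(float)
        out = binarize_intensity(GrayImage(binary), "fixed", 0.5, "bright-is-vegetation").mask
        assert np.array_equal(out, binary.astype(bool))


class TestModelRecipe:
    def test_uniform_biomass_propagates_to_full_mask(self):
        grid = BiomassGrid(np.full((100, 100), 10.0))
        out = segment_model_image(grid)
        assert out.shape == (50, 50)
        assert out.mask.all()

    def test_zero_biomass_gives_empty_mask(self):
        out = segment_model_image(BiomassGrid(np.zeros((100, 100))))
        assert not out.mask.any()

    def test_half_vegetated_keeps_single_vertical_boundary(self):
        values = np.zeros((100, 100))
        values[:, :50] = 10.0
        out = segment_model_image(BiomassGrid(values))
        assert out.shape == (50, 50)
        # each row is monotone True -> False: one boundary, left side vegetated
        for row in out.mask:
            flips = np.count_nonzero(row[:-1] != row[1:])
            assert flips == 1 and row[0] and not row[-1]

    def test_too_small_after_rescale_errors(self):
        grid = BiomassGrid(np.full((10, 10), 10.0))
        with pytest.raises(ValueError, match="smaller than"):
            segment_model_image(grid, SegmentationConfig(grid_upsample=1))


class TestSatelliteRecipe:
    def _disk_chip(self, radius=30, spacing=70):
        values = np.ones((350, 350))
        yy, xx = np.mgrid[0:350, 0:350]
        for cy in range(spacing // 2, 350, spacing):
            for cx in range(spacing // 2, 350, spacing):
                values[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = 0.0
        return GrayImage(values, "satellite")

    def test_dark_disks_area_fraction_preserved(self):
        chip = self._disk_chip()
        out = segment_satellite_image(chip)
        assert out.shape == (50, 50)
        dark_fraction = 1.0 - chip.values.mean()
        assert abs(out.cover_fraction - dark_fraction) < 0.05

    def test_constant_image_fixed_threshold_single_class(self):
        img = GrayImage(np.full((350, 350), 0.8), "satellite")
        cfg = SegmentationConfig(intensity_method="fixed", fixed_threshold=0.5,
                                 polarity_hint="bright-is-vegetation")
        assert segment_satellite_image(img, cfg).mask.all()

    def test_undersized_input_errors(self):
        img = GrayImage(np.zeros((349, 349)), "satellite")
        with pytest.raises(ValueError, match="smaller"):
            segment_satellite_image(img)


def test_rgb_luminance_conversion():
    rgb = np.zeros((2, 2, 3))
    rgb[0, 0] = [1, 1, 1]
    rgb[0, 1] = [0, 1, 0]
    gray = rgb_to_gray(rgb)
    assert gray[0, 0] == pytest.approx(1.0)
    assert gray[0, 1] == pytest.approx(0.7152)
    assert gray[1, 1] == 0.0
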