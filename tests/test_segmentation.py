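import numpy as np
import pytest

from rainbowspec.errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    SegmentationError,
)
from rainbowspec.segmentation import (
    SegmentationConfig,
    binarize,
    extract_rainbow,
    gray_histogram,
    median_filter,
    morphological_clean,
    otsu_criterion,
    otsu_threshold,
    to_grayscale,
)
from rainbowspec.synthetic_data import SceneSpec, make_rainbow_image


def otsu_bruteforce(p):
    """Independent exhaustive threshold search from the class-statistics
    definitions (probability masses, class means, product criterion)."""
    levels = np.arange(256, dtype=float)
    best_t, best_g = None, -1.0
    for t in range(256):
        w1 = p[: t + 1].sum()
        w2 = p[t + 1 :].sum()
        if w1 == 0 or w2 == 0:
            continue
        mu1 = (p[: t + 1] * levels[: t + 1]).sum() / w1
        mu2 = (p[t + 1 :] * levels[t + 1 :]).sum() / w2
        g = w1 * w2 * (mu2 - mu1) ** 2
        if g > best_g:
            best_t, best_g = t, g
    return best_t, best_g


def random_histogram(gen, n_levels=None):
    p = np.zeros(256)
    if n_levels is None:
        n_levels = gen.integers(2, 256)
    levels = gen.choice(256, size=n_levels, replace=False)
    weights = gen.random(n_levels)
    p[levels] = weights / weights.sum()
    return p


class TestToGrayscale:
    def test_red_weight_identity(self, rng):
        img = rng.integers(0, 256, (5, 7, 3), dtype=np.uint8)
        assert np.array_equal(to_grayscale(img, (1, 0, 0)), img[..., 0])

    def test_uniform_image(self):
        img = np.full((4, 4, 3), 99, dtype=np.uint8)
        assert np.all(to_grayscale(img, (0.299, 0.587, 0.114)) == 99)

    def test_hand_computed_2x2(self):
        img = np.array(
            [[[10, 20, 30], [200, 100, 50]], [[0, 0, 255], [255, 255, 255]]],
            dtype=np.uint8,
        )
        w = (0.299, 0.587, 0.114)
        expected = np.array(
            [
                [round(10 * w[0] + 20 * w[1] + 30 * w[2]), round(200 * w[0] + 100 * w[1] + 50 * w[2])],
                [round(255 * w[2]), 255],
            ]
        )
        assert np.array_equal(to_grayscale(img, w), expected)

    @pytest.mark.parametrize("weights", [(0, 0, 0), (-0.1, 0.6, 0.5)])
    def test_invalid_weights(self, weights):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        with pytest.raises(InvalidParameterError):
            to_grayscale(img, weights)

    def test_not_rgb(self):
        with pytest.raises(InvalidInputError):
            to_grayscale(np.zeros((3, 3)))


class TestMedianFilter:
    def test_uniform_unchanged(self):
        img = np.full((6, 6), 42, dtype=np.uint8)
        assert np.array_equal(median_filter(img, 3), img)

    def test_salt_pixel_removed(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        assert np.all(median_filter(img, 3) == 0)

    def test_matches_bruteforce_oracle(self, rng):
        img = rng.integers(0, 256, (5, 5), dtype=np.uint8)
        # edge-repeating reflection, i.e. numpy's "symmetric" convention
        padded = np.pad(img, 1, mode="symmetric")
        expected = np.empty_like(img)
        for i in range(5):
            for j in range(5):
                window = sorted(padded[i : i + 3, j : j + 3].ravel())
                expected[i, j] = window[4]  # middle of 9
        assert np.array_equal(median_filter(img, 3), expected)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            median_filter(np.zeros((3, 3), dtype=np.uint8), 4)

    def test_output_range_within_input_range(self, rng):
        img = rng.integers(50, 200, (10, 10), dtype=np.uint8)
        out = median_filter(img, 5)
        assert out.min() >= img.min() and out.max() <= img.max()


class TestGrayHistogram:
    def test_uniform_level(self):
        p = gray_histogram(np.full((3, 3), 7, dtype=np.uint8))
        assert p[7] == 1.0 and p.sum() == 1.0

    def test_two_levels(self):
        p = gray_histogram(np.array([[0, 0], [255, 255]], dtype=np.uint8))
        assert p[0] == 0.5 and p[255] == 0.5

    def test_matches_counting_oracle(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        p = gray_histogram(img)
        for level in range(256):
            assert p[level] == np.sum(img == level) / 64

    def test_empty_image(self):
        with pytest.raises(InvalidInputError):
            gray_histogram(np.zeros((0, 3), dtype=np.uint8))


class TestOtsu:
    def test_two_level_closed_form(self):
        p = np.zeros(256)
        p[50] = 0.5
        p[200] = 0.5
        res = otsu_threshold(p)
        assert 50 <= res.threshold <= 199
        assert res.criterion[res.threshold] == pytest.approx(0.25 * 150**2)
        assert res.omega1 == pytest.approx(0.5)
        assert res.mu1 == pytest.approx(50)
        assert res.mu2 == pytest.approx(200)

    def test_sum_and_product_forms_identical(self, rng):
        for _ in range(50):
            p = random_histogram(rng)
            np.testing.assert_allclose(
                otsu_criterion(p), otsu_criterion(p, decomposed=True), atol=1e-9
            )

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            p = random_histogram(rng, n_levels=16)
            res = otsu_threshold(p)
            t_star, g_star = otsu_bruteforce(p)
            assert res.criterion[res.threshold] == pytest.approx(g_star, rel=1e-12)

    def test_class_statistics_identities(self, rng):
        p = random_histogram(rng)
        res = otsu_threshold(p)
        assert res.omega1 + res.omega2 == pytest.approx(1.0, abs=1e-12)
        assert res.omega1 * res.mu1 + res.omega2 * res.mu2 == pytest.approx(res.mu, abs=1e-9)
        assert res.criterion[res.threshold] == res.criterion.max()

    def test_single_level_degenerate(self):
        p = np.zeros(256)
        p[10] = 1.0
        with pytest.raises(DegenerateInputError):
            otsu_threshold(p)


class TestBinarize:
    def test_all_below_threshold(self):
        assert not binarize(np.full((3, 3), 10, dtype=np.uint8), 100).any()

    def test_two_pixels_above(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        assert binarize(img, 100).sum() == 2

    def test_partition_matches_histogram_masses(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        p = gray_histogram(img)
        res = otsu_threshold(p)
        mask = binarize(img, res.threshold)
        assert mask.sum() / img.size == pytest.approx(res.omega2)
        assert (~mask).sum() / img.size == pytest.approx(res.omega1)

    def test_out_of_range_threshold(self):
        with pytest.raises(InvalidParameterError):
            binarize(np.zeros((2, 2), dtype=np.uint8), 300)


class TestMorphologicalClean:
    def test_radius_zero_identity(self, rng):
        mask = rng.random((8, 8)) > 0.5
        assert np.array_equal(morphological_clean(mask, 0), mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert not morphological_clean(mask, 1).any()

    def test_interior_hole_closed(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        mask[6, 6] = False
        out = morphological_clean(mask, 1)
        assert out[6, 6]

    def test_negative_radius(self):
        with pytest.raises(InvalidParameterError):
            morphological_clean(np.zeros((3, 3), dtype=bool), -1)


class TestExtractRainbow:
    def test_bbox_recovered(self, default_scene):
        img, truth = default_scene
        patch = extract_rainbow(img)
        assert max(abs(np.array(patch.source_bbox) - np.array(truth.bbox))) <= 2

    def test_two_symmetric_patches_yield_one(self):
        img, _ = make_rainbow_image(SceneSpec(center=(120.0, 70.0), two_patches=True))
        patch = extract_rainbow(img)
        assert patch.pixels.shape == (100, 100, 3)

    def test_all_black_raises_with_mask(self):
        img = np.zeros((60, 80, 3), dtype=np.uint8)
        with pytest.raises(SegmentationError) as excinfo:
            extract_rainbow(img)
        assert excinfo.value.mask is not None
        assert excinfo.value.mask.shape == (60, 80)

    @pytest.mark.parametrize("shape", [(131, 217), (320, 240)])
    def test_output_always_standard_size(self, shape):
        h, w = shape
        img = np.zeros((h, w, 3), dtype=np.uint8)
        rr, cc = np.mgrid[0:h, 0:w]
        inside = ((rr - h / 2) / (h / 3)) ** 2 + ((cc - w / 2) / (w / 4)) ** 2 <= 1
        img[inside] = (180, 120, 60)
        patch = extract_rainbow(img)
        assert patch.pixels.shape == (100, 100, 3)

    def test_saturation_gate_blocks_gray_object(self):
        # bright but colorless object is rejected by the HSV gate
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        img[10:40, 10:30] = 200
        with pytest.raises(SegmentationError):
            extract_rainbow(img, SegmentationConfig(saturation_min=0.15))
        patch = extract_rainbow(img, SegmentationConfig(saturation_min=None))
        assert patch.pixels.shape == (100, 100, 3)
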