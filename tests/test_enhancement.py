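"""Enhancement pipeline: hand-derived values, oracles, and invariants."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage import color as skcolor

from histocaps import (
    EnhancementConfig,
    build_pyramid,
    collapse_pyramid,
    compensate_channels,
    enhance_image,
    gamma_correct,
    laplacian_contrast_weight,
    multiscale_fusion,
    naive_fusion,
    normalize_weights,
    saliency_weight,
    saturation_weight,
    sharpen,
)
from histocaps.enhancement import default_pyramid_levels, load_image, save_image


# ---------------------------------------------------------------------------
# channel compensation
# ---------------------------------------------------------------------------

class TestCompensateChannels:
    def test_constant_image_hand_value(self):
        # r'=0.2+(0.6-0.2)(1-0.2)(0.6)=0.392 for a constant r=.2 g=.6 b=.5 tile
        img = np.zeros((4, 4, 3))
        img[..., 0], img[..., 1], img[..., 2] = 0.2, 0.6, 0.5
        out = compensate_channels(img, EnhancementConfig(alpha=1.0))
        assert out[..., 0] == pytest.approx(0.392)
        # g'=0.6+(0.2-0.6)(0.4)(0.2)=0.568; b'=0.5+(0.6-0.5)(0.5)(0.6)=0.53
        assert out[..., 1] == pytest.approx(0.568)
        assert out[..., 2] == pytest.approx(0.53)

    def test_equal_means_is_identity(self, rng):
        img = rng.uniform(0.2, 0.8, (16, 16, 3))
        img -= img.mean(axis=(0, 1)) - 0.5  # equal channel means, no clipping
        out = compensate_channels(img)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_saturated_red_pixel_unchanged(self):
        img = np.full((4, 4, 3), 0.3)
        img[..., 1] = 0.8  # green mean above red: compensation would raise red
        img[2, 2, 0] = 1.0
        out = compensate_channels(img)
        assert out[2, 2, 0] == pytest.approx(1.0)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            compensate_channels(np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# gamma and sharpening
# ---------------------------------------------------------------------------

def test_gamma_hand_values(random_image):
    assert gamma_correct(np.array([[[0.25] * 3]]), 2.0)[0, 0, 0] == pytest.approx(0.0625)
    np.testing.assert_allclose(gamma_correct(random_image, 1.0), random_image)
    ends = gamma_correct(np.array([[[0.0, 1.0, 0.5]]]), 3.7)
    assert ends[0, 0, 0] == 0.0 and ends[0, 0, 1] == 1.0


def test_gamma_rejects_nonpositive():
    with pytest.raises(ValueError):
        gamma_correct(np.zeros((2, 2, 3)), 0.0)


class TestSharpen:
    def test_all_zero_maps_to_zero(self):
        out = sharpen(np.zeros((8, 8, 3)))
        np.testing.assert_allclose(out, 0.0)

    def test_range_closure(self, random_image):
        out = sharpen(random_image)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_matches_brute_force_reference(self):
        # independent elementwise recomputation: blur, diff, stretch, average
        img = np.zeros((8, 8, 3))
        img[3, 4, :] = 1.0
        cfg = EnhancementConfig(sharpen_sigma=1.0)
        blurred = np.stack(
            [
                ndimage.gaussian_filter(img[..., c], 1.0, mode="reflect", truncate=4.0)
                for c in range(3)
            ],
            axis=-1,
        )
        diff = img - blurred
        stretched = (diff - diff.min()) / (diff.max() - diff.min())
        expected = (img + stretched) / 2.0
        np.testing.assert_allclose(sharpen(img, cfg), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# weight maps
# ---------------------------------------------------------------------------

class TestWeightMaps:
    def test_laplacian_constant_image_zero(self):
        assert laplacian_contrast_weight(np.full((6, 6, 3), 0.4)).max() == 0.0

    def test_laplacian_hand_convolution(self):
        # 3x3 luminance, center 1: |Laplacian| is 4 at center, 1 at edges
        img = np.zeros((3, 3, 3))
        img[1, 1, :] = 1.0
        w = laplacian_contrast_weight(img)
        assert w[1, 1] == pytest.approx(4.0)
        for pos in [(0, 1), (1, 0), (1, 2), (2, 1)]:
            assert w[pos] == pytest.approx(1.0)
        for pos in [(0, 0), (0, 2), (2, 0), (2, 2)]:
            assert w[pos] == pytest.approx(0.0)

    def test_laplacian_nonnegative(self, random_image):
        assert laplacian_contrast_weight(random_image).min() >= 0.0

    def test_saliency_constant_image_zero(self):
        np.testing.assert_allclose(
            saliency_weight(np.full((16, 16, 3), 0.37)), 0.0, atol=1e-9
        )

    def test_saliency_matches_brute_force(self):
        img = np.zeros((16, 16, 3))
        img[:, 8:, :] = 0.8  # two-tone half-dark/half-bright
        lab = skcolor.rgb2lab(img) / 100.0
        blurred = np.stack(
            [
                ndimage.gaussian_filter(img[..., c], 1.0, mode="reflect", truncate=4.0)
                for c in range(3)
            ],
            axis=-1,
        )
        lab_blur = skcolor.rgb2lab(np.clip(blurred, 0, 1)) / 100.0
        expected = np.sqrt(
            ((lab_blur - lab.reshape(-1, 3).mean(axis=0)) ** 2).sum(axis=2)
        )
        np.testing.assert_allclose(saliency_weight(img), expected, atol=1e-12)
        assert expected.min() >= 0.0

    def test_saturation_gray_is_zero(self):
        assert saturation_weight(np.full((5, 5, 3), 0.6)).max() == 0.0

    def test_saturation_hand_value(self):
        # pure red pixel: L=1/3, WSat = (1/3)[(2/3)^2 + 2*(1/3)^2] = 2/9
        img = np.zeros((1, 1, 3))
        img[0, 0, 0] = 1.0
        assert saturation_weight(img)[0, 0] == pytest.approx(2.0 / 9.0)
        assert saturation_weight(img, sqrt_form=True)[0, 0] == pytest.approx(
            math.sqrt(2.0 / 9.0)
        )

    def test_saturation_nonnegative(self, random_image):
        assert saturation_weight(random_image).min() >= 0.0


class TestNormalizeWeights:
    def test_hand_values(self):
        w1 = np.full((2, 2), 0.3)
        w2 = np.full((2, 2), 0.1)
        n1, n2 = normalize_weights([w1, w2], delta=0.1)
        np.testing.assert_allclose(n1, 0.4 / 0.6)
        np.testing.assert_allclose(n2, 0.2 / 0.6)

    def test_zero_maps_split_evenly(self):
        n1, n2 = normalize_weights([np.zeros((3, 3)), np.zeros((3, 3))], delta=0.1)
        np.testing.assert_allclose(n1, 0.5)
        np.testing.assert_allclose(n2, 0.5)

    def test_sums_to_one_everywhere(self, rng):
        maps = [rng.uniform(0, 5, (9, 7)) for _ in range(4)]
        normalized = normalize_weights(maps, delta=0.1)
        np.testing.assert_allclose(np.sum(normalized, axis=0), 1.0, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            normalize_weights([np.zeros((2, 2)), np.zeros((3, 3))], 0.1)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class TestFusion:
    def test_naive_hand_value(self):
        a = np.full((4, 4, 3), 0.2)
        b = np.full((4, 4, 3), 0.8)
        w = [np.full((4, 4), 0.25), np.full((4, 4), 0.75)]
        np.testing.assert_allclose(naive_fusion([a, b], w), 0.65)

    def test_naive_selection_and_convexity(self, rng):
        a = rng.uniform(0, 1, (6, 6, 3))
        b = rng.uniform(0, 1, (6, 6, 3))
        sel = naive_fusion([a, b], [np.ones((6, 6)), np.zeros((6, 6))])
        np.testing.assert_allclose(sel, a)
        w = rng.uniform(0, 1, (6, 6))
        same = naive_fusion([a, a], [w, 1.0 - w])
        np.testing.assert_allclose(same, a, atol=1e-12)

    def test_pyramid_shapes_and_single_level(self, rng):
        img = np.linspace(0, 1, 16 * 16 * 3).reshape(16, 16, 3)
        pyr = build_pyramid(img, 3, "laplacian")
        assert [lv.shape[:2] for lv in pyr.levels] == [(16, 16), (8, 8), (4, 4)]
        single = build_pyramid(img, 1, "gaussian")
        np.testing.assert_allclose(single.levels[0], img)

    def test_pyramid_collapse_roundtrip(self, rng):
        for _ in range(10):
            img = rng.uniform(0, 1, (24, 20, 3))
            pyr = build_pyramid(img, 3, "laplacian")
            rec = collapse_pyramid(pyr)
            assert np.abs(rec - img).max() <= 0.02

    def test_pyramid_too_deep_raises(self):
        with pytest.raises(ValueError):
            build_pyramid(np.zeros((8, 8, 3)), 4, "gaussian")

    def test_multiscale_single_level_equals_naive(self, rng):
        a = rng.uniform(0, 1, (12, 12, 3))
        b = rng.uniform(0, 1, (12, 12, 3))
        w = normalize_weights([rng.uniform(0, 1, (12, 12)) for _ in range(2)], 0.1)
        fused = multiscale_fusion([a, b], w, levels=1)
        np.testing.assert_allclose(
            fused, np.clip(naive_fusion([a, b], w), 0, 1), atol=1e-12
        )

    def test_multiscale_identical_inputs_reconstruct(self, rng):
        img = rng.uniform(0, 1, (32, 32, 3))
        w = normalize_weights([rng.uniform(0, 1, (32, 32)) for _ in range(2)], 0.1)
        fused = multiscale_fusion([img, img], w, levels=3)
        assert np.abs(fused - img).max() <= 0.02

    def test_multiscale_matches_straightline_reference(self, rng):
        # reference written directly from the per-level blend formula
        a = rng.uniform(0, 1, (32, 32, 3))
        b = rng.uniform(0, 1, (32, 32, 3))
        weights = normalize_weights([rng.uniform(0, 1, (32, 32)) for _ in range(2)], 0.1)
        levels = 3
        fused_levels = None
        for img, w in zip([a, b], weights):
            lap = build_pyramid(img, levels, "laplacian").levels
            gau = build_pyramid(w, levels, "gaussian").levels
            bands = [g[..., None] * l for g, l in zip(gau, lap)]
            if fused_levels is None:
                fused_levels = bands
            else:
                fused_levels = [f + x for f, x in zip(fused_levels, bands)]
        from histocaps import ImagePyramid

        expected = np.clip(
            collapse_pyramid(ImagePyramid(levels=fused_levels, flavor="laplacian")),
            0,
            1,
        )
        got = multiscale_fusion([a, b], weights, levels)
        np.testing.assert_allclose(got, expected, atol=1e-6)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestEnhanceImage:
    def test_contract_shape_range_determinism(self, cast_image):
        out1 = enhance_image(cast_image)
        out2 = enhance_image(cast_image)
        assert out1.shape == cast_image.shape
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        np.testing.assert_array_equal(out1, out2)

    def test_channel_spread_shrinks_on_cast_fixture(self, cast_image):
        before = cast_image.mean(axis=(0, 1))
        after = enhance_image(cast_image).mean(axis=(0, 1))
        assert before.max() - before.min() > after.max() - after.min()

    def test_default_levels_keep_min_side(self):
        assert default_pyramid_levels((50, 50, 3)) == 3   # 50 -> 25 -> 13
        assert default_pyramid_levels((8, 8)) == 1


def test_image_io_roundtrip(tmp_path, rng):
    img = rng.uniform(0, 1, (10, 12, 3))
    path = tmp_path / "tile.png"
    save_image(path, img)
    back = load_image(path)
    assert back.shape == img.shape
    assert np.abs(back - img).max() <= 1.0 / 255.0 + 1e-9
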