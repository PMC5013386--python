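import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.morphology import disk

from biofilmquant.imgio import GrayImage
from biofilmquant.preprocess import (PreprocessConfig, apply_preset, enhance_contrast,
                                     gamma_adjust, remove_outliers, sharpen,
                                     subtract_background)


def _img(arr):
    return GrayImage(np.asarray(arr, dtype=np.uint8))


def _disc_fixture(value=200, radius=3, size=128):
    arr = np.zeros((size, size))
    rr, cc = draw_disk((size // 2, size // 2), radius)
    arr[rr, cc] = value
    return arr


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(_img(np.full((64, 64), 173)), 1000)
        assert np.all(out.pixels == 0)

    def test_small_bright_disc_preserved(self):
        arr = _disc_fixture()
        out = subtract_background(_img(arr), 1000)
        # oracle: grayscale opening with a large flat element
        oracle = np.clip(arr - ndi.grey_opening(arr, footprint=disk(40)), 0, 255)
        assert np.abs(out.pixels.astype(int) - np.rint(oracle).astype(int)).max() <= 1

    def test_gentle_ramp_removed_disc_preserved(self):
        size = 128
        ramp = np.tile(np.linspace(0, 4, size), (size, 1))  # ~0.03 levels/px
        arr = np.rint(ramp + _disc_fixture()).astype(np.uint8)
        out = subtract_background(_img(arr), 1000)
        oracle = np.clip(arr.astype(float) - ndi.grey_opening(arr.astype(float),
                                                              footprint=disk(40)), 0, 255)
        assert np.abs(out.pixels.astype(int) - np.rint(oracle).astype(int)).max() <= 2
        mask = _disc_fixture() > 0
        assert out.pixels[~mask].max() <= 2  # residual background
        assert out.pixels[64, 64] >= 195  # disc height intact

    def test_mean_never_increases(self, rng):
        img = _img(rng.integers(0, 256, (96, 96)))
        out = subtract_background(img, 1000)
        assert out.pixels.mean() <= img.pixels.mean()

    def test_flat_ball_variant_runs(self):
        arr = _disc_fixture(size=64)
        out = subtract_background(_img(arr), radius=20, paraboloid=False)
        assert out.shape == (64, 64)


class TestEnhanceContrast:
    def test_full_range_zero_pct_is_identity(self):
        arr = np.tile(np.linspace(0, 255, 256).astype(np.uint8), (32, 1))
        out = enhance_contrast(_img(arr), 0.0)
        assert np.array_equal(out.pixels, arr)

    def test_constant_image_unchanged(self):
        img = _img(np.full((64, 64), 99))
        assert np.array_equal(enhance_contrast(img, 1.0).pixels, img.pixels)

    def test_percentile_rule_on_linear_ramp(self):
        # 1024 ramp pixels; 1% saturation -> 5 pixels clipped at each end
        vals = (np.arange(1024) * 255 // 1023).astype(np.uint8)
        arr = vals.reshape(32, 32)
        out = enhance_contrast(_img(arr), 1.0)
        v = np.sort(arr, axis=None).astype(float)
        k = int(arr.size * 1.0 / 200.0)
        assert k == 5
        vmin, vmax = v[k], v[len(v) - 1 - k]
        oracle = np.rint(np.clip((arr - vmin) / (vmax - vmin) * 255.0, 0, 255))
        assert np.array_equal(out.pixels, oracle.astype(np.uint8))
        assert out.pixels.min() == 0 and out.pixels.max() == 255

    def test_histogram_order_preserved(self, rng):
        arr = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = enhance_contrast(_img(arr), 2.0)
        flat_in, flat_out = arr.ravel(), out.pixels.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order].astype(int)) >= 0)


class TestRemoveOutliers:
    def test_single_hot_pixel_removed(self):
        arr = np.zeros((64, 64))
        arr[30, 30] = 255
        out = remove_outliers(_img(arr), threshold=50, radius=2)
        assert out.pixels[30, 30] == 0
        assert np.count_nonzero(out.pixels) == 0

    def test_exact_threshold_excess_is_kept(self):
        arr = np.zeros((64, 64))
        arr[30, 30] = 50  # exceeds local median (0) by exactly the threshold
        out = remove_outliers(_img(arr), threshold=50, radius=2)
        assert out.pixels[30, 30] == 50

    def test_threshold_zero_matches_bruteforce_disc_median(self, rng):
        arr = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        out = remove_outliers(_img(arr), threshold=0, radius=2)
        fp = disk(2).astype(bool)
        pad = np.pad(arr, 2, mode="symmetric")  # scipy reflect convention
        for y in range(40):
            for x in range(0, 40, 3):
                neigh = pad[y:y + 5, x:x + 5][fp]
                med = np.median(neigh)
                expected = med if arr[y, x] > med else arr[y, x]
                assert out.pixels[y, x] == expected
        assert np.all(out.pixels <= arr)  # bright polarity never increases


class TestGammaSharpen:
    def test_gamma_endpoints_and_identity(self):
        arr = np.zeros((32, 32), dtype=np.uint8)
        arr[0, 0] = 255
        out = gamma_adjust(_img(arr), 0.6)
        assert out.pixels[0, 0] == 255 and out.pixels[1, 1] == 0
        img = _img(np.arange(32 * 32).reshape(32, 32) % 256)
        assert np.array_equal(gamma_adjust(img, 1.0).pixels, img.pixels)

    def test_gamma_midpoint_value(self):
        arr = np.full((32, 32), 128, dtype=np.uint8)  # 128/255 ~ 0.502
        out = gamma_adjust(_img(arr), 0.6)
        expected = round((128 / 255) ** 0.6 * 255)
        assert np.all(out.pixels == expected)

    def test_gamma_strictly_monotone(self):
        levels = np.tile(np.arange(256, dtype=np.uint8), (32, 1))[:, :256]
        img = GrayImage(levels[:32, :])
        for g in (0.3, 0.6, 1.7):
            out = gamma_adjust(img, g).pixels[0].astype(int)
            assert np.all(np.diff(out) >= 0)
            assert out[0] == 0 and out[-1] == 255

    def test_sharpen_constant_unchanged(self):
        img = _img(np.full((64, 64), 77))
        assert np.array_equal(sharpen(img).pixels, img.pixels)

    def test_sharpen_impulse_is_tripled(self):
        arr = np.zeros((33, 33))
        arr[16, 16] = 60
        out = sharpen(_img(arr))
        assert out.pixels[16, 16] == 180
        assert out.pixels[16, 17] == 0  # -60/4 clipped

    def test_sharpen_matches_naive_convolution(self, rng):
        arr = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        out = sharpen(_img(arr))
        kernel = np.array([[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]]) / 4.0
        pad = np.pad(arr.astype(float), 1, mode="symmetric")
        oracle = np.zeros((32, 32))
        for y in range(32):
            for x in range(32):
                oracle[y, x] = (pad[y:y + 3, x:x + 3] * kernel[::-1, ::-1]).sum()
        oracle = np.rint(np.clip(oracle, 0, 255))
        assert np.array_equal(out.pixels, oracle.astype(np.uint8))


class TestPresets:
    @pytest.mark.parametrize("surface", ["sla", "polished"])
    def test_preset_on_constant_image_stays_constant(self, surface):
        img = _img(np.full((64, 64), 120))
        out = apply_preset(img, PreprocessConfig.for_surface(surface))
        assert len(np.unique(out.pixels)) == 1

    def test_sla_preset_equals_manual_composition(self, sla_pair):
        cfg = PreprocessConfig.for_surface("sla")
        img = sla_pair.before_img
        manual = subtract_background(img, cfg.rolling_ball_radius, cfg.use_paraboloid)
        manual = enhance_contrast(manual, cfg.contrast_saturated_pct)
        manual = remove_outliers(manual, cfg.outlier_threshold, cfg.outlier_radius)
        manual = gamma_adjust(manual, cfg.gamma)
        manual = sharpen(manual)
        assert np.array_equal(apply_preset(img, cfg).pixels, manual.pixels)

    def test_polished_preset_equals_manual_composition(self, polished_pair):
        cfg = PreprocessConfig.for_surface("polished")
        img = polished_pair.before_img
        manual = remove_outliers(enhance_contrast(img, 0.4), 0.0, 2)
        assert np.array_equal(apply_preset(img, cfg).pixels, manual.pixels)

    def test_all_filters_preserve_range_and_shape(self, sla_pair):
        img = sla_pair.before_img
        for out in (subtract_background(img, 1000), enhance_contrast(img, 1.0),
                    remove_outliers(img, 50, 2), gamma_adjust(img, 0.6), sharpen(img)):
            assert out.shape == img.shape
            assert out.pixels.dtype == np.uint8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(contrast_saturated_pct=60.0)
        with pytest.raises(ValueError):
            PreprocessConfig(gamma=0.0)
        with pytest.raises(ValueError):
            PreprocessConfig(rolling_ball_radius=0)
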