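import numpy as np
import pytest

from retinavasc.phantoms import disc_mask
from retinavasc.preprocessing import (
    CONVENTIONAL_GRAY_COEFFS,
    EmptyRoiError,
    PreprocessConfig,
    clahe_enhance,
    extract_roi,
    median_denoise,
    normalize,
    to_grayscale,
)


def _rgb(value, shape=(40, 40)):
    img = np.zeros(shape + (3,), np.float64)
    img[:] = value
    return img


class TestGrayscale:
    @pytest.mark.parametrize(
        "pixel,expected",
        [
            ((255, 0, 0), 76.245),
            ((0, 0, 0), 0.0),
            ((100, 100, 100), 103.0),  # coefficient sum is 1.03, not 1
        ],
    )
    def test_weighted_sum(self, pixel, expected):
        img = _rgb(pixel, shape=(4, 4))
        assert to_grayscale(img) == pytest.approx(np.full((4, 4), expected))

    def test_conventional_weights_sum_to_one(self):
        img = _rgb((100, 100, 100), shape=(4, 4))
        out = to_grayscale(img, CONVENTIONAL_GRAY_COEFFS)
        assert out == pytest.approx(np.full((4, 4), 100.0))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (16, 16, 3)).astype(float)
        for a in (0.25, 0.5, 1.0):
            assert to_grayscale(a * img) == pytest.approx(a * to_grayscale(img))


class TestRoi:
    def _flood_fill_components(self, mask):
        """Hand-rolled 8-connected component labeling (independent oracle)."""
        mask = np.asarray(mask, bool)
        seen = np.zeros_like(mask)
        comps = []
        for r0, c0 in zip(*np.nonzero(mask)):
            if seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], set()
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
        return comps

    def test_bright_disk_recovered(self):
        img = np.zeros((300, 300, 3), np.uint8)
        disk = disc_mask(300, (150, 150), 200)
        img[disk] = 200
        roi = extract_roi(img)
        assert abs(roi.sum() - np.pi * 100**2) / (np.pi * 100**2) < 0.02
        # oracle: threshold + flood fill, largest component
        red = img[..., 0].astype(float)
        cand = red >= red.mean() / 3
        largest = max(self._flood_fill_components(cand), key=len)
        overlap = sum(roi[r, c] for r, c in largest)
        assert overlap / len(largest) > 0.98

    def test_uniform_image_full_frame(self):
        roi = extract_roi(_rgb((128, 128, 128)))
        assert roi.all()

    def test_all_zero_errors(self):
        with pytest.raises(EmptyRoiError):
            extract_roi(_rgb((0, 0, 0)))

    def test_single_component_and_idempotent(self):
        img = np.zeros((300, 300, 3), np.uint8)
        img[disc_mask(300, (150, 150), 200)] = 200
        img[disc_mask(300, (20, 20), 10)] = 200  # decoy blob
        roi = extract_roi(img)
        assert len(self._flood_fill_components(roi)) == 1
        roi2 = extract_roi(img * roi[..., None])
        assert np.array_equal(roi, roi2)


class TestMedian:
    def test_constant_unchanged(self):
        img = _rgb((77, 77, 77))
        assert median_denoise(img, 3) == pytest.approx(img)

    def test_isolated_outlier_removed(self):
        img = np.zeros((11, 11))
        img[5, 5] = 255
        assert median_denoise(img, 3)[5, 5] == 0

    def test_sort_and_pick_oracle(self):
        img = np.arange(1.0, 10.0).reshape(3, 3)
        assert median_denoise(img, 3)[1, 1] == np.sort(img.ravel())[4] == 5

    @pytest.mark.parametrize("k", [2, 4, 1])
    def test_even_or_small_kernel_rejected(self, k):
        with pytest.raises(ValueError):
            median_denoise(np.zeros((8, 8)), k)

    def test_range_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (32, 32, 3)).astype(float)
        out = median_denoise(img, 5)
        assert out.min() >= 0 and out.max() <= 255


class TestNormalize:
    def test_additive_mean_calibration(self):
        img = _rgb((80, 80, 80))
        out = normalize(img, (120, 120, 120), None)
        assert out.reshape(-1, 3).mean(axis=0) == pytest.approx([120, 120, 120], abs=0.5)
        assert out[0, 0, 0] == pytest.approx(120.0)  # pure +40 shift

    def test_multiplicative_mean_calibration(self):
        img = _rgb((80, 60, 40))
        out = normalize(img, (120, 120, 120), None, calibration="multiplicative")
        assert out.reshape(-1, 3).mean(axis=0) == pytest.approx([120, 120, 120], abs=0.5)

    def test_constant_resize(self):
        out = normalize(_rgb((42, 42, 42), (512, 512)), None, 256)
        assert out.shape == (256, 256, 3)
        assert out == pytest.approx(42.0)

    def test_bilinear_center_of_checkerboard(self):
        cb = np.zeros((2, 2, 3))
        cb[0, 1] = 100
        cb[1, 0] = 100
        out = normalize(cb, None, 3)
        assert out[1, 1, 0] == pytest.approx(50.0)

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            normalize(_rgb((50, 50, 50)), None, 1)

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize(_rgb((50, 50, 50)), (0, 120, 120), None)


class TestClahe:
    def test_constant_stays_constant(self):
        out = clahe_enhance(np.full((64, 64), 128.0))
        assert np.ptp(out) < 1e-6

    def test_two_level_monotone(self):
        img = np.full((64, 64), 50.0)
        img[:, 32:] = 200.0
        out = clahe_enhance(img)
        assert out[:, :32].max() < out[:, 32:].min()

    def test_low_contrast_range_grows(self):
        ramp = np.tile(np.linspace(100, 140, 64), (64, 1))
        out = clahe_enhance(ramp)
        assert np.ptp(out) > np.ptp(ramp)

    def test_output_bounded(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (64, 64))
        out = clahe_enhance(img, clip=4.0, tiles=4)
        assert out.min() >= 0 and out.max() <= 255

    @pytest.mark.parametrize("kwargs", [{"clip": 0}, {"tiles": 0}])
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            clahe_enhance(np.zeros((32, 32)), **kwargs)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(median_kernel=4)
    with pytest.raises(ValueError):
        PreprocessConfig(roi_threshold_fraction=1.5)
    with pytest.raises(ValueError):
        PreprocessConfig(gray_coeffs=(0.3, -0.1, 0.2))
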