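"""CT preprocessing: HU windowing, cropping, equalization, normalization,
tumor-slice filtering and 2.5D stacking."""

import numpy as np
import pytest

from risunet.preprocess import (CTVolume, MaskVolume, PreprocessConfig,
                                build_stack, center_crop, crop_mask,
                                filter_tumor_slices, hist_equalize,
                                normalize01, preprocess_case,
                                preprocess_volume, window_hu)


def _vol(data, spacing=(1, 1, 1)):
    return CTVolume(np.asarray(data, dtype=float), spacing)


class TestWindowHU:
    def test_clamps_to_bounds(self, rng):
        vol = _vol(rng.normal(0, 600, size=(8, 8, 4)))
        out = window_hu(vol, -200, 200)
        assert out.data.min() >= -200 and out.data.max() <= 200
        assert out.data.shape == vol.data.shape
        assert out.spacing == vol.spacing

    def test_pointwise_values(self):
        vol = _vol(np.array([[[0.0, 1000.0, -800.0]]]))
        out = window_hu(vol, -200, 200)
        np.testing.assert_array_equal(out.data, [[[0.0, 200.0, -200.0]]])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            window_hu(_vol(np.zeros((2, 2, 2))), 200, -200)


class TestCenterCrop:
    def test_512_to_448_window(self):
        img = np.arange(512 * 512, dtype=float).reshape(512, 512)
        out = center_crop(img, 448)
        np.testing.assert_array_equal(out, img[32:480, 32:480])

    def test_identity_when_full_size(self, rng):
        img = rng.random((64, 64))
        np.testing.assert_array_equal(center_crop(img, 64), img)

    def test_odd_margin_goes_high_side(self):
        img = np.arange(49, dtype=float).reshape(7, 7)
        # 7 -> 4: margin 3, low side gets 1, high side 2 -> rows/cols [1, 5)
        np.testing.assert_array_equal(center_crop(img, 4), img[1:5, 1:5])

    def test_too_large_crop_rejected(self, rng):
        with pytest.raises(ValueError):
            center_crop(rng.random((8, 8)), 9)


class TestHistEqualize:
    def test_constant_image_stays_constant(self):
        out = hist_equalize(np.full((5, 5), 3.7), 0, 10)
        assert np.unique(out).size == 1

    def test_monotone_in_input(self, rng):
        img = rng.normal(0, 50, size=(32, 32))
        out = hist_equalize(img, -200, 200)
        order = np.argsort(img.ravel())
        assert (np.diff(out.ravel()[order]) >= -1e-12).all()
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_matches_empirical_cdf(self):
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        out = hist_equalize(img, 0.0, 3.0, n_bins=4)
        np.testing.assert_allclose(out, [[0.25, 0.5], [0.75, 1.0]])


class TestNormalize01:
    def test_endpoints(self, rng):
        img = rng.normal(size=(16, 16))
        out = normalize01(img)
        assert out[np.unravel_index(img.argmin(), img.shape)] == 0.0
        assert out[np.unravel_index(img.argmax(), img.shape)] == 1.0

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize01(np.full((4, 4), 7.0)),
                                      np.zeros((4, 4)))

    def test_formula_oracle(self, rng):
        img = rng.normal(size=(10, 10))
        expected = (img - img.min()) / (img.max() - img.min())
        np.testing.assert_allclose(normalize01(img), expected, atol=1e-12)


class TestFilterTumorSlices:
    def test_empty_mask(self):
        assert filter_tumor_slices(MaskVolume(np.zeros((4, 4, 6), dtype=int))) == []

    def test_explicit_slices(self):
        data = np.zeros((4, 4, 9), dtype=int)
        data[1, 2, 3] = 1
        data[0, 0, 7] = 1
        assert filter_tumor_slices(MaskVolume(data)) == [3, 7]

    def test_matches_brute_force(self, rng):
        data = (rng.random((6, 6, 12)) > 0.97).astype(int)
        expected = [t for t in range(12) if data[:, :, t].any()]
        assert filter_tumor_slices(MaskVolume(data)) == expected


class TestBuildStack:
    def test_single_slice_degenerate(self, rng):
        vol = _vol(rng.random((5, 5, 4)))
        stack = build_stack(vol, 2, 1)
        assert stack.data.shape == (1, 5, 5)
        np.testing.assert_array_equal(stack.data[0], vol.data[:, :, 2])

    def test_boundary_zero_fill(self, rng):
        vol = _vol(rng.random((5, 5, 4)))
        stack = build_stack(vol, 0, 3)
        np.testing.assert_array_equal(stack.data[0], np.zeros((5, 5)))
        np.testing.assert_array_equal(stack.data[1], vol.data[:, :, 0])
        np.testing.assert_array_equal(stack.data[2], vol.data[:, :, 1])

    def test_interior_window(self, rng):
        vol = _vol(rng.random((4, 4, 20)))
        stack = build_stack(vol, 5, 5)
        for k, s in enumerate(range(3, 8)):
            np.testing.assert_array_equal(stack.data[k], vol.data[:, :, s])

    def test_errors(self, rng):
        vol = _vol(rng.random((4, 4, 4)))
        with pytest.raises(IndexError):
            build_stack(vol, 4, 3)
        with pytest.raises(ValueError):
            build_stack(vol, 0, 2)


class TestPreprocessCase:
    def _case(self, rng, shape=(72, 80, 6), n_tumor_slices=3):
        vol = _vol(rng.normal(0, 300, size=shape))
        mask = np.zeros(shape, dtype=int)
        for t in range(n_tumor_slices):
            mask[shape[0] // 2, shape[1] // 2, 2 * t] = 1
        return vol, MaskVolume(mask)

    def test_stack_shapes_and_count(self, rng):
        vol, mask = self._case(rng)
        cfg = PreprocessConfig(crop_size=64)
        pairs = preprocess_case(vol, mask, cfg)
        assert len(pairs) == 3          # one stack per tumor-bearing slice
        for stack, m in pairs:
            assert stack.data.shape == (3, 64, 64)
            assert m.shape == (64, 64)

    def test_empty_tumor_gives_empty_sequence(self, rng):
        vol, _ = self._case(rng)
        mask = MaskVolume(np.zeros(vol.data.shape, dtype=int))
        assert preprocess_case(vol, mask, PreprocessConfig(crop_size=64)) == []

    def test_keep_all_slices(self, rng):
        vol, mask = self._case(rng)
        cfg = PreprocessConfig(crop_size=64, keep_only_tumor_slices=False)
        assert len(preprocess_case(vol, mask, cfg)) == vol.n_slices

    def test_mask_alignment(self, rng):
        vol, mask = self._case(rng)
        cfg = PreprocessConfig(crop_size=64)
        cropped = crop_mask(mask, 64)
        for stack, m in preprocess_case(vol, mask, cfg):
            np.testing.assert_array_equal(m, cropped.data[:, :, stack.center_index])

    def test_deterministic(self, rng):
        vol, mask = self._case(rng)
        cfg = PreprocessConfig(crop_size=64)
        a = preprocess_case(vol, mask, cfg)
        b = preprocess_case(vol, mask, cfg)
        for (sa, ma), (sb, mb) in zip(a, b):
            np.testing.assert_array_equal(sa.data, sb.data)
            np.testing.assert_array_equal(ma, mb)

    def test_shape_mismatch_rejected(self, rng):
        vol, _ = self._case(rng)
        mask = MaskVolume(np.zeros((8, 8, 2), dtype=int))
        with pytest.raises(ValueError):
            preprocess_case(vol, mask, PreprocessConfig(crop_size=8))


def test_window_and_crop_commute(rng):
    """Pointwise windowing commutes with spatial selection."""
    vol = _vol(rng.normal(0, 400, size=(20, 24, 5)))
    a = np.stack([center_crop(window_hu(vol, -200, 200).data[:, :, t], 16)
                  for t in range(5)], axis=2)
    windowed_after = window_hu(_vol(np.stack(
        [center_crop(vol.data[:, :, t], 16) for t in range(5)], axis=2)),
        -200, 200)
    np.testing.assert_array_equal(a, windowed_after.data)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(hu_lo=100, hu_hi=-100)
    with pytest.raises(ValueError):
        PreprocessConfig(n_slices=2)
    with pytest.raises(ValueError):
        CTVolume(np.zeros((4, 4, 4)), spacing=(1, -1, 1))
    with pytest.raises(ValueError):
        MaskVolume(np.full((2, 2, 2), 3))


def test_preprocessed_volume_range(rng):
    vol = _vol(rng.normal(0, 500, size=(40, 40, 4)))
    out = preprocess_volume(vol, PreprocessConfig(crop_size=32))
    assert out.data.shape == (32, 32, 4)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
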