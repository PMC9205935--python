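import numpy as np
import pytest
from scipy import ndimage

from radsig.grids import RoiMask, VolumetricImage
from radsig.phantom import PhantomConfig, generate_phantom
from radsig.preprocess import (PreprocessConfig, correct_bias_field,
                               log_filter_bank, log_single, mask_background,
                               resample_isotropic, resegment_hu,
                               scale_to_percentile, soft_tissue_mask)


def _body_truth(cfg, mr):
    return RoiMask(mr.meta["body_mask"], mr.spacing_mm)


class TestSoftTissueMask:
    def test_phantom_body_dice(self):
        cfg = PhantomConfig(grid_shape=(48, 48, 24), background_offset=2.0)
        mr, _, _ = generate_phantom(cfg, seed=5)
        truth = _body_truth(cfg, mr).values
        mask = soft_tissue_mask(mr).values
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_masked_image_background_exactly_zero(self):
        cfg = PhantomConfig(background_offset=10.0)
        mr, _, _ = generate_phantom(cfg, seed=6)
        mask = soft_tissue_mask(mr)
        masked = mask_background(mr, mask)
        assert (masked.values[~mask.values] == 0).all()
        np.testing.assert_array_equal(masked.values[mask.values],
                                      mr.values[mask.values])

    def test_empty_mask_raises_with_advice(self):
        img = VolumetricImage(np.zeros((8, 8, 8)), (1, 1, 1), modality="MR")
        with pytest.raises(ValueError, match="canny"):
            soft_tissue_mask(img)


class TestBiasCorrection:
    def _uniform_body(self, amplitude, seed=3):
        cfg = PhantomConfig(grid_shape=(32, 32, 16), noise_sd=0.0,
                            mr_bias_amplitude=amplitude,
                            texture_corr_len_mm=np.inf,
                            gtv_level=100.0)  # homogeneous body
        mr, _, _ = generate_phantom(cfg, seed=seed)
        body = RoiMask(mr.meta["body_mask"], mr.spacing_mm)
        return mr, body

    def test_bias_free_image_left_nearly_unchanged(self):
        mr, body = self._uniform_body(0.0)
        out = correct_bias_field(mask_background(mr, body), body)
        rel = np.abs(out.values[body.values] - mr.values[body.values])
        rel /= mr.values[body.values]
        assert rel.max() < 0.01

    def test_known_field_reduces_cov(self):
        cfg = PhantomConfig(grid_shape=(32, 32, 16), noise_sd=0.5,
                            mr_bias_amplitude=0.3)
        mr, _, _ = generate_phantom(cfg, seed=8)
        body = RoiMask(mr.meta["body_mask"], mr.spacing_mm)
        out = correct_bias_field(mask_background(mr, body), body)
        cov_in = mr.values[body.values].std() / mr.values[body.values].mean()
        cov_out = out.values[body.values].std() / out.values[body.values].mean()
        assert cov_out < cov_in

    def test_constant_times_smooth_field_recovered(self):
        mr, body = self._uniform_body(0.3, seed=11)
        out = correct_bias_field(mask_background(mr, body), body)
        vals = out.values[body.values]
        assert vals.max() / vals.min() <= 1.05

    def test_mean_preserved(self):
        mr, body = self._uniform_body(0.2, seed=12)
        out = correct_bias_field(mask_background(mr, body), body)
        before = mr.values[body.values].mean()
        after = out.values[body.values].mean()
        assert abs(after - before) / before < 0.01


class TestPercentileScaling:
    def _image(self, in_mask_values):
        vals = np.zeros((10, 10, 1))
        mask = np.zeros((10, 10, 1), dtype=bool)
        flat = np.asarray(in_mask_values, dtype=float)
        vals.ravel()[:flat.size] = flat
        mask.ravel()[:flat.size] = True
        return (VolumetricImage(vals, (1, 1, 1)), RoiMask(mask, (1, 1, 1)))

    def test_uniform_1_to_100(self):
        img, mask = self._image(np.arange(1, 101))
        out = scale_to_percentile(img, mask, 95)
        expected_divisor = np.percentile(np.arange(1, 101), 95)
        assert out.meta["scale_divisor"] == pytest.approx(expected_divisor)
        assert out.values[mask.values].max() == pytest.approx(
            100 / expected_divisor)

    def test_constant_image_scales_to_one(self):
        img, mask = self._image(np.full(50, 7.0))
        out = scale_to_percentile(img, mask)
        assert np.allclose(out.values[mask.values], 1.0)

    def test_idempotence(self):
        img, mask = self._image(np.arange(1, 101))
        once = scale_to_percentile(img, mask)
        twice = scale_to_percentile(once, mask)
        assert twice.meta["scale_divisor"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_divisor_raises(self):
        img, mask = self._image(np.zeros(30))
        with pytest.raises(ValueError, match="degenerate"):
            scale_to_percentile(img, mask)


class TestResampling:
    def test_identity_at_target_spacing(self):
        rng = np.random.default_rng(0)
        img = VolumetricImage(rng.uniform(size=(8, 9, 10)), (1, 1, 1))
        out, _ = resample_isotropic(img, None, 1.0)
        assert out.shape == img.shape
        np.testing.assert_allclose(out.values, img.values, atol=1e-9)

    def test_constant_preserved(self):
        img = VolumetricImage(np.full((6, 6, 4), 3.5), (0.7, 1.3, 2.0))
        out, _ = resample_isotropic(img, None, 1.0)
        np.testing.assert_allclose(out.values, 3.5, atol=1e-12)

    def test_linear_ramp_exact(self):
        # trilinear interpolation is exact on affine fields
        sp = (0.8, 1.1, 2.0)
        idx = np.meshgrid(*[np.arange(n) * s for n, s in
                            zip((12, 12, 8), sp)], indexing="ij")
        ramp = 2.0 * idx[0] + 0.5 * idx[1] - 1.5 * idx[2] + 3.0
        img = VolumetricImage(ramp, sp)
        out, _ = resample_isotropic(img, None, 1.0)
        oidx = np.meshgrid(*[np.arange(n) for n in out.shape], indexing="ij")
        expected = 2.0 * oidx[0] + 0.5 * oidx[1] - 1.5 * oidx[2] + 3.0
        # interior points (edge handling may clamp at boundaries)
        sl = tuple(slice(1, -1) for _ in range(3))
        np.testing.assert_allclose(out.values[sl], expected[sl], atol=1e-6)

    def test_mask_threshold_and_origin(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:6, 2:6, 1:3] = True
        img = VolumetricImage(np.ones((8, 8, 4)), (1, 1, 2), origin_mm=(5, 6, 7))
        m = RoiMask(mask, (1, 1, 2), (5, 6, 7))
        out_img, out_mask = resample_isotropic(img, m, 1.0)
        assert out_img.origin_mm == (5, 6, 7)
        assert out_mask.n_voxels > 0
        assert out_img.spacing_mm == (1.0, 1.0, 1.0)


class TestResegmentation:
    def test_boundary_inclusion(self):
        vals = np.zeros((5, 1, 1))
        vals[:, 0, 0] = [-200, -150, 0, 180, 181]
        img = VolumetricImage(vals, (1, 1, 1), modality="CT")
        mask = RoiMask(np.ones((5, 1, 1), bool), (1, 1, 1))
        out = resegment_hu(img, mask)
        np.testing.assert_array_equal(out.values[:, 0, 0],
                                      [False, True, True, True, False])

    def test_phantom_fraction_removed(self):
        cfg = PhantomConfig(ct_air_fraction=0.1, ct_bone_fraction=0.05)
        _, ct, mask = generate_phantom(cfg, seed=4)
        out = resegment_hu(ct, mask)
        n = mask.n_voxels
        expected = n - round(0.1 * n) - round(0.05 * n)
        assert abs(out.n_voxels - expected) <= 1

    def test_all_soft_tissue_unchanged(self):
        cfg = PhantomConfig(ct_air_fraction=0.0, ct_bone_fraction=0.0)
        _, ct, mask = generate_phantom(cfg, seed=5)
        out = resegment_hu(ct, mask)
        np.testing.assert_array_equal(out.values, mask.values)

    def test_empty_result_raises(self):
        img = VolumetricImage(np.full((4, 4, 4), -1000.0), (1, 1, 1),
                              modality="CT")
        mask = RoiMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="soft tissue"):
            resegment_hu(img, mask)


class TestLogFilterBank:
    def test_constant_image_zero_response(self):
        img = VolumetricImage(np.full((16, 16, 16), 5.0), (1, 1, 1))
        out = log_filter_bank(img)
        assert np.abs(out.values).max() < 1e-9

    def test_linearity(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(12, 12, 12))
        img = VolumetricImage(vals, (1, 1, 1))
        scaled = VolumetricImage(3.0 * vals, (1, 1, 1))
        np.testing.assert_allclose(log_filter_bank(scaled).values,
                                   3.0 * log_filter_bank(img).values,
                                   atol=1e-9)

    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_gaussian_blob_closed_form(self, sigma):
        # LoG_sigma * exp(-r^2/(2 s^2)) at the centre = -3 s^3/(s^2+sigma^2)^{5/2}
        s = 3.0
        n = 41
        idx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        r2 = sum(g.astype(float) ** 2 for g in idx)
        blob = np.exp(-r2 / (2 * s ** 2))
        img = VolumetricImage(blob, (1, 1, 1))
        resp = log_single(img, sigma)
        expected = -3 * s ** 3 / (s ** 2 + sigma ** 2) ** 2.5
        assert resp[n // 2, n // 2, n // 2] == pytest.approx(expected, rel=0.02)

    def test_average_equals_mean_of_single_maps(self):
        rng = np.random.default_rng(2)
        img = VolumetricImage(rng.uniform(size=(10, 10, 10)), (1, 1, 1))
        sigmas = (1.0, 2.0, 3.0)
        bank = log_filter_bank(img, sigmas)
        singles = np.mean([log_single(img, s) for s in sigmas], axis=0)
        np.testing.assert_allclose(bank.values, singles, atol=1e-12)
        assert bank.meta["log_sigmas_mm"] == sigmas
        assert bank.modality == "LOG"
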