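import numpy as np
import pandas as pd
import pytest

import oracles
from radsig.grids import RoiMask, VolumetricImage
from radsig.robustness import (PerturbationSetting, adapt_volume,
                               enumerate_perturbations, estimate_noise_sd,
                               icc_1_1, icc_filter, perturb_and_extract,
                               stable_features)


class TestEnumeration:
    def test_default_grid_gives_81(self):
        settings = enumerate_perturbations()
        assert len(settings) == 81
        assert len({s.setting_id for s in settings}) == 81

    def test_degenerate_grids_single_setting(self):
        settings = enumerate_perturbations((0.0,), (0.0,))
        assert len(settings) == 1

    def test_deterministic_across_runs(self):
        a = enumerate_perturbations(base_seed=5)
        b = enumerate_perturbations(base_seed=5)
        assert a == b
        assert all(s.noise_seed < 2**31 for s in a)


class TestNoiseEstimate:
    def test_pure_noise_recovered(self):
        rng = np.random.default_rng(0)
        img = VolumetricImage(rng.normal(0, 5.0, (64, 64, 64)), (1, 1, 1))
        est = estimate_noise_sd(img)
        assert est == pytest.approx(5.0, rel=0.10)

    def test_constant_image_epsilon(self):
        img = VolumetricImage(np.full((16, 16, 16), 3.0), (1, 1, 1))
        assert estimate_noise_sd(img) == pytest.approx(1e-9)

    def test_ct_air_boundary_does_not_inflate_estimate(self):
        # a -1000 HU air background with a soft-tissue body inside: the
        # sharp interface must not leak into the noise estimate
        rng = np.random.default_rng(5)
        vals = np.full((40, 40, 40), -1000.0)
        idx = np.indices(vals.shape)
        ball = ((idx - 20) ** 2).sum(axis=0) <= 15 ** 2
        vals[ball] = 40.0
        vals += rng.normal(0, 2.0, vals.shape)
        img = VolumetricImage(vals, (1, 1, 1), modality="CT")
        assert estimate_noise_sd(img) == pytest.approx(2.0, rel=0.15)

    def test_ramp_plus_noise_structure_suppressed(self):
        rng = np.random.default_rng(1)
        ramp = np.indices((48, 48, 48)).sum(axis=0).astype(float)
        img = VolumetricImage(ramp + rng.normal(0, 2.0, ramp.shape), (1, 1, 1))
        assert estimate_noise_sd(img) == pytest.approx(2.0, rel=0.15)


def _ball_mask(radius, spacing=(1.0, 1.0, 1.0)):
    n = [int(2 * radius / s) + 5 for s in spacing]
    idx = np.meshgrid(*[np.arange(m) * s for m, s in zip(n, spacing)],
                      indexing="ij")
    c = [(m - 1) * s / 2 for m, s in zip(n, spacing)]
    d2 = sum((g - ci) ** 2 for g, ci in zip(idx, c))
    return RoiMask(d2 <= radius ** 2, spacing)


class TestAdaptVolume:
    def test_zero_fraction_identity(self):
        mask = _ball_mask(6.0)
        assert adapt_volume(mask, 0.0) is mask

    def test_shrink_ball_by_15_percent(self):
        mask = _ball_mask(13.4)  # ~10,000 voxels
        n0 = mask.n_voxels
        assert n0 == pytest.approx(10000, rel=0.02)
        out = adapt_volume(mask, -0.15)
        assert out.n_voxels == pytest.approx(0.85 * n0, rel=0.02)

    def test_grow_then_shrink_near_inverse(self):
        mask = _ball_mask(10.0)
        grown = adapt_volume(mask, 0.15)
        back = adapt_volume(grown, -0.15 / 1.15)
        inter = (back.values & mask.values).sum()
        dice = 2 * inter / (back.n_voxels + mask.n_voxels)
        assert dice >= 0.98

    def test_shrink_to_empty_raises(self):
        mask = _ball_mask(2.0)
        with pytest.raises(ValueError):
            adapt_volume(mask, -0.999)


class TestPerturbExtract:
    def test_identity_setting_bit_equal(self, preprocessed_subject):
        from radsig.features import extract_all
        setting = PerturbationSetting("id", 1, 0.0, (0.0, 0.0, 0.0))
        table = perturb_and_extract(preprocessed_subject, [setting],
                                    noise_sd_override=0.0)
        baseline = extract_all(preprocessed_subject)
        row = table.iloc[0]
        for name, val in baseline.items():
            assert row[name] == val

    def test_volume_fraction_moves_morph_volume(self, preprocessed_subject):
        settings = [PerturbationSetting("a", 1, 0.0, (0.0, 0.0, 0.0)),
                    PerturbationSetting("b", 2, 0.15, (0.0, 0.0, 0.0)),
                    PerturbationSetting("c", 3, -0.15, (0.0, 0.0, 0.0))]
        table = perturb_and_extract(preprocessed_subject, settings,
                                    noise_sd_override=0.0)
        av = table["MR_morph_av"]
        assert av["b"] == pytest.approx(1.15 * av["a"], rel=0.03)
        assert av["c"] == pytest.approx(0.85 * av["a"], rel=0.03)

    def test_reproducible_with_same_seeds(self, preprocessed_subject):
        settings = enumerate_perturbations(base_seed=3)[:3]
        t1 = perturb_and_extract(preprocessed_subject, settings)
        t2 = perturb_and_extract(preprocessed_subject, settings)
        pd.testing.assert_frame_equal(t1, t2)


class TestIcc:
    def test_toy_table_matches_anova_oracle(self):
        data = np.array([[9.0, 10.0, 11.0],
                         [5.0, 6.0, 4.0],
                         [1.0, 2.0, 3.0]])
        icc, lo, hi = icc_1_1(data)
        assert icc == pytest.approx(oracles.icc_oneway(data))
        assert lo <= icc <= hi
        assert icc <= 1

    def test_within_subject_invariance_gives_one(self):
        data = np.repeat([[1.0], [5.0], [9.0], [13.0]], 4, axis=1)
        icc, lo, hi = icc_1_1(data)
        assert icc == pytest.approx(1.0)

    def test_pure_noise_low_icc_removed(self):
        rng = np.random.default_rng(2)
        tables = {f"s{i}": pd.DataFrame({"f": rng.normal(size=20)})
                  for i in range(10)}
        results = icc_filter(tables)
        assert results[0].icc < 0.3
        assert not results[0].kept

    def test_affine_invariance_of_icc(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 8)) + 5 * rng.normal(size=(6, 1))
        i1, *_ = icc_1_1(base)
        i2, *_ = icc_1_1(3.7 * base - 11.0)
        assert i1 == pytest.approx(i2, abs=1e-10)

    def test_added_noise_never_raises_icc(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(8, 10)) * 0.3 + 4 * rng.normal(size=(8, 1))
        wins = 0
        trials = 40
        for t in range(trials):
            noisy = base + rng.normal(size=base.shape) * 0.5
            if icc_1_1(noisy)[0] <= icc_1_1(base)[0]:
                wins += 1
        assert wins / trials >= 0.95

    def test_zero_variance_flagged(self):
        tables = {f"s{i}": pd.DataFrame({"f": np.ones(5)}) for i in range(4)}
        results = icc_filter(tables)
        assert results[0].flag == "zero_variance"
        assert not results[0].kept

    def test_kept_set_reproducible(self):
        rng = np.random.default_rng(5)
        subj = {f"s{i}": pd.DataFrame(
            {"stable": np.full(6, i * 2.0) + rng.normal(scale=0.01, size=6),
             "unstable": rng.normal(size=6)}) for i in range(8)}
        r1 = stable_features(icc_filter(subj))
        r2 = stable_features(icc_filter(subj))
        assert r1 == r2 == ["stable"]
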