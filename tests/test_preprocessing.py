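"""Global normalization, resizing, and paired augmentation."""

import numpy as np
import pytest

from wbcseg import (
    AugmentConfig,
    NormalizationStats,
    RenderedSample,
    augment,
    compute_global_stats,
    normalize,
    resize_to_model,
)


class TestGlobalStats:
    def test_constant_input(self):
        stats = compute_global_stats([np.full((4, 4, 3), 7.0)])
        assert stats.global_mean == 7.0
        assert stats.global_std == 0.0

    def test_pooled_population_std(self):
        # pooled pixel multiset {0, 2}: mean 1, population SD 1
        stats = compute_global_stats([np.array([[0.0]]), np.array([[2.0]])])
        assert stats.global_mean == pytest.approx(1.0)
        assert stats.global_std == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        imgs = [rng.uniform(0, 255, size=(5, 5, 3)) for _ in range(4)]
        a = compute_global_stats(imgs)
        b = compute_global_stats(imgs[::-1])
        assert a.global_mean == pytest.approx(b.global_mean)
        assert a.global_std == pytest.approx(b.global_std)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            compute_global_stats([])


class TestNormalize:
    def test_centering_constant_image(self):
        stats = NormalizationStats(10.0, 2.0)
        out = normalize(np.full((3, 3), 10.0), stats)
        np.testing.assert_allclose(out, 0.0)

    def test_zero_std_guarded_by_epsilon(self):
        stats = compute_global_stats([np.full((3, 3), 5.0)])
        out = normalize(np.full((3, 3), 5.0), stats)
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, 0.0)

    def test_direct_arithmetic(self):
        stats = NormalizationStats(1.0, 1.0, epsilon=1e-10)
        out = normalize(np.array([0.0, 2.0]), stats)
        np.testing.assert_allclose(out, [-1.0, 1.0], atol=1e-9)

    def test_pooled_standardization_contract(self):
        rng = np.random.default_rng(1)
        imgs = [rng.uniform(0, 255, size=(8, 8, 3)) for _ in range(5)]
        stats = compute_global_stats(imgs)
        pooled = np.concatenate([normalize(i, stats).ravel() for i in imgs])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-6)
        assert pooled.std() == pytest.approx(1.0, abs=1e-6)


class TestResize:
    def test_identity_for_masks(self):
        mask = (np.random.default_rng(0).random((32, 32)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(resize_to_model(mask, 32, is_mask=True), mask)

    def test_mask_stays_binary(self):
        mask = (np.random.default_rng(1).random((50, 50)) > 0.7).astype(np.uint8)
        out = resize_to_model(mask, 224, is_mask=True)
        assert set(np.unique(out)) <= {0, 1}

    def test_disc_foreground_fraction_preserved(self):
        rr, cc = np.mgrid[0:100, 0:100]
        mask = (((rr - 50) ** 2 + (cc - 50) ** 2) <= 25**2).astype(np.uint8)
        out = resize_to_model(mask, 224, is_mask=True)
        assert abs(out.mean() - mask.mean()) / mask.mean() < 0.03

    def test_small_side_rejected(self):
        with pytest.raises(ValueError):
            resize_to_model(np.zeros((16, 16)), 4)


def _disc_sample(side=64, radius=12):
    rr, cc = np.mgrid[0:side, 0:side]
    mask = (((rr - side // 2) ** 2 + (cc - side // 2) ** 2) <= radius**2).astype(
        np.uint8
    )
    img = np.full((side, side, 3), 220, dtype=np.uint8)
    img[mask == 1] = (80, 60, 120)
    return RenderedSample(image=img, mask=mask, sample_id="disc", seed=0)


class TestAugment:
    def test_identity_transform(self):
        sample = _disc_sample()
        cfg = AugmentConfig(rotation_range=(0, 0), zoom_range=(1, 1), scale_range=(1, 1))
        out = augment(sample, cfg, seed=0)
        np.testing.assert_array_equal(out.mask, sample.mask)
        np.testing.assert_array_equal(out.image, sample.image)

    def test_deterministic_given_seed(self):
        sample = _disc_sample()
        cfg = AugmentConfig()
        a = augment(sample, cfg, seed=9)
        b = augment(sample, cfg, seed=9)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_image_and_mask_share_the_geometric_map(self):
        # paint the mask's own dot into the image and check both move together
        sample = _disc_sample(radius=8)
        marked = sample.image.copy()
        marked[..., 0] = sample.mask * 255
        sample = RenderedSample(marked, sample.mask, "marker", 0)
        out = augment(sample, AugmentConfig(), seed=4)
        recovered = (out.image[..., 0] > 127).astype(np.uint8)
        inter = np.sum(recovered & out.mask)
        union = np.sum(recovered | out.mask)
        assert inter / union > 0.9

    def test_pure_rotation_preserves_area(self):
        sample = _disc_sample(radius=10)
        cfg = AugmentConfig(
            rotation_range=(30, 30), zoom_range=(1, 1), scale_range=(1, 1)
        )
        out = augment(sample, cfg, seed=2)
        before, after = sample.mask.sum(), out.mask.sum()
        assert abs(after - before) / before < 0.05

    def test_disabled_flag_returns_input(self):
        sample = _disc_sample()
        out = augment(sample, AugmentConfig(enabled=False), seed=1)
        assert out is sample

    def test_masks_binary_after_augment(self):
        sample = _disc_sample()
        out = augment(sample, AugmentConfig(), seed=3)
        assert set(np.unique(out.mask)) <= {0, 1}
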