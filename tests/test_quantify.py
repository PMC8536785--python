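"""Volume/thick fractions, periphery restriction, fibrosis score, and the
trainable pixel classifier."""

import numpy as np
import pytest

from fibroquant import (
    AcquisitionGeometry,
    BinaryMask,
    PixelTrainingSet,
    ThicknessMap,
    UndefinedScoreError,
    VolumeImage,
    area_fraction,
    channel_volume,
    classify_pixels,
    estimate_support,
    fibrosis_score,
    make_organoid_support,
    restrict_to_periphery,
    thick_fraction,
    train_pixel_classifier,
    volume_fraction,
)
from fibroquant.local_thickness import local_thickness_map
from oracles import brute_edt_squared, random_blob_mask


def mask_of(arr, geom):
    return BinaryMask(np.asarray(arr, bool), geom)


class TestFractions:
    def test_half_full_mask(self, geom_factory):
        g = geom_factory((4, 4, 4))
        m = np.zeros(g.shape, bool)
        m[:2] = True
        res = volume_fraction(mask_of(m, g))
        assert res.volume_fraction_pct == 50.0
        assert res.n_voxels_collagen == 32

    def test_empty_mask(self, geom_factory):
        g = geom_factory((4, 4, 4))
        assert volume_fraction(mask_of(np.zeros(g.shape, bool), g)).volume_fraction_pct == 0.0

    def test_thick_fraction_zero_when_all_thin(self, geom_factory):
        g = geom_factory((4, 8, 8))
        tau = np.zeros(g.shape)
        tau[2, 4, :] = 2.0  # a thin fiber, τ = 2 μm < 6 μm
        res = thick_fraction(ThicknessMap(tau, g), 6.0)
        assert res.thick_fraction_pct == 0.0
        assert res.n_voxels_collagen == 8

    def test_threshold_zero_recovers_volume_fraction(self, rng, geom_factory):
        g = geom_factory((6, 10, 10))
        m = random_blob_mask(rng, g.shape, p_fg=0.3)
        tau = local_thickness_map(mask_of(m, g))
        res = thick_fraction(tau, 0.0)
        assert res.thick_fraction_pct == volume_fraction(mask_of(m, g)).volume_fraction_pct

    def test_denominator_is_total_stack_voxels(self, geom_factory):
        g = geom_factory((2, 5, 5))
        tau = np.zeros(g.shape)
        tau[0, 0, :5] = 7.0
        res = thick_fraction(ThicknessMap(tau, g), 6.0)
        assert res.thick_fraction_pct == 100.0 * 5 / 50


class TestPeriphery:
    def test_small_ball_entirely_peripheral(self):
        g = AcquisitionGeometry(2.0, 2.0, (44, 44, 44))
        support = make_organoid_support(g, radius_um=40.0)
        m = mask_of(np.ones(g.shape, bool), g)
        out = restrict_to_periphery(m, support, depth_um=50.0)
        assert np.array_equal(out.voxels, support.voxels)

    def test_zero_depth_empty(self):
        g = AcquisitionGeometry(2.0, 2.0, (20, 20, 20))
        support = make_organoid_support(g, radius_um=15.0)
        out = restrict_to_periphery(mask_of(np.ones(g.shape, bool), g), support, depth_um=0.0)
        assert not out.voxels.any()

    def test_large_ball_shell_matches_bruteforce_distance(self):
        """Ball of radius 100 μm, depth 50 μm: retained voxels are exactly
        those with nearest-exterior distance < 50 μm (brute-force check)."""
        g = AcquisitionGeometry(10.0, 10.0, (24, 24, 24))
        support = make_organoid_support(g, radius_um=100.0)
        m = mask_of(np.ones(g.shape, bool), g)
        out = restrict_to_periphery(m, support, depth_um=50.0)
        ref_d = np.sqrt(brute_edt_squared(support.voxels, g.spacing))
        expected = support.voxels & (ref_d < 50.0)
        assert np.array_equal(out.voxels, expected)
        assert expected.sum() < support.n_foreground  # a core was removed

    def test_empty_support_rejected(self, geom_factory):
        g = geom_factory((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            restrict_to_periphery(
                mask_of(np.ones(g.shape, bool), g), mask_of(np.zeros(g.shape, bool), g)
            )

    def test_estimate_support_recovers_bright_body(self):
        g = AcquisitionGeometry(1.0, 1.0, (16, 32, 32))
        body = make_organoid_support(g, radius_um=10.0).voxels
        img = VolumeImage(np.where(body, 100.0, 2.0), g)
        est = estimate_support(img)
        inter = (est.voxels & body).sum()
        union = (est.voxels | body).sum()
        assert inter / union > 0.8


class TestScore:
    def test_channel_volume_example(self):
        g = AcquisitionGeometry(1.0, 2.0, (1, 5, 5))
        m = np.zeros(g.shape, bool)
        m[0].flat[:10] = True
        assert channel_volume(mask_of(m, g)) == pytest.approx(20.0)

    def test_channel_volume_identity(self, rng, geom_factory):
        g = AcquisitionGeometry(0.7, 1.3, (5, 9, 9))
        m = rng.random(g.shape) < 0.4
        assert channel_volume(mask_of(m, g)) == pytest.approx(
            m.sum() * g.voxel_volume_um3, rel=1e-12
        )

    def test_identical_masks_score_one(self, rng, geom_factory):
        g = geom_factory((4, 8, 8))
        m = mask_of(random_blob_mask(rng, g.shape, p_fg=0.3), g)
        assert fibrosis_score(m, m).score == 1.0

    def test_quarter_ratio_on_counted_masks(self, geom_factory):
        g = geom_factory((10, 40, 40))
        col = np.zeros(g.shape, bool)
        ck8 = np.zeros(g.shape, bool)
        col.flat[:1000] = True
        ck8.flat[:4000] = True
        assert fibrosis_score(mask_of(col, g), mask_of(ck8, g)).score == 0.25

    def test_empty_collagen_scores_zero(self, geom_factory):
        g = geom_factory((2, 6, 6))
        ck8 = np.ones(g.shape, bool)
        assert fibrosis_score(mask_of(np.zeros(g.shape, bool), g), mask_of(ck8, g)).score == 0.0

    def test_empty_ck8_is_undefined(self, geom_factory):
        g = geom_factory((2, 6, 6))
        with pytest.raises(UndefinedScoreError):
            fibrosis_score(mask_of(np.ones(g.shape, bool), g), mask_of(np.zeros(g.shape, bool), g))

    def test_scale_invariance_under_upsampling(self, rng):
        g = AcquisitionGeometry(1.0, 1.0, (3, 6, 6))
        col = random_blob_mask(rng, g.shape, p_fg=0.3)
        ck8 = random_blob_mask(rng, g.shape, p_fg=0.5) | col
        s1 = fibrosis_score(mask_of(col, g), mask_of(ck8, g)).score
        g2 = AcquisitionGeometry(0.5, 0.5, (6, 12, 12))
        up = lambda m: np.repeat(np.repeat(np.repeat(m, 2, 0), 2, 1), 2, 2)  # noqa: E731
        s2 = fibrosis_score(mask_of(up(col), g2), mask_of(up(ck8), g2)).score
        assert abs(s1 - s2) < 1e-9


@pytest.fixture(scope="module")
def separable_fixture():
    """Two-class image with disjoint intensity ranges (≈20 vs ≈230) split
    left/right, plus sparse scribbles in each half."""
    rng = np.random.default_rng(7)
    img = np.empty((60, 60))
    img[:, :30] = rng.uniform(0, 50, (60, 30))
    img[:, 30:] = rng.uniform(200, 255, (60, 30))
    scribbles = np.zeros((60, 60), dtype=np.int64)
    for y in (8, 25, 48):
        scribbles[y : y + 3, 5:10] = 1
        scribbles[y : y + 3, 45:50] = 2
    truth = np.broadcast_to(np.where(np.arange(60) < 30, 1, 2), (60, 60))
    return img, scribbles, truth


class TestPixelClassifier:
    def test_separable_classes_high_heldout_accuracy(self, separable_fixture):
        img, scribbles, truth = separable_fixture
        clf = train_pixel_classifier(PixelTrainingSet(img, scribbles), seed=0)
        prob = classify_pixels(clf, img)
        pred = np.asarray(clf.classes)[np.argmax(prob.values, axis=2)]
        heldout = (scribbles == 0) & (np.abs(np.arange(60)[None, :] - 30) >= 10)
        acc = (pred[heldout] == truth[heldout]).mean()
        assert acc >= 0.99

    def test_training_scribbles_reproduced(self, separable_fixture):
        img, scribbles, _ = separable_fixture
        clf = train_pixel_classifier(PixelTrainingSet(img, scribbles), seed=0)
        prob = classify_pixels(clf, img)
        pred = np.asarray(clf.classes)[np.argmax(prob.values, axis=2)]
        labeled = scribbles > 0
        assert (pred[labeled] == scribbles[labeled]).all()

    def test_deterministic_given_seed(self, separable_fixture):
        img, scribbles, _ = separable_fixture
        p1 = classify_pixels(
            train_pixel_classifier(PixelTrainingSet(img, scribbles), seed=5), img
        )
        p2 = classify_pixels(
            train_pixel_classifier(PixelTrainingSet(img, scribbles), seed=5), img
        )
        assert np.array_equal(p1.values, p2.values)

    def test_probabilities_normalized(self, separable_fixture):
        img, scribbles, _ = separable_fixture
        prob = classify_pixels(
            train_pixel_classifier(PixelTrainingSet(img, scribbles)), img
        )
        np.testing.assert_allclose(prob.values.sum(axis=2), 1.0, atol=1e-6)
        assert prob.values.min() >= 0.0 and prob.values.max() <= 1.0

    def test_constant_image_uniform_map(self):
        rng = np.random.default_rng(1)
        img = np.where(np.arange(40)[None, :] < 20, 10.0, 200.0) * np.ones((20, 1))
        scribbles = np.zeros((20, 40), np.int64)
        scribbles[5:8, 2:6] = 1
        scribbles[5:8, 30:34] = 2
        clf = train_pixel_classifier(PixelTrainingSet(img, scribbles), seed=0)
        flat = np.full((10, 10), 10.0) + rng.normal(0, 1e-9, (10, 10))
        prob = classify_pixels(clf, flat)
        assert np.allclose(prob.values, prob.values[0, 0], atol=1e-9)

    def test_channel_mismatch_rejected(self, separable_fixture):
        img, scribbles, _ = separable_fixture
        clf = train_pixel_classifier(PixelTrainingSet(img, scribbles))
        with pytest.raises(ValueError, match="channels"):
            classify_pixels(clf, np.zeros((10, 10, 3)))

    def test_single_class_rejected(self):
        scribbles = np.zeros((10, 10), np.int64)
        scribbles[2:4, 2:4] = 1
        with pytest.raises(ValueError):
            PixelTrainingSet(np.zeros((10, 10)), scribbles)


class TestAreaFraction:
    def make_prob(self, p_class1):
        p = np.stack([p_class1, 1 - p_class1], axis=-1)
        from fibroquant import ProbabilityMap

        return ProbabilityMap(values=p, classes=(1, 2))

    def test_all_positive(self):
        res = area_fraction(self.make_prob(np.ones((5, 5))), 1)
        assert res.area_fraction_pct == 100.0

    def test_all_negative(self):
        res = area_fraction(self.make_prob(np.zeros((5, 5))), 1)
        assert res.area_fraction_pct == 0.0

    def test_checkerboard_half(self):
        yy, xx = np.indices((8, 8))
        p = np.where((yy + xx) % 2 == 0, 0.9, 0.1)
        res = area_fraction(self.make_prob(p), 1)
        assert res.area_fraction_pct == 50.0

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            area_fraction(self.make_prob(np.ones((3, 3))), 99)
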