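"""Augmentation protocol and training loop contracts."""

import numpy as np
import pytest

from fissnet.architecture import ArchitectureSpec
from fissnet.grids import GridError
from fissnet.phantom import PhantomParams, generate_phantom
from fissnet.training import (TrainingConfig, augment_image, random_rigid_params,
                              soft_dice_loss, split_samples, train_model)

TINY_ARCH = ArchitectureSpec(encoder_filters=(2, 2, 4, 8, 16),
                             decoder_filters=(16, 8, 4, 2, 2))
TINY_PHANTOM = PhantomParams(grid_shape=(16, 16, 16), ellipsoid_semi_axes=(6, 5, 4),
                             n_fissures=1, fissure_width=1.5, noise_sigma=4.0,
                             bias_field_amplitude=0.05)


def tiny_samples(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in rng.integers(0, 2 ** 31 - 1, size=n):
        ph = generate_phantom(PhantomParams(**{**TINY_PHANTOM.__dict__, "seed": int(s)}))
        out.append((ph.volume, ph.truth))
    return out


class TestRigidDraws:
    def test_thousand_draws_within_ranges(self):
        cfg = TrainingConfig()
        rng = np.random.default_rng(0)
        for _ in range(1000):
            angles, shifts, axes = random_rigid_params(cfg, rng)
            assert all(-10.0 <= a <= 10.0 for a in angles)
            assert all(-10 <= s <= 10 for s in shifts)
            assert all(shifts[i] == 0 for i in range(3) if i not in axes)

    def test_fixed_seed_reproduces_sequence(self):
        cfg = TrainingConfig()
        seq = lambda: [random_rigid_params(cfg, np.random.default_rng(7))
                       for _ in range(50)]
        assert seq() == seq()

    def test_zero_ranges_give_identity_transform(self):
        cfg = TrainingConfig(rotation_range=0.0, shift_range=0)
        angles, shifts, _ = random_rigid_params(cfg, np.random.default_rng(0))
        assert all(a == 0.0 for a in angles) and all(s == 0 for s in shifts)


@pytest.fixture(scope="module")
def sample():
    ph = generate_phantom(PhantomParams(grid_shape=(24, 24, 24),
                                        ellipsoid_semi_axes=(9, 8, 7),
                                        n_fissures=2, seed=5))
    return ph.volume, ph.truth


class TestAugmentImage:
    def test_default_protocol_emits_forty_pairs(self, sample):
        vol, labels = sample
        pairs = augment_image(vol, labels, TrainingConfig(), seed=1)
        assert len(pairs) == 40

    def test_triplet_invariants_preserved(self, sample):
        vol, labels = sample
        cfg = TrainingConfig(augment_per_image=6)
        for v, trip in augment_image(vol, labels, cfg, seed=2):
            f, t, w = trip.fissures.bool, trip.tissue.bool, trip.whole.bool
            assert not np.any(f & t)
            assert np.array_equal(f | t, w)
            assert v.shape == vol.shape

    def test_zero_range_transform_is_identity(self, sample):
        vol, labels = sample
        cfg = TrainingConfig(augment_per_image=3, rotation_range=0.0, shift_range=0)
        for v, trip in augment_image(vol, labels, cfg, seed=3):
            np.testing.assert_allclose(v.data, vol.data, atol=1e-5)
            assert np.array_equal(trip.whole.data, labels.whole.data)

    def test_labels_stay_binary(self, sample):
        vol, labels = sample
        cfg = TrainingConfig(augment_per_image=4)
        for _, trip in augment_image(vol, labels, cfg, seed=4):
            for m in (trip.fissures, trip.tissue, trip.whole):
                assert set(np.unique(m.data)) <= {0, 1}


class TestSoftDiceLoss:
    def test_perfect_binary_prediction_is_zero(self, rng):
        g = (rng.random((4, 4, 4)) > 0.5).astype(float)
        assert soft_dice_loss(g, g) == pytest.approx(0.0)

    def test_complement_prediction_is_one(self, rng):
        g = (rng.random((4, 4, 4)) > 0.5).astype(float)
        assert soft_dice_loss(1.0 - g, g) == pytest.approx(1.0)

    def test_uniform_half_vs_half_full_truth_hand_value(self):
        # 2³ grid, truth has 4 foreground voxels, prediction uniform 0.5:
        # num = 2·(4·0.5) = 4 ; den = 8·0.25 + 4 = 6 ; loss = 1 − 4/6 = 1/3
        p = np.full((2, 2, 2), 0.5)
        g = np.zeros((2, 2, 2))
        g.ravel()[:4] = 1.0
        assert soft_dice_loss(p, g) == pytest.approx(1.0 / 3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GridError):
            soft_dice_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestTrainModel:
    def test_single_epoch_history_length(self):
        samples = tiny_samples(3, seed=1)
        cfg = TrainingConfig(target="whole", epochs=1, augment_per_image=0, seed=0)
        res = train_model(TINY_ARCH, samples[:2], samples[2:], cfg)
        assert len(res.history) == 1
        assert all(np.isfinite(res.history.train_loss))

    def test_same_seed_same_final_loss(self):
        samples = tiny_samples(3, seed=2)
        cfg = TrainingConfig(target="whole", epochs=2, augment_per_image=0, seed=9)
        run = lambda: train_model(TINY_ARCH, samples[:2], samples[2:], cfg)
        a, b = run(), run()
        assert a.history.train_loss == b.history.train_loss
        assert a.history.val_dsc == b.history.val_dsc

    def test_loss_trend_decreases(self):
        samples = tiny_samples(5, seed=3)
        cfg = TrainingConfig(target="whole", epochs=10, augment_per_image=0, seed=0)
        res = train_model(TINY_ARCH, samples[:4], samples[4:], cfg)
        first = np.median(res.history.train_loss[:3])
        last = np.median(res.history.train_loss[-3:])
        assert last < first

    def test_empty_partition_rejected(self):
        samples = tiny_samples(2, seed=4)
        cfg = TrainingConfig(target="whole", epochs=1)
        with pytest.raises(ValueError):
            train_model(TINY_ARCH, samples, [], cfg)

    def test_target_selects_label_channel(self):
        samples = tiny_samples(3, seed=5)
        cfg = TrainingConfig(target="fissures", epochs=1, augment_per_image=0, seed=0)
        res = train_model(TINY_ARCH, samples[:2], samples[2:], cfg)
        assert res.config.target == "fissures"
        assert len(res.history) == 1


def test_split_samples_partitions_everything():
    samples = list(range(24))
    train, val, test = split_samples(samples, seed=0)
    assert len(train) == 17 and len(val) == 2 and len(test) == 5
    assert sorted(train + val + test) == samples


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainingConfig(target="lobules")
    with pytest.raises(ValueError):
        TrainingConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainingConfig(augment_per_image=-1)
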