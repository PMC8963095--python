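"""Label construction: Otsu thresholding, snakes, and mask algebra."""

import numpy as np
import pytest

from fissnet.grids import DegenerateInputError, GridError
from fissnet.maskgen import (MaskGenConfig, binarize, build_label_triplet,
                             derive_fissure_mask, derive_tissue_mask,
                             otsu_threshold, smooth_mask)
from fissnet.metrics import dice
from fissnet.phantom import ellipsoid_mask
from fissnet.preprocess import enhance_contrast

from conftest import mask_from, volume_from


def brute_force_otsu_split(values):
    """Independent oracle: exhaustive search over all candidate thresholds,
    maximizing between-class variance of the induced voxel partition."""
    vals = np.asarray(values, dtype=float).ravel()
    best_sb, best_t = -1.0, None
    for t in np.unique(vals)[:-1]:
        c0, c1 = vals[vals <= t], vals[vals > t]
        w0 = c0.size / vals.size
        sb = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if sb > best_sb + 1e-12:
            best_sb, best_t = sb, t
    return best_t


class TestOtsu:
    def test_bimodal_threshold_separates_classes(self):
        data = np.resize(np.array([10.0] * 500 + [200.0] * 500), (10, 10, 10))
        t = otsu_threshold(volume_from(data))
        assert 10.0 < t < 200.0
        mask = binarize(volume_from(data), t)
        assert np.array_equal(mask.bool, data > 100)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_partition_search(self, seed):
        """On ≤ 64-level volumes the 256-bin histogram threshold induces the
        same partition as the exhaustive brute-force maximizer."""
        rng = np.random.default_rng(seed)
        # mixture of two discrete intensity clusters, 64 integer levels
        vals = np.where(rng.random(20 ** 3) < 0.6,
                        rng.integers(0, 25, 20 ** 3),
                        rng.integers(38, 64, 20 ** 3)).astype(float)
        vol = volume_from(vals.reshape(20, 20, 20))
        mine = otsu_threshold(vol)
        oracle_t = brute_force_otsu_split(vals)
        assert np.array_equal(vol.data > mine, vol.data > oracle_t)

    def test_symmetric_swap_same_separation(self):
        a = np.resize(np.array([10.0] * 400 + [200.0] * 600), (10, 10, 10))
        b = 210.0 - a  # swap the two class intensities symmetrically
        bright_a = binarize(volume_from(a), otsu_threshold(volume_from(a)))
        bright_b = binarize(volume_from(b), otsu_threshold(volume_from(b)))
        # the bright class of b is exactly the dark class of a
        assert np.array_equal(bright_b.bool, ~bright_a.bool)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(volume_from(np.full((4, 4, 4), 7.0)))


class TestBinarize:
    def test_threshold_below_min_gives_all_ones(self, rng):
        vol = volume_from(rng.uniform(10, 20, (6, 6, 6)))
        assert binarize(vol, 5.0).count() == 216

    def test_strict_inequality_at_max(self, rng):
        vol = volume_from(rng.uniform(10, 20, (6, 6, 6)))
        assert binarize(vol, vol.data.max()).count() == 0

    def test_two_level_volume_recovers_bright_class(self):
        data = np.resize(np.array([10.0, 200.0]), (10, 10, 10))
        mask = binarize(volume_from(data), 100.0)
        assert np.array_equal(mask.bool, data == 200.0)


class TestSmoothMask:
    def test_ball_nearly_unchanged(self):
        ball = ellipsoid_mask((32, 32, 32), (10, 10, 10))
        out = smooth_mask(mask_from(ball), iterations=5)
        assert dice(out, mask_from(ball)) >= 0.95

    def test_boundary_spikes_removed(self):
        ball = ellipsoid_mask((32, 32, 32), (9, 9, 9)).astype(np.uint8)
        spiky = ball.copy()
        # one-voxel spikes sticking out along an axis
        spiky[26, 16, 16] = spiky[16, 26, 16] = spiky[16, 16, 26] = 1

        def boundary_voxels(m):
            from scipy.ndimage import binary_erosion
            return int(m.sum() - binary_erosion(m).sum())

        out = smooth_mask(mask_from(spiky), iterations=3)
        assert boundary_voxels(out.data) < boundary_voxels(spiky)
        ratio_in = boundary_voxels(spiky) / spiky.sum()
        ratio_out = boundary_voxels(out.data) / max(out.count(), 1)
        assert ratio_out < ratio_in

    def test_zero_iterations_is_identity(self):
        ball = mask_from(ellipsoid_mask((24, 24, 24), (8, 8, 8)))
        out = smooth_mask(ball, iterations=0)
        assert np.array_equal(out.data, ball.data)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            smooth_mask(mask_from(np.zeros((8, 8, 8))), iterations=2)


class TestMaskAlgebra:
    def _block(self):
        whole = np.zeros((5, 5, 5), dtype=np.uint8)
        whole[1:4, 1:4, 1:4] = 1  # 3³ block = 27 voxels
        return whole

    def test_binary_superset_gives_empty_fissures(self):
        whole = self._block()
        fiss = derive_fissure_mask(mask_from(np.ones((5, 5, 5))), mask_from(whole))
        assert fiss.count() == 0

    def test_missing_center_voxel_becomes_fissure(self):
        whole = self._block()
        binary = whole.copy()
        binary[2, 2, 2] = 0
        fiss = derive_fissure_mask(mask_from(binary), mask_from(whole))
        assert fiss.count() == 1 and fiss.data[2, 2, 2] == 1

    def test_bright_voxels_outside_whole_ignored(self):
        whole = self._block()
        binary = np.ones((5, 5, 5), dtype=np.uint8)
        binary[0, 0, 0] = 0  # dark voxel outside the cerebellum
        fiss = derive_fissure_mask(mask_from(binary), mask_from(whole))
        assert fiss.count() == 0

    def test_tissue_is_whole_minus_fissures(self):
        whole = self._block()
        fiss = np.zeros_like(whole)
        fiss[2, 2, 2] = 1
        tissue = derive_tissue_mask(mask_from(whole), mask_from(fiss))
        assert tissue.count() == 26
        assert tissue.data[2, 2, 2] == 0

    def test_empty_fissures_gives_tissue_equal_whole(self):
        whole = self._block()
        tissue = derive_tissue_mask(mask_from(whole), mask_from(np.zeros_like(whole)))
        assert np.array_equal(tissue.data, whole)

    def test_fissures_equal_whole_gives_empty_tissue(self):
        whole = self._block()
        assert derive_tissue_mask(mask_from(whole), mask_from(whole)).count() == 0

    def test_uncontained_fissures_rejected(self):
        whole = self._block()
        fiss = np.zeros_like(whole)
        fiss[0, 0, 0] = 1
        with pytest.raises(GridError):
            derive_tissue_mask(mask_from(whole), mask_from(fiss))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridError):
            derive_fissure_mask(mask_from(np.ones((4, 4, 4))),
                                mask_from(np.ones((5, 5, 5))))


class TestBuildLabelTriplet:
    def test_noiseless_phantom_recovers_truth_exactly(self, clean_phantom):
        enhanced = enhance_contrast(clean_phantom.volume)
        trip = build_label_triplet(enhanced, clean_phantom.truth.whole,
                                   MaskGenConfig(use_snakes=False))
        assert dice(trip.fissures, clean_phantom.truth.fissures) == 1.0
        assert np.array_equal(trip.tissue.data, clean_phantom.truth.tissue.data)
        assert np.array_equal(trip.whole.data, clean_phantom.truth.whole.data)

    def test_no_fissure_phantom_gives_empty_fissure_map(self):
        from fissnet.phantom import PhantomParams, generate_phantom

        s = generate_phantom(PhantomParams(grid_shape=(32, 32, 32),
                                           ellipsoid_semi_axes=(12, 10, 8),
                                           n_fissures=0, noise_sigma=0.0,
                                           bias_field_amplitude=0.0))
        trip = build_label_triplet(enhance_contrast(s.volume), s.truth.whole,
                                   MaskGenConfig(use_snakes=False))
        assert trip.fissures.count() == 0

    def test_invariants_hold_with_snakes_and_noise(self, noisy_phantom):
        enhanced = enhance_contrast(noisy_phantom.volume)
        trip = build_label_triplet(enhanced, noisy_phantom.truth.whole,
                                   MaskGenConfig(snake_iterations=5))
        f, t, w = trip.fissures.bool, trip.tissue.bool, trip.whole.bool
        assert not np.any(f & t)
        assert np.array_equal(f | t, w)

    def test_deterministic(self, clean_phantom):
        enhanced = enhance_contrast(clean_phantom.volume)
        a = build_label_triplet(enhanced, clean_phantom.truth.whole)
        b = build_label_triplet(enhanced, clean_phantom.truth.whole)
        assert np.array_equal(a.fissures.data, b.fissures.data)
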