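"""Morphometry operations: projection, registration, bleaching, Isodata,
segmentation, volume law, ROI and area statistics."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_isodata

from ecsastro.morphometry import (EmptyMaskError, area_fraction,
                                  average_projection, bleach_correct,
                                  isodata_threshold, register_timestack,
                                  roi_intensity, soma_mask, volume_timecourse)
from helpers import brute_force_intermeans, gaussian_blob


class TestProjection:
    def test_constant_stack(self):
        assert np.all(average_projection(np.full((5, 4, 4), 7.0)) == 7.0)

    def test_two_slice_mean(self):
        stack = np.stack([np.zeros((3, 3)), np.full((3, 3), 8.0)])
        assert np.all(average_projection(stack) == 4.0)

    def test_projection_mass_equals_voxel_sum(self, rng):
        stack = rng.random((10, 32, 32))
        proj = average_projection(stack)
        assert proj.sum() * stack.shape[0] == pytest.approx(stack.sum())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_projection(np.empty((0, 4, 4)))


class TestRegistration:
    def test_identical_frames_zero_shift(self):
        f = gaussian_blob()
        _, shifts = register_timestack([f, f.copy(), f.copy()])
        np.testing.assert_allclose(shifts, 0.0, atol=1e-6)

    def test_integer_shift_recovered(self):
        f = gaussian_blob()
        moved = np.roll(np.roll(f, 3, axis=0), -2, axis=1)
        _, shifts = register_timestack([f, moved])
        np.testing.assert_allclose(shifts[1], [3, -2], atol=0.1)

    def test_subpixel_shift_recovered(self):
        f = gaussian_blob()
        moved = ndimage.shift(f, (0.5, -0.5), order=3)
        _, shifts = register_timestack([f, moved])
        np.testing.assert_allclose(shifts[1], [0.5, -0.5], atol=0.2)

    def test_alignment_restores_frame(self):
        f = gaussian_blob()
        moved = np.roll(f, 4, axis=1)
        aligned, _ = register_timestack([f, moved])
        core = np.s_[10:-10, 10:-10]
        assert np.max(np.abs(aligned[1][core] - f[core])) < 1e-6 * f.max() + 1e-3

    def test_featureless_frames_warn(self):
        with pytest.warns(UserWarning):
            _, shifts = register_timestack([np.zeros((16, 16)),
                                            np.zeros((16, 16))])
        np.testing.assert_allclose(shifts, 0.0)


class TestBleachCorrection:
    def test_no_decay_leaves_frames_unchanged(self):
        frames = [gaussian_blob()] * 4
        corrected, decay = bleach_correct(frames, n_baseline=3)
        np.testing.assert_allclose(decay, 1.0)
        np.testing.assert_allclose(corrected[3], frames[3])

    def test_linear_decay_restored(self):
        base = gaussian_blob()
        frames = [base * (1 - 0.02 * i) for i in range(6)]
        corrected, _ = bleach_correct(frames, n_baseline=3)
        totals = [f.sum() for f in corrected]
        np.testing.assert_allclose(totals, totals[0], rtol=1e-3)

    def test_increasing_baseline_caps_and_warns(self):
        base = gaussian_blob()
        frames = [base * (1 + 0.05 * i) for i in range(4)]
        with pytest.warns(UserWarning):
            _, decay = bleach_correct(frames, n_baseline=3)
        assert np.all(decay <= 1.0)

    def test_single_baseline_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct([gaussian_blob()] * 3, n_baseline=1)


class TestIsodata:
    def test_two_valued_fixed_point(self):
        """Equal counts of {10, 200}: fixed point at (10+200)/2 = 105."""
        frame = np.array([[10.0, 200.0]] * 8)
        assert isodata_threshold(frame) == pytest.approx(105.0, abs=1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        frame = np.concatenate([rng.normal(60, 15, 600),
                                rng.normal(180, 20, 400)])
        frame = np.clip(frame, 0, 255).round().reshape(40, 25)
        T = isodata_threshold(frame)
        T_bf = brute_force_intermeans(frame)
        assert abs(T - T_bf) <= (frame.max() - frame.min()) / 256 + 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_skimage_on_bimodal_frames(self, seed):
        rng = np.random.default_rng(100 + seed)
        frame = np.concatenate([rng.normal(50, 10, 500),
                                rng.normal(200, 15, 500)])
        frame = np.clip(frame, 0, 255).round().astype(np.uint8).reshape(50, 20)
        T = isodata_threshold(frame)
        T_sk = threshold_isodata(frame)
        assert abs(T - T_sk) <= 2.0

    def test_scale_equivariance(self, rng):
        frame = np.clip(rng.normal(100, 40, (32, 32)), 0, 255)
        T = isodata_threshold(frame)
        assert isodata_threshold(frame * 3.0) == pytest.approx(3.0 * T,
                                                               rel=2e-2)

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError):
            isodata_threshold(np.full((8, 8), 3.0))


class TestSomaMask:
    def disk_frame(self, radius=10, shape=(64, 64), value=200.0):
        rr, cc = np.indices(shape)
        frame = np.zeros(shape)
        frame[(rr - 32) ** 2 + (cc - 32) ** 2 <= radius**2] = value
        return frame

    def test_disk_area_matches_analytic(self):
        frame = self.disk_frame(radius=10)
        mask, ss = soma_mask(frame, 100.0, (32, 32), pixel_size_um=(0.41, 0.41))
        analytic = np.pi * (10 * 0.41) ** 2
        # one pixel-boundary ring of tolerance
        ring = 2 * np.pi * 10 * 0.41**2
        assert abs(ss - analytic) <= ring

    def test_only_seeded_component_counted(self):
        frame = np.zeros((64, 64))
        frame[10:20, 10:20] = 200.0
        frame[40:50, 40:50] = 200.0
        mask, ss = soma_mask(frame, 100.0, (15, 15), pixel_size_um=(1.0, 1.0))
        assert ss == pytest.approx(100.0)
        assert not mask[45, 45]

    def test_seed_below_threshold_raises(self):
        frame = np.zeros((16, 16))
        with pytest.raises(EmptyMaskError):
            soma_mask(frame, 0.5, (8, 8))


class TestVolumeLaw:
    def test_ratio_identity_and_four_to_eight(self):
        tc = volume_timecourse([5.0, 5.0, 20.0], [0, 1, 2], reference_index=0)
        assert tc.vol_pct[0] == 100.0
        assert tc.vol_pct[1] == 100.0
        assert tc.vol_pct[2] == pytest.approx(800.0)

    def test_linear_scale_f_gives_f_cubed(self):
        """Area scale f² → volume scale f³, exact for analytic areas."""
        f = 1.37
        tc = volume_timecourse([10.0, 10.0 * f**2], [0, 1], reference_index=0)
        assert tc.vol_pct[1] == pytest.approx(100.0 * f**3, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            volume_timecourse([0.0, 5.0], [0, 1], reference_index=0)


class TestRoiIntensity:
    def test_constant_frame_sum(self):
        frame = np.full((64, 64), 3.0)
        fi = roi_intensity([frame], (32, 32), diameter_um=2.0,
                           pixel_size_um=(0.41, 0.41))
        # brute-force pixel-in-circle count
        rr, cc = np.indices((64, 64))
        n_px = np.sum(((rr - 32) * 0.41) ** 2 + ((cc - 32) * 0.41) ** 2 <= 1.0)
        assert fi[0] == pytest.approx(3.0 * n_px)

    def test_linearity(self, rng):
        frame = rng.random((64, 64))
        fi1 = roi_intensity([frame], (32, 32))
        fi2 = roi_intensity([2 * frame], (32, 32))
        assert fi2[0] == pytest.approx(2 * fi1[0])

    def test_clipped_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_intensity([np.ones((16, 16))], (0, 0), diameter_um=4.0)


class TestAreaFraction:
    def test_half_bright_region(self):
        frame = np.zeros((40, 40))
        frame[:, 20:] = 200.0
        frac, mean_gray = area_fraction(frame, np.ones((40, 40), bool))
        assert frac == pytest.approx(0.5, abs=0.02)
        assert mean_gray == pytest.approx(200.0, abs=1.0)

    def test_mean_gray_of_segmented_exceeds_region_mean(self, rng):
        frame = np.clip(rng.normal(50, 10, (40, 40)), 0, None)
        frame[10:20, 10:20] += 150.0
        frac, mean_gray = area_fraction(frame, np.ones((40, 40), bool))
        assert mean_gray >= frame.mean()

    def test_constant_region_rejected(self):
        with pytest.raises(ValueError):
            area_fraction(np.full((8, 8), 1.0), np.ones((8, 8), bool))
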