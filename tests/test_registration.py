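"""Channel splitting, hot pixels, rotation estimation, derotation,
subpixel refinement, background subtraction and cross-sample alignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from tiltscope.registration import (
    RegisteredStack,
    SampleMap,
    align_across_samples,
    derotate_stack,
    detect_beads,
    estimate_rotation,
    refine_registration,
    repair_hot_pixels,
    split_channels,
    subtract_background,
)
from tiltscope.stimulus import make_tilt_trajectory
from tiltscope.synthetic import (
    Acquisition,
    ArtifactModel,
    bead_sources,
    make_bead_field,
    render_stack,
)


class TestSplitChannels:
    def test_zero_offset_recovers_channels(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        back = split_channels(stack.to_wview())
        assert np.array_equal(back.green, stack.green)
        assert np.array_equal(back.red, stack.red)

    def test_offset_applied_at_export_is_undone_at_split(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        w = stack.to_wview().copy()
        h = stack.green.shape[1]
        # simulate a 1-row red-vs-green misalignment on the sensor
        w[:, h:] = np.roll(w[:, h:], 1, axis=1)
        back = split_channels(w, vertical_offset=1)
        # realigned to < 0.5 px: interior rows agree exactly
        assert np.array_equal(back.red[:, 1:-1], stack.red[:, 1:-1])

    def test_odd_height_without_offsets_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            split_channels(np.zeros((2, 31, 16)))

    def test_huge_offsets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            split_channels(np.zeros((2, 32, 16)), vertical_offset=10)


class TestHotPixels:
    def _stack_with_hot(self, coords, shape=(448, 456), n_frames=6):
        rng = np.random.default_rng(0)
        g = rng.poisson(100.0, (n_frames, *shape)).astype(np.float32)
        r = rng.poisson(100.0, (n_frames, *shape)).astype(np.float32)
        for (row, col) in coords:
            g[:, row, col] = 60000.0
        from tiltscope.synthetic import TwoChannelStack

        return TwoChannelStack(green=g, red=r, pixel_size_um=1 / 3.4,
                               frame_rate=10.0,
                               angle_per_frame=np.zeros(n_frames))

    def test_three_hot_pixels_in_448x456_gives_paper_fraction(self):
        stack = self._stack_with_hot([(10, 10), (200, 300), (400, 50)])
        _, rep = repair_hot_pixels(stack)
        assert rep.n_pixels == 3
        # 3 / (448 × 456) = 0.0015% of the per-channel FOV (to 2 significant
        # figures)
        per_channel = rep.n_pixels / (448 * 456)
        assert round(per_channel * 100, 4) == 0.0015

    def test_no_hot_pixels_leaves_stack_unchanged(self):
        stack = self._stack_with_hot([])
        out, rep = repair_hot_pixels(stack)
        assert rep.n_pixels == 0
        assert np.array_equal(out.green, stack.green)

    def test_replacement_is_neighborhood_median(self):
        stack = self._stack_with_hot([(5, 5)], shape=(32, 32))
        nb = [stack.green[0, r, c]
              for r in range(4, 7) for c in range(4, 7) if (r, c) != (5, 5)]
        out, _ = repair_hot_pixels(stack)
        assert out.green[0, 5, 5] == np.median(nb)

    def test_auto_detection_needs_three_frames(self):
        stack = self._stack_with_hot([], n_frames=2)
        with pytest.raises(ValueError):
            repair_hot_pixels(stack)

    def test_excessive_flags_warn(self):
        stack = self._stack_with_hot([], shape=(24, 24), n_frames=5)
        mask = np.zeros((24, 24), bool)
        mask[:3] = True  # 12.5% of pixels
        with pytest.warns(UserWarning, match="suspicious"):
            repair_hot_pixels(stack, detection="mask", mask_green=mask)


class TestDetectBeads:
    def _frame_with_spot(self, row, col, sigma=1.5, shape=(128, 128)):
        from tiltscope.synthetic import _render_spot

        f = np.zeros(shape)
        _render_spot(f, row, col, 20000.0, sigma)
        return f

    def test_subpixel_centroid_recovery(self):
        f = self._frame_with_spot(100.3, 50.7)
        det = detect_beads(f)
        assert len(det) == 1
        assert det.row[0] == pytest.approx(100.3, abs=0.2)
        assert det.col[0] == pytest.approx(50.7, abs=0.2)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            detect_beads(np.zeros((64, 64)))

    def test_merged_beads_flagged(self):
        f = self._frame_with_spot(60.0, 60.0)
        f += self._frame_with_spot(60.0, 62.5)  # closer than 2 sigma
        det = detect_beads(f)
        assert len(det) == 1
        assert bool(det.merged[0])

    def test_border_components_excluded(self):
        f = self._frame_with_spot(64.0, 64.0) + self._frame_with_spot(1.0, 30.0)
        det = detect_beads(f)
        assert len(det) == 1
        assert det.row[0] == pytest.approx(64.0, abs=0.2)


class TestEstimateRotation:
    def test_known_angles_recovered_to_02_degrees(self):
        traj = make_tilt_trajectory("tilt90", ring=False, hold=1.0,
                                    pre_still=1.0)
        acq = Acquisition(fov=(192, 192))
        beads = make_bead_field(20, fov=(192, 192), seed=0)
        stack = render_stack(bead_sources(beads), traj, acq=acq, seed=0)
        est = estimate_rotation(stack)
        err = est.angle_per_frame - stack.angle_per_frame
        assert np.abs(err).max() < 0.2

    def test_static_stack_gives_zero_angles(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        est = estimate_rotation(stack)
        assert np.abs(est.angle_per_frame).max() < 1e-6

    def test_symmetric_two_bead_pair_flagged_ambiguous(self, static_traj):
        from tiltscope.synthetic import BeadField

        acq = Acquisition(fov=(128, 128), rotation_center=(63.5, 63.5))
        beads = BeadField(
            offsets_px=np.array([[0.0, 30.0], [0.0, -30.0]]),
            green=np.array([20000.0, 20000.0]),
            red=np.array([20000.0, 20000.0]),
            sigma_px=1.5, fov=(128, 128), pixel_size_um=1 / 3.4, seed=0)
        stack = render_stack(bead_sources(beads), static_traj,
                             artifact=ArtifactModel.disabled(), acq=acq, seed=0)
        est = estimate_rotation(stack)
        assert est.ambiguous

    def test_single_bead_requires_center(self, static_traj):
        from tiltscope.synthetic import BeadField

        acq = Acquisition(fov=(96, 96))
        beads = BeadField(offsets_px=np.array([[10.0, 10.0]]),
                          green=np.array([20000.0]), red=np.array([20000.0]),
                          sigma_px=1.5, fov=(96, 96), pixel_size_um=1 / 3.4,
                          seed=0)
        stack = render_stack(bead_sources(beads), static_traj,
                             artifact=ArtifactModel.disabled(), acq=acq, seed=0)
        with pytest.raises(ValueError, match="center"):
            estimate_rotation(stack)

    def test_angle_series_is_continuous(self):
        traj = make_tilt_trajectory("tilt360", ring=False, hold=1.0,
                                    pre_still=1.0)
        acq = Acquisition(fov=(192, 192))
        beads = make_bead_field(15, fov=(192, 192), seed=2)
        stack = render_stack(bead_sources(beads), traj, acq=acq, seed=2)
        est = estimate_rotation(stack)
        assert np.abs(np.diff(est.angle_per_frame)).max() < 10.0


class TestDerotation:
    def test_round_trip_correlates_with_first_frame(self):
        traj = make_tilt_trajectory("tilt90", ring=False, hold=1.0,
                                    pre_still=1.0)
        acq = Acquisition(fov=(160, 160))
        beads = make_bead_field(12, fov=(160, 160), seed=3)
        stack = render_stack(bead_sources(beads), traj,
                             artifact=ArtifactModel.disabled(), acq=acq, seed=3)
        est = estimate_rotation(stack)
        reg = derotate_stack(stack, est)
        j = int(np.argmax(np.abs(stack.angle_per_frame)))
        m = reg.valid[j] & reg.valid[0]
        corr = np.corrcoef(reg.green[j][m], reg.green[0][m])[0, 1]
        assert corr > 0.99

    def test_zero_angles_are_identity(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        est = estimate_rotation(stack)
        reg = derotate_stack(stack, est)
        assert np.allclose(reg.green, stack.green, atol=1e-3)

    def test_transform_log_covers_all_frames(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        reg = derotate_stack(stack, estimate_rotation(stack))
        assert len(reg.transforms) == stack.n_frames


class TestRefinement:
    def _shifted_stack(self, shifts):
        rng_shift = np.asarray(shifts)
        from tiltscope.synthetic import make_bead_field, render_stack

        acq = Acquisition(fov=(128, 128))
        beads = make_bead_field(15, fov=(128, 128), seed=5)
        n = len(shifts) * 100 * 10 + 1
        from tiltscope.stimulus import StageTrajectory

        t = np.arange(len(shifts) * 1000) / 1000.0
        z = np.zeros_like(t)
        traj = StageTrajectory(t=t, theta=z, omega=z, alpha=z,
                               protocol="static", sample_rate=1000.0)
        stack = render_stack(bead_sources(beads), traj,
                             artifact=ArtifactModel.disabled(), acq=acq, seed=5)
        g = stack.green.copy()
        r = stack.red.copy()
        T = g.shape[0]
        applied = np.zeros((T, 2))
        for j in range(min(T, len(shifts))):
            applied[j] = shifts[j]
            if np.any(applied[j]):
                g[j] = ndimage.shift(stack.green[j], applied[j], order=1)
                r[j] = ndimage.shift(stack.red[j], applied[j], order=1)
        reg = RegisteredStack(
            green=g, red=r, valid=np.ones_like(g, bool),
            angle_applied=np.zeros(T), center=np.array([63.5, 63.5]),
            shifts=np.zeros((T, 2)), pixel_size_um=1 / 3.4, frame_rate=10.0)
        return reg, applied

    def test_known_subpixel_shifts_recovered_to_tenth_pixel(self):
        grid = [(dy, dx) for dy in (-0.5, -0.2, 0.0, 0.3)
                for dx in (-0.4, 0.0, 0.1, 0.5)]
        # unshifted frames first: they form the temporal-median reference
        grid = [(0.0, 0.0)] * 10 + grid
        reg, applied = self._shifted_stack(grid)
        out = refine_registration(reg)
        err = np.abs(out.shifts + applied)
        assert err.max() <= 0.1

    def test_specific_shift_estimated_within_005(self):
        reg, applied = self._shifted_stack([(0, 0), (0, 0), (0.3, -0.2)])
        out = refine_registration(reg)
        assert np.abs(out.shifts[2] + np.array([0.3, -0.2])).max() <= 0.05

    def test_identical_frames_give_zero_shift(self):
        reg, _ = self._shifted_stack([(0, 0)] * 5)
        out = refine_registration(reg)
        assert np.all(out.shifts == 0.0)

    def test_refinement_is_idempotent(self):
        reg, _ = self._shifted_stack(
            [(0, 0), (0, 0), (0.37, -0.11), (-0.23, 0.44)])
        once = refine_registration(reg)
        twice = refine_registration(once)
        assert np.abs(twice.shifts - once.shifts).max() < 0.02


class TestBackground:
    def test_uniform_background_recovered(self, static_traj):
        beads = bead_sources(make_bead_field(10, fov=(96, 96), seed=6))
        acq = Acquisition(fov=(96, 96))
        art = ArtifactModel(gain_excursion=0.0, channel_noise_sd=0.0,
                            n_hot_pixels=0, background_level=80.0,
                            photon_noise=False)
        stack = render_stack(beads, static_traj, artifact=art, acq=acq, seed=6)
        reg = derotate_stack(stack, estimate_rotation(stack))
        out = subtract_background(reg)
        assert out.background[0] == pytest.approx(80.0, abs=2.0)
        assert out.background[1] == pytest.approx(80.0, abs=2.0)

    def test_zero_background_stack_unchanged(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        reg = derotate_stack(stack, estimate_rotation(stack))
        out = subtract_background(reg)
        assert out.background[0] == pytest.approx(0.0, abs=1e-6)

    def test_bright_region_warns(self, clean_bead_stack):
        stack, beads, acq = clean_bead_stack
        reg = derotate_stack(stack, estimate_rotation(stack))
        mask = np.zeros(reg.green.shape[1:], bool)
        r, c = np.round(beads.offsets_px[0] + acq.center()).astype(int)
        mask[r - 2:r + 3, c - 2:c + 3] = True
        with pytest.warns(UserWarning, match="brighter"):
            subtract_background(reg, region=mask)


class TestAlignAcrossSamples:
    def _map(self, side):
        df = pd.DataFrame({
            "x_rc": [0.0, 10.0], "y_ml": [5.0, -5.0],
            "pref_rc": [1.0, 0.0], "pref_ml": [0.0, 2.0],
        })
        return SampleMap(table=df, side=side, landmark_um=(0.0, 20.0))

    def test_left_map_only_translated(self):
        out = align_across_samples([self._map("left")])[0]
        assert np.allclose(out.y_ml, [5.0 - 20.0, -5.0 - 20.0])
        assert np.allclose(out.pref_ml, [0.0, 2.0])

    def test_right_map_mirrored_twice_is_original(self):
        m = self._map("right")
        once = align_across_samples([m])[0]
        again = align_across_samples(
            [SampleMap(table=once, side="right", landmark_um=(0.0, 0.0))])[0]
        # two mirrors cancel on the vector components
        assert np.allclose(again.pref_ml, m.table.pref_ml)

    def test_mirrored_lateral_down_vector_stays_lateral_down(self):
        # in a right-ear camera frame the lateral direction appears with
        # flipped sign; after mirroring, anatomical lateral is positive again
        df = pd.DataFrame({"x_rc": [0.0], "y_ml": [0.0],
                           "pref_rc": [0.0], "pref_ml": [-2.0]})
        m = SampleMap(table=df, side="right", landmark_um=(0.0, 0.0))
        out = align_across_samples([m])[0]
        assert out.pref_ml.iloc[0] == pytest.approx(2.0)

    def test_missing_landmark_rejected(self):
        m = SampleMap(table=pd.DataFrame({"x_rc": [0.0]}), side="left",
                      landmark_um=None)
        with pytest.raises(ValueError, match="landmark"):
            align_across_samples([m])
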