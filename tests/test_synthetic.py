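"""Generator ground truth: layouts, response model, rendering, volumes."""

import numpy as np
import pytest

from tiltscope.stimulus import make_tilt_trajectory
from tiltscope.synthetic import (
    Acquisition,
    ArtifactModel,
    ResponseModel,
    bead_sources,
    make_bead_field,
    make_macula_layout,
    make_photoconversion_volume,
    render_stack,
    simulate_responses,
)


class TestBeadField:
    def test_single_bead_is_seeded(self):
        b1 = make_bead_field(1, fov=(128, 128), seed=3)
        b2 = make_bead_field(1, fov=(128, 128), seed=3)
        assert np.array_equal(b1.offsets_px, b2.offsets_px)

    def test_layout_reproducible_at_paper_scale(self):
        a = make_bead_field(116, fov=(448, 456), seed=9)
        b = make_bead_field(116, fov=(448, 456), seed=9)
        assert np.array_equal(a.offsets_px, b.offsets_px)
        assert a.n == 116

    def test_minimum_separation_enforced(self):
        b = make_bead_field(60, fov=(256, 256), seed=0)
        d = np.linalg.norm(b.offsets_px[:, None] - b.offsets_px[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3.0 * 3.4 - 1e-9

    def test_overcrowded_fov_rejected(self):
        with pytest.raises(ValueError):
            make_bead_field(500, fov=(64, 64), seed=0)

    def test_beads_stay_inside_rotation_circle(self):
        b = make_bead_field(40, fov=(256, 256), seed=1)
        r = np.linalg.norm(b.offsets_px, axis=1)
        assert r.max() <= 128 - 14


class TestMaculaLayout:
    def test_polarity_vectors_are_unit_norm(self):
        lay = make_macula_layout(85, seed=0)
        n = np.hypot(lay.cells.pol_rc, lay.cells.pol_ml)
        assert np.allclose(n, 1.0)

    def test_polarity_reverses_across_lpr(self):
        lay = make_macula_layout(200, seed=1, min_sep_um=3.0)
        rel = lay.cells[["x_rc", "y_ml"]].to_numpy() - np.array(lay.focus_um)
        d = np.hypot(*rel.T)
        outward = rel / d[:, None]
        pol = lay.cells[["pol_rc", "pol_ml"]].to_numpy()
        dot = np.sum(outward * pol, axis=1)
        beyond = d > lay.lpr_distance_um
        assert np.all(dot[beyond] < 0)      # reversed: point back toward LPR
        assert np.all(dot[~beyond] > 0)     # normal: point toward LPR

    def test_striolar_count_strictly_between_0_and_n(self):
        lay = make_macula_layout(85, seed=2)
        k = int(lay.cells.striolar.sum())
        assert 0 < k < lay.n

    def test_reversed_cells_are_all_striolar(self):
        # medial-down preferring cells must not exist in the extrastriola
        lay = make_macula_layout(85, seed=3)
        rel = lay.cells[["x_rc", "y_ml"]].to_numpy() - np.array(lay.focus_um)
        beyond = np.hypot(*rel.T) > lay.lpr_distance_um
        assert np.all(lay.cells.striolar.to_numpy()[beyond])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            make_macula_layout(5)

    def test_seeded_reproducibility(self):
        a = make_macula_layout(85, seed=4).cells
        b = make_macula_layout(85, seed=4).cells
        assert a.equals(b)


class TestResponseModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ResponseModel(tilt_gain_striola=0.9, tilt_gain_extrastriola=0.8)
        with pytest.raises(ValueError):
            ResponseModel(vibration_gain_striola=0.01,
                          vibration_gain_extrastriola=0.05)
        with pytest.raises(ValueError):
            ResponseModel(indicator_rise_tau=0.0)

    def test_flat_trajectory_gives_zero_traces(self, static_traj):
        lay = make_macula_layout(20, seed=0)
        tr = simulate_responses(lay, static_traj, seed=0)
        assert np.all(tr.traces == 0.0)

    def test_monophasic_antipreferred_tilt_is_zero(self):
        traj = make_tilt_trajectory("tilt90", ring=False)
        lay = make_macula_layout(40, seed=1)
        # silence the vibration pathway: tilt ramps impose a little real
        # inertial acceleration that would otherwise leak in
        model = ResponseModel(biphasic_fraction=0.0,
                              vibration_gain_striola=1e-12,
                              vibration_gain_extrastriola=0.0)
        tr = simulate_responses(lay, traj, model, session="pitch", seed=0)
        pol = lay.cells[["pol_rc", "pol_ml"]].to_numpy()
        c = pol[:, 0]
        # a caudally-tuned cell never responds while theta > 0 (nose-down)
        caudal = np.argmin(c)
        nose_down = np.interp(tr.t, traj.t, traj.theta) > 5.0
        assert c[caudal] < -0.3
        assert np.all(tr.traces[caudal][nose_down] <= 1e-12)

    def test_biphasic_antipreferred_steady_state_matches_closed_form(self):
        # steady state of the first-order kinetics equals the drive:
        # −negative_lobe_ratio × gain × |p·a|
        traj = make_tilt_trajectory("tilt90", hold=20.0, ring=False)
        lay = make_macula_layout(30, seed=2)
        model = ResponseModel(biphasic_fraction=1.0, negative_lobe_ratio=0.2)
        tr = simulate_responses(lay, traj, model, session="pitch", seed=0)
        pol = lay.cells[["pol_rc", "pol_ml"]].to_numpy()
        c = pol[:, 0]
        striolar = lay.cells.striolar.to_numpy()
        gains = np.where(striolar, model.tilt_gain_striola,
                         model.tilt_gain_extrastriola)
        theta = np.interp(tr.t, traj.t, traj.theta)
        # end of the +90° hold: anti-preferred for caudal-pointing cells
        j = np.nonzero(theta > 89.9)[0][-1]
        anti = c < -0.3
        expected = -model.negative_lobe_ratio * gains[anti] * np.abs(c[anti])
        assert np.allclose(tr.traces[anti, j], expected, atol=5e-3)

    def test_vgn_adaptation_decays_during_hold(self):
        from tiltscope.synthetic import vgn_model

        traj = make_tilt_trajectory("tilt90", ring=False)
        lay = make_macula_layout(20, seed=3)
        tr = simulate_responses(lay, traj, vgn_model(), session="pitch", seed=0)
        theta = np.interp(tr.t, traj.t, traj.theta)
        hold = np.nonzero(theta > 89.9)[0]
        i = int(np.argmax(tr.traces[:, hold[0]]))
        early = tr.traces[i, hold[:3]].mean()
        late = tr.traces[i, hold[-3:]].mean()
        assert late < early


class TestRenderStack:
    def test_identical_seeds_give_bit_identical_stacks(self, static_traj):
        beads = bead_sources(make_bead_field(5, fov=(96, 96), seed=0))
        acq = Acquisition(fov=(96, 96))
        a = render_stack(beads, static_traj, acq=acq, seed=7)
        b = render_stack(beads, static_traj, acq=acq, seed=7)
        assert np.array_equal(a.green, b.green)
        assert np.array_equal(a.red, b.red)

    def test_clean_static_frames_are_identical(self, clean_bead_stack):
        stack, _, _ = clean_bead_stack
        assert np.array_equal(stack.green[0], stack.green[-1])

    def test_rotation_moves_sources_as_rigid_rotation(self):
        # artifact off: a frame at angle θ equals frame 0 with positions
        # rotated by θ about the center
        from tiltscope.registration import detect_beads

        traj = make_tilt_trajectory("tilt90", ring=False)
        acq = Acquisition(fov=(160, 160))
        beads = make_bead_field(6, fov=(160, 160), seed=2)
        stack = render_stack(bead_sources(beads), traj,
                             artifact=ArtifactModel.disabled(), acq=acq, seed=2)
        j = int(np.argmax(stack.angle_per_frame))
        th = np.deg2rad(stack.angle_per_frame[j])
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = beads.offsets_px @ R.T + acq.center()
        found = detect_beads(stack.green[j])[["row", "col"]].to_numpy()
        d = np.linalg.norm(expected[:, None] - found[None], axis=2).min(axis=1)
        assert d.max() < 0.2

    def test_hot_pixels_have_zero_temporal_variance(self, static_traj):
        beads = bead_sources(make_bead_field(5, fov=(96, 96), seed=1))
        acq = Acquisition(fov=(96, 96))
        art = ArtifactModel(n_hot_pixels=4)
        stack = render_stack(beads, static_traj, artifact=art, acq=acq, seed=1)
        for (r, c, v) in stack.metadata["hot_pixels"]:
            ch, row = (stack.green, r) if r < 96 else (stack.red, r - 96)
            assert np.all(ch[:, int(row), int(c)] == v)

    def test_full_common_mode_gain_keeps_static_ratio_constant(self, static_traj):
        beads = bead_sources(make_bead_field(8, fov=(96, 96), seed=3))
        acq = Acquisition(fov=(96, 96))
        art = ArtifactModel(common_mode_fraction=1.0, channel_noise_sd=0.0,
                            n_hot_pixels=0, background_level=0.0,
                            photon_noise=False)
        stack = render_stack(beads, static_traj, artifact=art, acq=acq, seed=3)
        bright = stack.red[0] > np.percentile(stack.red[0], 99)
        ratio = stack.green[:, bright] / stack.red[:, bright]
        drift = np.abs(ratio / ratio[0] - 1.0)
        assert drift.max() < 1e-3

    def test_default_artifact_360_tilt_exceeds_50pct_single_channel(self):
        traj = make_tilt_trajectory("tilt360", ring=False)
        acq = Acquisition(fov=(256, 256))
        beads = make_bead_field(35, fov=(256, 256), seed=1)
        stack = render_stack(bead_sources(beads), traj, acq=acq, seed=1)
        # track the max green excursion at the (known) bead positions
        theta = stack.angle_per_frame
        maxdev = 0.0
        base = None
        for j in range(0, stack.n_frames, 7):
            th = np.deg2rad(theta[j])
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            pos = np.round(beads.offsets_px @ R.T + acq.center()).astype(int)
            vals = stack.green[j][pos[:, 0], pos[:, 1]].astype(float)
            if base is None:
                base = vals
            maxdev = max(maxdev, np.abs(vals / base - 1.0).max())
        assert maxdev > 0.5

    def test_trace_length_mismatch_rejected(self, static_traj):
        beads = bead_sources(make_bead_field(3, fov=(96, 96), seed=0))
        with pytest.raises(ValueError):
            render_stack(beads, static_traj, traces=np.zeros((3, 4)),
                         acq=Acquisition(fov=(96, 96)))

    def test_wview_roundtrip(self, clean_bead_stack):
        from tiltscope.registration import split_channels

        stack, _, _ = clean_bead_stack
        back = split_channels(stack.to_wview())
        assert np.array_equal(back.green, stack.green)
        assert np.array_equal(back.red, stack.red)


class TestRenderMeasureRoundTrip:
    def test_perfect_oracle_recovers_truth_traces(self):
        """Render → register → measure with truth ROIs reproduces the input
        response traces to better than 1% relative error (no artifacts)."""
        from tiltscope.pipeline import measure_stack, register_stack
        from tiltscope.synthetic import layout_sources

        traj = make_tilt_trajectory("tilt90", ring=False)
        # well-separated somata: no spot-overlap crosstalk between ROIs
        lay = make_macula_layout(12, seed=6, semi_axes_um=(32.0, 20.0),
                                 min_sep_um=10.0)
        model = ResponseModel(biphasic_fraction=0.0)
        tr = simulate_responses(lay, traj, model, session="pitch", seed=0)
        acq = Acquisition(fov=(256, 256))
        src = layout_sources(lay, acq, session="pitch")
        stack = render_stack(src, traj, traces=tr,
                             artifact=ArtifactModel.disabled(), acq=acq, seed=6)
        reg, _ = register_stack(stack, repair=False)
        traces = measure_stack(
            reg, src[["row_off", "col_off"]].to_numpy() + acq.center(),
            3.5, traj)
        from tiltscope.ratiometric import boxcar_smooth

        truth = boxcar_smooth(tr.traces, 3, axis=1)
        err = np.abs(traces.drr - truth)
        assert err.max() < 0.01


class TestPhotoconversionVolume:
    def test_seeded_volumes_identical(self):
        a, _, _, _ = make_photoconversion_volume(seed=5)
        b, _, _, _ = make_photoconversion_volume(seed=5)
        assert np.array_equal(a, b)

    def test_zero_gradient_gives_flat_truth(self):
        _, _, _, truth = make_photoconversion_volume(
            ratio_range=(1.5, 1.5), seed=0)
        u = np.linspace(0, 1, 7)
        assert np.allclose(truth(u), 1.5)

    def test_decreasing_gradient_truth_monotone(self):
        _, _, _, truth = make_photoconversion_volume(
            ratio_range=(2.0, 0.5), seed=0)
        u = np.linspace(0, 1, 9)
        assert np.all(np.diff(truth(u)) < 0)

    def test_minimum_shape_enforced(self):
        with pytest.raises(ValueError):
            make_photoconversion_volume(shape=(8, 32, 32))
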