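"""Side-view detection, profile extraction, smoothing, alignment, peaks."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synquant import synthdata as sd
from synquant import profiles as prof
from synquant.errors import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
)
from synquant.stack import ImageStack


def _stack_from_arrays(px, **role_images):
    roles, mods, planes = [], [], []
    for role, img in role_images.items():
        roles.append(role)
        mods.append("sted" if role in ("psd95", "channel_of_interest") else "confocal")
        planes.append(np.asarray(img, dtype=float))
    return ImageStack(np.stack(planes), tuple(roles), tuple(mods), px)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


class TestDetection:
    def test_single_side_view_synapse(self, single_synapse_stack):
        scene, stack = single_synapse_stack
        dets = prof.detect_side_view_synapses(stack)
        assert len(dets) == 1
        truth = scene.synapses[0]
        d_angle = abs(dets[0].axis_angle_rad - truth.axis_angle_rad)
        d_angle = min(d_angle, math.pi - d_angle)
        assert d_angle < math.radians(5.0)
        err = np.hypot(dets[0].anchor_nm[0] - truth.center_nm[0],
                       dets[0].anchor_nm[1] - truth.center_nm[1])
        assert err < 50.0  # anchor lands on the PSD bar center

    def test_round_psd_rejected_by_elongation(self, small_optics):
        s = sd.SynapseTruth(center_nm=(2700.0, 2700.0), axis_angle_rad=0.0,
                            psd_length_nm=101.0, psd_thickness_nm=100.0,
                            channel_amplitude=0.0)
        scene = sd.SceneTruth(optics=small_optics, synapses=(s,), seed=0)
        stack = sd.render_stack(scene, noise="none")
        assert prof.detect_side_view_synapses(stack, min_elongation=2.0) == []

    def test_blank_psd_channel(self, small_optics):
        scene = sd.build_scene(small_optics, 0, seed=0)
        stack = sd.render_stack(scene, noise="none")
        assert prof.detect_side_view_synapses(stack) == []

    def test_missing_channel_is_configuration_error(self):
        stack = _stack_from_arrays(14.194, psd95=np.zeros((16, 16)))
        with pytest.raises(ConfigurationError):
            prof.detect_side_view_synapses(stack)

    def test_far_synapsin_rejected_by_adjacency(self, small_optics):
        s = sd.SynapseTruth(center_nm=(2700.0, 2700.0), axis_angle_rad=0.0,
                            channel_amplitude=0.0,
                            vesicle_cloud_offset_nm=1500.0)
        scene = sd.SceneTruth(optics=small_optics, synapses=(s,), seed=0)
        stack = sd.render_stack(scene, noise="none")
        assert prof.detect_side_view_synapses(stack, adjacency_radius_nm=150.0) == []


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


class TestExtractProfile:
    def test_zero_image_gives_zero_profile(self):
        stack = _stack_from_arrays(
            20.0, psd95=np.zeros((128, 128)), synapsin=np.zeros((128, 128))
        )
        syn = prof.SideViewSynapse("s", (1280.0, 1280.0), 0.0)
        p = prof.extract_profile(stack, syn, length_nm=600, width_nm=100)
        assert np.all(p.values["psd95"] == 0)

    def test_uniform_band_plateau(self):
        """An axis-aligned band of value v spanning the ROI width reproduces
        its 1-D cross-section with plateau v."""
        px = 20.0
        img = np.zeros((128, 128))
        img[60:66, :] = 7.0  # band along x, 6 px (120 nm) thick
        stack = _stack_from_arrays(px, psd95=img, synapsin=np.zeros_like(img))
        syn = prof.SideViewSynapse("s", (1280.0, 62.5 * px), 0.0)
        p = prof.extract_profile(stack, syn, length_nm=800, width_nm=200)
        assert p.values["psd95"].max() == pytest.approx(7.0)
        inside = np.abs(p.positions_nm) <= 30.0
        assert np.allclose(p.values["psd95"][inside], 7.0)
        outside = np.abs(p.positions_nm) >= 200.0
        assert np.allclose(p.values["psd95"][outside], 0.0)

    def test_rotation_equivariance(self, small_optics):
        """The same synapse rendered at 0° and at 30° yields the same
        profile to within 2% RMS (noiseless)."""
        profiles = []
        for angle in (0.0, math.radians(30.0)):
            s = sd.SynapseTruth(center_nm=(2700.0, 2700.0), axis_angle_rad=angle,
                                channel_offset_nm=-50.0)
            scene = sd.SceneTruth(optics=small_optics, synapses=(s,), seed=0)
            stack = sd.render_stack(scene, noise="none")
            syn = prof.SideViewSynapse("s", (2700.0, 2700.0), angle)
            profiles.append(prof.extract_profile(stack, syn))
        a = profiles[0].values["channel_of_interest"]
        b = profiles[1].values["channel_of_interest"]
        rms = np.sqrt(np.mean((a - b) ** 2)) / a.max()
        assert rms < 0.02

    def test_translation_equivariance(self, small_optics):
        """Translating the scene by whole pixels translates the profile."""
        px = small_optics.pixel_size_nm
        outs = []
        for shift_px in (0, 7):
            c = (2000.0 + shift_px * px, 2500.0)
            s = sd.SynapseTruth(center_nm=c, axis_angle_rad=1.0,
                                channel_offset_nm=-50.0)
            scene = sd.SceneTruth(optics=small_optics, synapses=(s,), seed=0)
            stack = sd.render_stack(scene, noise="none")
            syn = prof.SideViewSynapse("s", c, 1.0)
            outs.append(prof.extract_profile(stack, syn))
        a = outs[0].values["channel_of_interest"]
        b = outs[1].values["channel_of_interest"]
        assert np.sqrt(np.mean((a - b) ** 2)) / a.max() < 0.02

    def test_rectangle_exiting_image_is_boundary_error(self):
        stack = _stack_from_arrays(20.0, psd95=np.ones((64, 64)),
                                   synapsin=np.ones((64, 64)))
        syn = prof.SideViewSynapse("s", (40.0, 40.0), 0.0)
        with pytest.raises(prof.BoundaryError):
            prof.extract_profile(stack, syn, length_nm=1000, width_nm=200)

    def test_presynaptic_side_is_negative(self, single_synapse_stack):
        """The synapsin-heavier side lands on negative positions."""
        _, stack = single_synapse_stack
        det = prof.detect_side_view_synapses(stack)[0]
        p = prof.extract_profile(stack, det)
        syn = p.values["synapsin"]
        assert syn[p.positions_nm < 0].sum() > syn[p.positions_nm > 0].sum()


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


class TestSmoothing:
    def test_constant_preserved(self):
        out = prof.smooth_rolling_average(np.full(11, 3.25), 5)
        assert np.allclose(out, 3.25)

    def test_impulse_center(self):
        out = prof.smooth_rolling_average([0, 0, 0, 0, 5, 0, 0, 0, 0], 5)
        assert out[4] == pytest.approx(1.0)

    def test_edge_window_clips(self):
        out = prof.smooth_rolling_average([5, 0, 0, 0, 0], 5)
        assert out[0] == pytest.approx(5.0 / 3.0)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            prof.smooth_rolling_average([1, 2, 3, 4], 4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=60),
           st.sampled_from([1, 3, 5]))
    def test_bounded_by_input_range(self, values, window):
        out = prof.smooth_rolling_average(values, window)
        assert out.min() >= min(values) - 1e-6 * (1 + abs(min(values)))
        assert out.max() <= max(values) + 1e-6 * (1 + abs(max(values)))


# ---------------------------------------------------------------------------
# peak location / alignment
# ---------------------------------------------------------------------------


def _profile(positions, psd, coi=None, synapse_id="s"):
    vals = {"psd95": np.asarray(psd, dtype=float)}
    if coi is not None:
        vals["channel_of_interest"] = np.asarray(coi, dtype=float)
    return prof.IntensityProfile(np.asarray(positions, dtype=float), vals, synapse_id)


class TestLocatePeak:
    def test_gaussian_center_recovered(self):
        pos = np.arange(-500, 501, 10.0)
        psd = np.exp(-0.5 * ((pos - 300) / 80.0) ** 2)
        loc = prof.locate_psd_peak(_profile(pos, psd))
        assert abs(loc.position_nm - 300.0) <= 5.0  # half a grid step

    def test_tie_broken_to_smallest_position(self):
        pos = np.arange(-100, 101, 50.0)
        psd = np.array([0.0, 2.0, 1.0, 2.0, 0.0])
        loc = prof.locate_psd_peak(_profile(pos, psd), smooth_px=1)
        assert loc.position_nm == -50.0

    def test_all_zero_is_degenerate(self):
        pos = np.arange(-100, 101, 50.0)
        with pytest.raises(DegenerateInputError):
            prof.locate_psd_peak(_profile(pos, np.zeros(5)))

    def test_flat_profile_flagged(self):
        pos = np.arange(-100, 101, 50.0)
        loc = prof.locate_psd_peak(_profile(pos, np.full(5, 2.0)), smooth_px=1)
        assert loc.degenerate and loc.position_nm == -100.0


class TestAlign:
    def test_single_profile_mean_is_member(self):
        pos = np.arange(-500, 501, 10.0)
        psd = np.exp(-0.5 * (pos / 80.0) ** 2)
        coi = np.exp(-0.5 * ((pos + 50) / 60.0) ** 2)
        aligned = prof.align_profiles([_profile(pos, psd, coi)])
        assert np.allclose(aligned.sem["channel_of_interest"], 0.0)
        assert aligned.n_synapses == 1
        i0 = np.argmin(np.abs(aligned.positions_nm))
        sm = aligned.mean["psd95"]
        assert sm[i0] == sm.max()

    def test_shifted_copies_align_identically(self):
        pos = np.arange(-500, 501, 10.0)
        psd = np.exp(-0.5 * (pos / 80.0) ** 2)
        coi = np.exp(-0.5 * ((pos + 50) / 60.0) ** 2)
        k = 3
        aligned = prof.align_profiles(
            [_profile(pos, psd, coi, "a"),
             _profile(pos, np.roll(psd, k), np.roll(coi, k), "b")],
            min_coverage=1.0,
        )
        m = aligned.members["channel_of_interest"]
        ok = ~np.isnan(m[0]) & ~np.isnan(m[1])
        # interior samples identical after alignment (roll wrap ends excluded)
        assert np.allclose(m[0][ok][k:-k or None], m[1][ok][k:-k or None])
        assert np.allclose(aligned.sem["channel_of_interest"][ok][k:-k or None], 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(prof.ValidationError):
            prof.align_profiles([])

    def test_members_peak_at_zero(self, small_optics):
        """Alignment invariant: every member's smoothed PSD peaks at 0."""
        scene = sd.build_scene(small_optics, 2, seed=9, min_spacing_nm=2000.0,
                               margin_nm=1500.0)
        stack = sd.render_stack(scene, noise="poisson")
        dets = prof.detect_side_view_synapses(stack)
        ps = [prof.extract_profile(stack, d) for d in dets]
        aligned = prof.align_profiles(ps)
        i0 = int(np.argmin(np.abs(aligned.positions_nm)))
        for row in aligned.members["psd95"]:
            assert np.nanmax(row) == row[i0]


class TestPeakInWindow:
    def test_out_of_window_max_ignored(self):
        pos = np.arange(-500, 501, 10.0)
        val = np.zeros_like(pos)
        val[pos == -300] = 9.0
        val[pos == -40] = 7.0
        m = prof.peak_in_window(pos, val, window_nm=200)
        assert m.peak_value == 7.0 and m.peak_position_nm == -40.0

    def test_all_zero_flagged(self):
        pos = np.arange(-500, 501, 10.0)
        m = prof.peak_in_window(pos, np.zeros_like(pos))
        assert m.peak_value == 0.0 and m.degenerate

    def test_window_exceeding_grid_rejected(self):
        pos = np.arange(-50, 51, 10.0)
        with pytest.raises(ParameterError):
            prof.peak_in_window(pos, np.ones_like(pos), window_nm=500)

    def test_tie_prefers_nearest_zero_then_negative(self):
        pos = np.arange(-100, 101, 50.0)
        val = np.array([1.0, 5.0, 0.0, 5.0, 1.0])
        m = prof.peak_in_window(pos, val, window_nm=200)
        assert m.peak_position_nm == -50.0

    def test_window_monotonicity(self, rng):
        pos = np.arange(-500, 501, 10.0)
        val = rng.normal(size=pos.shape)
        peaks = [prof.peak_in_window(pos, val, window_nm=w).peak_value
                 for w in (100, 200, 400, 800)]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))


class TestOffsetRecovery:
    def test_noiseless_recovery_within_one_pixel(self, small_optics):
        px = small_optics.pixel_size_nm
        for i, off in enumerate([0.0, 25.0, 50.0, 100.0, 150.0]):
            scene = sd.build_scene(small_optics, 1, fixed_offsets_nm=[-off],
                                   seed=20 + i, margin_nm=2000.0)
            stack = sd.render_stack(scene, noise="none")
            det = prof.detect_side_view_synapses(stack)[0]
            aligned = prof.align_profiles([prof.extract_profile(stack, det)])
            pk = prof.member_peaks(aligned, window_nm=400)[0]
            assert abs(pk.peak_position_nm - (-off)) <= px + 1e-9


def test_summarize_peaks_shapes():
    ms = [prof.PeakMeasurement(f"s{i}", "channel_of_interest", float(i), 0.0, 200.0)
          for i in range(3)]
    with pytest.warns(UserWarning):
        df = prof.summarize_peaks({"a": ms, "b": ms, "empty": []})
    assert len(df) == 6
    assert set(df["condition"]) == {"a", "b"}
    assert list(df.loc[df.condition == "a", "peak_value"]) == [0.0, 1.0, 2.0]
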