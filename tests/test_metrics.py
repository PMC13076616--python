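"""DSI, primitive metrics, noise robustness and space-time mapping."""

import numpy as np
import pytest

from emdevo.metrics import (PRESENCE_THRESHOLD, PrimitiveCoordinates,
                            alignment_metric, amplitude_metric, bl_metrics,
                            classify_primitives, compare_slopes, dsi,
                            grating_dsi, hr_metric, noise_robustness_curve,
                            response_duration_fwhm, spacetime_map)
from emdevo.stimuli import Arena, make_1d_bar_noise


def boxcar(start, width, total=200, amp=1.0):
    tr = np.zeros(total)
    tr[start:start + width] = amp
    return tr


class TestDSI:
    def test_equal_responses_over_equally_spaced_directions_give_zero(self):
        th = np.arange(12) * 2 * np.pi / 12
        assert dsi(np.full(12, 3.7), th) == pytest.approx(0.0, abs=1e-12)

    def test_single_preferred_response_gives_one(self):
        assert dsi([5.0, 0.0, 0.0], [0.0, 2.0, 4.0]) == 1.0

    def test_two_direction_worked_value(self):
        # R = {0: 2, pi: 1} -> (2 - 1) / 3 = 1/3, bit-exact
        assert dsi([2.0, 1.0], [0.0, np.pi]) == (2.0 - 1.0) / 3.0

    def test_negative_responses_floored_at_zero(self):
        assert dsi([2.0, -5.0], [0.0, np.pi]) == 1.0

    def test_all_zero_convention(self):
        assert dsi([0.0, 0.0], [0.0, np.pi]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsi([1.0, 2.0], [0.0])


class TestGratingDSI:
    def test_identical_sinusoids_untuned(self):
        t = np.linspace(0, 10 * np.pi, 500)
        traces = [np.sin(t)] * 4
        th = np.arange(4) * np.pi / 2
        assert grating_dsi(traces, th) == pytest.approx(0.0, abs=1e-12)

    def test_flat_trace_contributes_zero(self):
        t = np.linspace(0, 10 * np.pi, 500)
        assert grating_dsi([np.sin(t), np.zeros(500) - 60.0],
                           [0.0, np.pi]) == 1.0

    def test_modulation_depth_increases_dsi(self):
        t = np.linspace(0, 10 * np.pi, 500)
        base = grating_dsi([np.sin(t), 0.5 * np.sin(t)], [0.0, np.pi])
        deeper = grating_dsi([2 * np.sin(t), 0.5 * np.sin(t)], [0.0, np.pi])
        assert deeper > base

    def test_onset_transient_excluded_from_steady_window(self):
        v = np.zeros(1000)
        v[:100] = 50.0  # large transient, then silence
        v2 = np.sin(np.linspace(0, 20 * np.pi, 1000))
        assert grating_dsi([v, v2], [0.0, np.pi]) == pytest.approx(-1.0)


class TestDurationAndHR:
    def test_fwhm_of_boxcar(self):
        assert response_duration_fwhm(boxcar(50, 40), 5.0) == 200.0

    def test_fwhm_uses_largest_contiguous_interval(self):
        tr = boxcar(10, 10) + boxcar(100, 30)
        assert response_duration_fwhm(tr, 5.0) == 150.0

    def test_equal_durations_give_zero(self):
        traces = [boxcar(10 * i, 20) for i in range(4)]
        assert hr_metric(np.array(traces), [0, 1, 2, 3], 5.0) == 0.0

    def test_worked_magnitude_half_ratio(self):
        # narrowest = half of widest -> (1 - 0.5)^2 = 0.25; narrowing
        # durations along the axis -> positive (H&R) sign
        traces = np.array([boxcar(0, 40), boxcar(60, 30), boxcar(120, 20)])
        val = hr_metric(traces, [0.0, 1.0, 2.0], 5.0)
        assert val == pytest.approx(+0.25)

    def test_axis_reversal_flips_sign_preserves_magnitude(self):
        traces = np.array([boxcar(0, 40), boxcar(60, 30), boxcar(120, 20)])
        a = hr_metric(traces, [0.0, 1.0, 2.0], 5.0)
        b = hr_metric(traces, [2.0, 1.0, 0.0], 5.0)
        assert b == pytest.approx(-a)

    def test_too_few_active_synapses_rejected(self):
        with pytest.raises(ValueError):
            hr_metric(np.array([boxcar(0, 10), np.zeros(200)]), [0, 1], 5.0)


class TestOverlapMetrics:
    def test_identical_waveforms_maximal_for_both(self):
        tr = np.array([boxcar(40, 60)] * 8)
        amp = amplitude_metric(tr)
        ali = alignment_metric(tr)
        # mean of the normalized common waveform over its active window
        assert amp == pytest.approx(1.0)
        assert ali == pytest.approx(1.0)

    def test_disjoint_waveforms_zero_alignment_metric(self):
        # five sequential non-overlapping activations: a single active
        # trace is 20% of the population, below the 25% quorum
        tr = np.array([boxcar(35 * i, 20) for i in range(5)])
        assert alignment_metric(tr) == 0.0

    def test_alignment_exceeds_amplitude_on_staggered_but_aligned_peaks(self):
        # same shape, staggered in time: peak alignment recovers overlap
        tr = np.array([boxcar(20 * i, 30) for i in range(4)])
        assert amplitude_metric(tr) > alignment_metric(tr) - 1e-12

    def test_quorum_boundary_inclusive(self):
        # exactly 25% of waveforms active counts as overlap for alignment
        tr = np.vstack([boxcar(0, 40), np.zeros(200), np.zeros(200),
                        np.zeros(200)])
        tr[1, 100:110] = 1.0
        tr[2, 120:130] = 1.0
        tr[3, 140:150] = 1.0
        assert alignment_metric(tr) > 0.0

    def test_half_overlapping_boxcars_match_hand_computation(self):
        # two populations of equal boxcars shifted by half their width:
        # after peak alignment they coincide exactly -> metric 1;
        # unaligned, the quorum holds over the 60-sample union and the
        # mean overlap waveform is (20*0.5 + 20*1 + 20*0.5)/60 = 2/3
        a = boxcar(40, 40)
        b = boxcar(60, 40)
        tr = np.array([a, a, b, b])
        assert amplitude_metric(tr) == pytest.approx(1.0)
        assert alignment_metric(tr) == pytest.approx(2.0 / 3.0)

    def test_all_zero_traces_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert amplitude_metric(np.zeros((3, 50))) == 0.0


class TestBLMetrics:
    def test_uniform_inhibition_gives_thirds(self):
        exc = np.ones(300)
        inh = np.ones(300)
        m = bl_metrics(exc, inh, inh, dt=1.0)
        assert m["bl"] == pytest.approx(1.0 / 3.0, abs=0.01)
        assert m["anti_bl"] == pytest.approx(1.0 / 3.0, abs=0.01)
        assert m["amp_inhib"] == 0.0

    def test_late_inhibition_is_pure_bl(self):
        exc = boxcar(0, 90, total=300)
        inh = boxcar(200, 50, total=300)
        m = bl_metrics(exc, inh, inh, dt=1.0)
        assert m["bl"] == pytest.approx(1.0)
        assert m["anti_bl"] == 0.0

    def test_pause_worked_value_three_vs_one(self):
        # peak inhibition 3 in the null direction vs 1 inside the middle
        # window of the preferred response -> (3-1)/(3+1) = 0.5
        exc = np.ones(300)
        inh_pref = boxcar(120, 60, total=300)  # entirely inside the middle window
        inh_null = np.full(300, 3.0)
        m = bl_metrics(exc, inh_pref, inh_null, dt=1.0)
        assert m["bl"] < PRESENCE_THRESHOLD and m["anti_bl"] < PRESENCE_THRESHOLD
        assert m["pause"] == pytest.approx((3.0 - 1.0) / (3.0 + 1.0))

    def test_pause_not_computed_when_bl_present(self):
        exc = boxcar(0, 90, total=300)
        inh = boxcar(210, 60, total=300)
        m = bl_metrics(exc, inh, inh, dt=1.0)
        assert m["pause"] is None

    def test_amp_inhib_clipped_at_zero(self):
        exc = np.ones(100)
        m = bl_metrics(exc, 3.0 * np.ones(100), np.ones(100), dt=1.0)
        assert m["amp_inhib"] == 0.0

    def test_zero_excitatory_area_rejected(self):
        with pytest.raises(ValueError):
            bl_metrics(np.zeros(100), np.ones(100), np.ones(100))

    def test_window_fraction_bound(self):
        # inhibition fully inside the excitatory window: the three
        # fractions can never sum above one
        rng = np.random.default_rng(0)
        exc = np.abs(rng.normal(1, 0.3, 300))
        inh = np.abs(rng.normal(1, 0.3, 300))
        m = bl_metrics(exc, inh, inh, dt=1.0)
        assert m["bl"] + m["anti_bl"] <= 1.0 + 1e-12


class TestClassification:
    def test_presence_threshold_is_twenty_percent(self):
        c = PrimitiveCoordinates(x=0.21, y=-0.19)
        assert "HR" in c.present and "amplitude" not in c.present
        c2 = PrimitiveCoordinates(x=-0.25, y=0.3)
        assert {"anti-HR", "alignment"} <= c2.present
        assert c2.hybrid

    def test_symmetric_circuit_has_no_primitive(self):
        traces = np.array([boxcar(30 + 10 * i, 30) for i in range(4)])
        coords = classify_primitives(traces, [0, 1, 2, 3], 5.0)
        assert coords.x == 0.0
        assert not {"HR", "anti-HR"} & coords.present

    def test_classification_deterministic(self):
        rng = np.random.default_rng(2)
        traces = np.abs(rng.normal(0.5, 0.2, (6, 120)))
        a = classify_primitives(traces, np.arange(6), 5.0)
        b = classify_primitives(traces, np.arange(6), 5.0)
        assert (a.x, a.y) == (b.x, b.y)

    def test_inhibitory_axes_populated_when_drives_given(self):
        traces = np.array([boxcar(30, 40), boxcar(50, 40)])
        exc = traces.sum(axis=0)
        inh_pref = boxcar(150, 30)
        coords = classify_primitives(traces, [0, 1], 5.0,
                                     exc_drive_pref=exc,
                                     inh_drive_pref=inh_pref,
                                     inh_drive_null=inh_pref)
        assert coords.x_inh is not None
        assert "BL" in coords.present


class TestNoiseRobustness:
    @staticmethod
    def _response(noise_sd, direction, seed):
        # synthetic circuit: preferred responses 1, null 0.5, with noise
        rng = np.random.default_rng(seed + int(direction * 1000))
        base = 1.0 if abs(direction) < 1e-9 else 0.5
        return base * max(0.0, 1.0 - 0.05 * noise_sd + rng.normal(0, 0.02 * (1 + noise_sd)))

    def test_zero_noise_normalizes_to_exactly_one(self):
        out = noise_robustness_curve(self._response, (0.0, 1.0, 2.5), 10, seed=0)
        assert out["normalized_dsi"][0] == 1.0

    def test_declining_synthetic_tuning_gives_negative_slope(self):
        out = noise_robustness_curve(self._response, (0.0, 1.0, 2.5, 5.0), 30,
                                     seed=1)
        assert out["slope"] < 0.0

    def test_mean_estimate_variance_shrinks_with_trial_count(self):
        # Monte-Carlo scaling: the dispersion of the per-level mean DSI
        # across repeated campaigns shrinks roughly like 1/sqrt(n)
        def means(n_trials):
            return [noise_robustness_curve(self._response, (0.0, 5.0),
                                           n_trials, seed=s)["mean_dsi"][1]
                    for s in range(8)]
        v_small = np.var(means(5))
        v_large = np.var(means(80))
        assert v_large < v_small / 3.0

    def test_slope_anova_detects_group_difference(self):
        f, p = compare_slopes([-0.10, -0.11, -0.09, -0.12],
                              [-0.02, -0.01, -0.03, -0.02])
        assert p < 0.01


class TestSpaceTimeMap:
    def _linear_response(self, stim, kernel, gain_per_bar):
        # noiseless linear responder: per-bar gain, shared temporal kernel
        vals = stim.meta["epoch_values"][stim.meta["epoch_of_frame"]]
        drive = vals @ gain_per_bar
        return np.convolve(drive, kernel)[:drive.size]

    def test_map_recovers_spatial_gain_profile(self):
        arena = Arena(width=200.0, height=200.0, pixel_size=20.0, dt=10.0)
        stim = make_1d_bar_noise(arena, bar_width=40.0, update_interval=100.0,
                                 seed=0, duration=60000.0)
        gains = np.array([0.2, 1.0, 3.0, 1.0, 0.2])
        kernel = np.exp(-np.arange(20) / 5.0)
        resp = self._linear_response(stim, kernel, gains)
        m = spacetime_map(resp, 10.0, stim, window=200.0)
        profile = m.spatial_rf
        assert profile.argmax() == 2
        np.testing.assert_allclose(profile / profile.max(), gains / gains.max(),
                                   atol=0.25)

    def test_uniform_model_gives_flat_spatial_profile(self):
        arena = Arena(width=200.0, height=200.0, pixel_size=20.0, dt=10.0)
        stim = make_1d_bar_noise(arena, bar_width=40.0, update_interval=100.0,
                                 seed=3, duration=60000.0)
        kernel = np.exp(-np.arange(20) / 5.0)
        resp = self._linear_response(stim, kernel, np.ones(5))
        m = spacetime_map(resp, 10.0, stim, window=200.0)
        p = m.spatial_rf
        assert np.ptp(p) / p.max() < 0.25

    def test_under_sampling_warns_with_counts(self):
        arena = Arena(width=200.0, height=200.0, pixel_size=20.0, dt=10.0)
        stim = make_1d_bar_noise(arena, bar_width=40.0, update_interval=100.0,
                                 seed=1, duration=800.0)
        with pytest.warns(UserWarning, match="under-sampled"):
            spacetime_map(np.zeros(80), 10.0, stim, window=200.0)

    def test_requires_bar_noise_stimulus(self, small_arena):
        from emdevo.stimuli import make_moving_bar
        stim = make_moving_bar(small_arena, 1.0, 0.0)
        with pytest.raises(ValueError):
            spacetime_map(np.zeros(10), 5.0, stim)
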