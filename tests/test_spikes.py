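import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import proteospike as ps
from _oracles import brute_force_peaks
from conftest import make_recording


class TestRemoveBaseline:
    @pytest.mark.parametrize("method,kw", [
        ("linear_fit", {}),
        ("prestim_mean", {"prestim_end": 5.0}),
    ])
    def test_constant_maps_to_zeros(self, method, kw):
        rec = make_recording(np.full(50, 7.0))
        out = ps.remove_baseline(rec, method=method, **kw)
        assert np.allclose(out.values, 0.0)

    def test_linear_fit_removes_drift(self):
        t = np.arange(5000.0)
        spikes = np.zeros_like(t)
        spikes[::500] = 5.0
        rec = make_recording(0.01 * t + spikes)
        out = ps.remove_baseline(rec, method="linear_fit")
        residual_slope = np.polyfit(t, out.values, 1)[0]
        assert abs(residual_slope) < 1e-6 * 0.01

    def test_moving_median_preserves_isolated_spike_heights(self):
        # spikes well separated relative to the window, so heights are "truth"
        cfg = ps.GeneratorConfig(
            amplitude_mean=3.76, amplitude_sd=1.85,
            period_mean=2000.0, period_sd=200.0,
            duration=10.0, noise_sd=0.0, seed=13,
            baseline=ps.BaselineConfig(offset=2.0, drift=1e-5),
        )
        rec, ev = ps.simulate_recording(cfg, n_events=100)
        out = ps.remove_baseline(rec, method="moving_median", window=500.0)
        peaks = ps.detect_spikes(out, min_prominence=0.5, min_height=0.5)
        assert len(peaks) == 100
        assert np.allclose(peaks.heights, ev.event_amplitudes, rtol=0.01)

    def test_window_below_three_samples_rejected(self):
        rec = make_recording(np.zeros(100))
        with pytest.raises(ValueError, match="3"):
            ps.remove_baseline(rec, method="moving_median", window=2.0)


class TestSubtractReference:
    def test_self_difference_is_zero(self, rng):
        rec = make_recording(rng.normal(size=100))
        assert np.allclose(ps.subtract_reference(rec, rec).values, 0.0)

    def test_constant_offset_recovered(self, rng):
        x = rng.normal(size=100)
        a, b = make_recording(x + 3.0), make_recording(x)
        assert np.allclose(ps.subtract_reference(a, b).values, 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            ps.subtract_reference(make_recording(np.zeros(5)),
                                  make_recording(np.zeros(6)))

    def test_temperature_minus_drift_twin_leaves_spikes(self):
        base = ps.BaselineConfig(offset=19.0, drift=1e-5, sin_amplitude=0.2,
                                 sin_period=2000.0)
        cfg = ps.GeneratorConfig(amplitude_mean=0.5, period_mean=300.0,
                                 duration=3000.0, spike_width=20.0,
                                 noise_sd=0.0, baseline=base, seed=4)
        ev = ps.sample_event_train(cfg)
        stim = ps.render_signal(ev, cfg, channel_kind=ps.TEMPERATURE_C)
        twin = ps.render_signal(ps.EventTrain([], []), cfg,
                                channel_kind=ps.TEMPERATURE_C)
        residual = ps.subtract_reference(stim, twin)
        assert residual.channel_kind == ps.TEMPERATURE_C
        assert residual.values.max() == pytest.approx(0.5, rel=1e-3)
        # off-spike residual is identically zero
        far = np.ones(len(residual), bool)
        for tk in ev.event_times:
            far &= np.abs(residual.times - tk) > 6 * cfg.spike_width
        assert np.allclose(residual.values[far], 0.0)


class TestDetectSpikes:
    def test_monotone_signal_has_no_peaks(self):
        rec = make_recording(np.arange(50.0))
        peaks = ps.detect_spikes(rec, min_prominence=0.0, min_height=0.0,
                                 min_separation=1.0)
        assert len(peaks) == 0

    def test_two_gaussian_bumps(self):
        t = np.arange(400.0)
        v = np.exp(-0.5 * ((t - 100) / 8) ** 2) + np.exp(-0.5 * ((t - 300) / 8) ** 2)
        peaks = ps.detect_spikes(make_recording(v), min_prominence=0.5,
                                 min_height=0.0, min_separation=10.0)
        assert np.array_equal(peaks.indices, [100, 300])

    def test_plateau_reports_leftmost_sample(self):
        v = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        peaks = ps.detect_spikes(make_recording(v), min_prominence=0.0,
                                 min_height=0.0, min_separation=1.0)
        assert np.array_equal(peaks.indices, [1])

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            ps.detect_spikes(make_recording([0.0, 1.0]), min_prominence=0,
                             min_height=0, min_separation=1.0)

    def test_matches_brute_force_on_random_signals(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 1000))
            v = np.round(rng.normal(size=n), 2)  # rounding provokes ties/plateaus
            prom = float(rng.uniform(0, 2))
            sep = float(rng.integers(1, 15))
            height = float(rng.uniform(-1, 1))
            rec = make_recording(v)
            got = ps.detect_spikes(rec, min_prominence=prom,
                                   min_separation=sep, min_height=height)
            want_idx, want_prom = brute_force_peaks(
                rec.times, v, prom, sep, height)
            assert list(got.indices) == want_idx
            assert np.allclose(got.prominences, want_prom)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.integers(min_value=-5, max_value=5), min_size=3, max_size=40
        ),
        sep=st.integers(min_value=1, max_value=8),
        prom=st.integers(min_value=0, max_value=4),
    )
    def test_property_equals_oracle(self, values, sep, prom):
        """Integer-valued signals maximize tie and plateau coverage."""
        v = np.array(values, float)
        rec = make_recording(v)
        got = ps.detect_spikes(rec, min_prominence=prom, min_separation=sep,
                               min_height=-10.0)
        want_idx, _ = brute_force_peaks(rec.times, v, prom, sep, -10.0)
        assert list(got.indices) == want_idx


class TestPeriodsAndSummaries:
    def test_periods_are_successive_differences(self):
        peaks = ps.PeakSet(np.array([0, 100, 250]), np.array([0.0, 100.0, 250.0]),
                           np.ones(3), np.ones(3))
        assert np.array_equal(ps.peak_periods(peaks), [100.0, 150.0])

    def test_single_peak_has_no_periods(self):
        peaks = ps.PeakSet(np.array([5]), np.array([5.0]), np.ones(1), np.ones(1))
        assert ps.peak_periods(peaks).size == 0

    def test_constant_sample_summary(self):
        s = ps.summarize(np.full(10, 5.0))
        assert (s.q1, s.q2, s.q3, s.mean, s.max, s.min, s.sd) == (5,) * 6 + (0,)

    def test_type7_quartiles_hand_values(self):
        s = ps.summarize([1.0, 2.0, 3.0, 4.0])
        assert (s.q1, s.q2, s.q3) == (1.75, 2.5, 3.25)

    def test_midpoint_convention_is_selectable(self):
        s = ps.summarize([1.0, 2.0, 3.0, 4.0], quartile_method="midpoint")
        assert (s.q1, s.q2, s.q3) == (1.5, 2.5, 3.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.summarize([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        scale=st.floats(-5, 5).filter(lambda c: abs(c) > 1e-3),
        shift=st.floats(-50, 50),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariant_and_affine_equivariant(self, data, scale, shift, seed):
        x = np.array(data)
        s = ps.summarize(x)
        perm = ps.summarize(np.random.default_rng(seed).permutation(x))
        for field in ("q1", "q2", "q3", "mean", "max", "min", "sd"):
            assert getattr(perm, field) == pytest.approx(
                getattr(s, field), rel=1e-12, abs=1e-12)
        a = ps.summarize(scale * x + shift)
        lo, hi = sorted((scale * s.min + shift, scale * s.max + shift))
        assert a.mean == pytest.approx(scale * s.mean + shift, abs=1e-6)
        assert a.min == pytest.approx(lo, abs=1e-6)
        assert a.max == pytest.approx(hi, abs=1e-6)
        assert a.sd == pytest.approx(abs(scale) * s.sd, abs=1e-6)
        qs = sorted((scale * s.q1 + shift, scale * s.q3 + shift))
        assert a.q1 == pytest.approx(qs[0], abs=1e-6)
        assert a.q2 == pytest.approx(scale * s.q2 + shift, abs=1e-6)
        assert a.q3 == pytest.approx(qs[1], abs=1e-6)


class TestProfileCharacter:
    def test_zero_noise_periodic_train_has_tiny_period_sd(self):
        cfg = ps.GeneratorConfig(amplitude_mean=3.0, period_mean=200.0,
                                 duration=5000.0, spike_width=10.0,
                                 noise_sd=0.0, seed=1, label="A")
        rec, _ = ps.simulate_recording(cfg)
        prof = ps.profile_character(rec, min_prominence=1.0, min_height=1.0)
        assert prof.period.sd <= rec.sampling_interval
        assert prof.period.mean == pytest.approx(200.0, abs=1.0)

    def test_single_spike_is_an_error(self):
        cfg = ps.GeneratorConfig(amplitude_mean=3.0, period_mean=200.0,
                                 duration=350.0, spike_width=10.0,
                                 noise_sd=0.0, seed=1, label="A")
        rec, ev = ps.simulate_recording(cfg)
        assert len(ev) == 1
        with pytest.raises(ValueError, match="insufficient spikes"):
            ps.profile_character(rec, min_prominence=1.0, min_height=1.0)

    def test_label_required(self):
        rec = make_recording(np.zeros(100))
        with pytest.raises(ValueError, match="label"):
            ps.profile_character(rec)

    def test_unbiased_over_seeds(self, table):
        # parameter recovery: pooled estimate within Monte-Carlo error
        profile = table["O"]
        n, seeds = 150, range(5)
        estimates = []
        for seed in seeds:
            cfg = ps.GeneratorConfig.from_profile(profile, duration=10.0, seed=seed)
            rec, _ = ps.simulate_recording(cfg, n_events=n)
            estimates.append(ps.profile_character(rec, label="O").amplitude.mean)
        pooled_se = profile.amplitude.sd / np.sqrt(n * len(estimates))
        assert abs(np.mean(estimates) - profile.amplitude.mean) < 3 * pooled_se + 0.05
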