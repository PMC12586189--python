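"""Generator tests: breath trains, IPFM heartbeats, rendered channels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resphrv as rv
from resphrv.synth import respiratory_waveform


class TestBreathTrain:
    def test_zero_variance_tiles_exactly(self):
        resp = rv.RespParams(base_frequency=120, frequency_cv=0,
                             amplitude_cv=0)
        train = rv.generate_breath_train(resp, 60.0, seed=0)
        assert train.n_cycles == 120
        assert np.allclose(train.periods, 0.5)
        assert np.allclose(train.end_inspirations - train.onsets,
                           resp.inspiration_fraction * 0.5)
        # contiguous tiling of [0, 60]
        assert np.allclose(train.onsets[1:], train.ends[:-1])
        assert train.onsets[0] == 0.0

    def test_variable_periods_match_drawn_statistics(self):
        resp = rv.RespParams(base_frequency=125, frequency_cv=0.1)
        train = rv.generate_breath_train(resp, 60.0, seed=1)
        # count within Poisson-like tolerance of 125; mean period ~0.48 s
        assert abs(train.n_cycles - 125) < 4 * np.sqrt(125) * 0.1 + 3
        assert np.isclose(train.periods.mean(), 0.48, rtol=0.05)
        # drawn-period statistics: CV close to requested
        assert np.isclose(train.periods.std() / train.periods.mean(), 0.1,
                          atol=0.03)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            rv.generate_breath_train(rv.RespParams(), 0.0, seed=0)

    def test_seed_reproducibility_bitwise(self):
        a = rv.generate_breath_train(rv.RespParams(), 30.0, seed=42)
        b = rv.generate_breath_train(rv.RespParams(), 30.0, seed=42)
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            rv.RespParams(base_frequency=-1)
        with pytest.raises(ValueError):
            rv.RespParams(inspiration_fraction=1.2)


def _steady_train(period=0.5, fi=0.33, duration=60.0):
    n = int(np.ceil(duration / period))
    on = np.arange(n) * period
    return rv.BreathTrain(on, on + fi * period, on + period, np.ones(n))


class TestIPFM:
    @pytest.mark.parametrize("hr_bpm, duration", [(600.0, 1.0), (60.0, 10.0)])
    def test_constant_rate_closed_form(self, hr_bpm, duration):
        card = rv.CardiacParams(base_hr=hr_bpm, resp_mod_depth=0.0,
                                hr_noise_sd=0.0)
        train = _steady_train(duration=duration + 1)
        beats = rv.simulate_beats_ipfm(card, train, duration, seed=0)
        expected = np.arange(1, int(hr_bpm / 60 * duration) + 1) * (60 / hr_bpm)
        assert beats.times.size == expected.size
        np.testing.assert_allclose(beats.times, expected, atol=1e-9)

    def test_matches_fine_grid_integration_oracle(self):
        """Beat times agree with an independent fine-step integration of
        the same modulated rate to < 1 ms."""
        card = rv.CardiacParams(base_hr=500.0, resp_mod_depth=13.2, gain=1.0,
                                hr_noise_sd=0.0)
        train = _steady_train(period=0.48, duration=12.0)
        beats = rv.simulate_beats_ipfm(card, train, 10.0, seed=0)

        # oracle: brute-force integration on a 50 kHz grid
        dt = 2e-5
        t = np.arange(0.0, 10.0 + dt / 2, dt)
        m = card.base_hr + card.gain * card.resp_mod_depth * \
            respiratory_waveform(train, t)
        integral = np.concatenate(
            ([0.0], np.cumsum((m[:-1] + m[1:]) * dt / 120.0)))
        oracle = np.interp(np.arange(1, int(integral[-1]) + 1), integral, t)
        assert beats.times.size == oracle.size
        assert np.max(np.abs(beats.times - oracle)) < 1e-3

    def test_beat_count_tracks_rate_integral(self):
        card = rv.CardiacParams(base_hr=480.0, resp_mod_depth=20.0,
                                hr_noise_sd=0.0)
        train = _steady_train(duration=35.0)
        beats = rv.simulate_beats_ipfm(card, train, 30.0, seed=0)
        # modulation is zero-mean per cycle: integral ~ base_hr/60 * T
        assert abs(beats.times.size - 480.0 / 60 * 30.0) <= 1.0

    def test_rate_driven_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rv.CardiacParams(base_hr=5.0, resp_mod_depth=20.0, gain=1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(hr=st.floats(min_value=60.0, max_value=800.0))
    def test_constant_rate_intervals_are_exact(self, hr):
        card = rv.CardiacParams(base_hr=hr, resp_mod_depth=0.0,
                                hr_noise_sd=0.0)
        train = _steady_train(duration=6.0)
        beats = rv.simulate_beats_ipfm(card, train, 5.0, seed=0)
        if beats.times.size > 1:
            np.testing.assert_allclose(beats.intervals, 60.0 / hr, atol=1e-9)

    def test_modulation_waveform_is_zero_mean_unit_range(self):
        train = _steady_train(period=0.48, fi=0.33, duration=2.0)
        u = np.linspace(0.0, 0.48, 4801)[:-1]
        s = respiratory_waveform(train, u)
        assert abs(s.mean()) < 1e-6
        assert np.isclose(s.max() - s.min(), 1.0, atol=1e-4)
        # peak sits mid-inspiration
        assert np.isclose(u[np.argmax(s)], 0.33 * 0.48 / 2, atol=0.01)


class TestChannels:
    def test_ecg_peak_at_beat_time(self):
        beats = rv.EventSeries(np.array([1.0]))
        sig = rv.synthesize_ecg(beats, 2.0, 1000.0, noise_sd=0.0)
        t_max = sig.times[np.argmax(sig.values)]
        assert abs(t_max - 1.0) <= 0.5 / sig.rate + 1e-12

    def test_ecg_empty_beats_is_baseline(self):
        sig = rv.synthesize_ecg(rv.EventSeries(np.empty(0)), 1.0, 1000.0,
                                noise_sd=0.0)
        assert np.all(sig.values == 0.0)

    def test_ecg_overlapping_templates_rejected(self):
        beats = rv.EventSeries(np.array([1.0, 1.005]))
        with pytest.raises(ValueError):
            rv.synthesize_ecg(beats, 2.0, 1000.0)

    def test_ecg_rate_floor(self):
        with pytest.raises(ValueError):
            rv.synthesize_ecg(rv.EventSeries(np.array([1.0])), 2.0, 500.0)

    def test_pleth_peaks_at_end_inspiration(self):
        train = _steady_train(period=0.5, duration=10.0)
        sig = rv.synthesize_pleth(train, 10.0, 2000.0, noise_sd=0.0)
        for ei in train.end_inspirations[:5]:
            i0 = max(0, int((ei - 0.2) * sig.rate))
            i1 = int((ei + 0.2) * sig.rate)
            t_peak = sig.times[i0 + np.argmax(sig.values[i0:i1])]
            assert abs(t_peak - ei) <= 1.0 / sig.rate + 1e-12

    def test_pleth_constant_amplitude_constant_peaks(self):
        resp = rv.RespParams(amplitude_cv=0.0, frequency_cv=0.0)
        train = rv.generate_breath_train(resp, 10.0, seed=0)
        sig = rv.synthesize_pleth(train, 10.0, 2000.0, noise_sd=0.0)
        peaks = [np.max(sig.values[int(a * 2000):int(b * 2000)])
                 for a, b in zip(train.onsets, train.ends)]
        np.testing.assert_allclose(peaks, peaks[0], rtol=1e-3)

    def test_nerve_unknown_kind_rejected(self):
        train = _steady_train(duration=5.0)
        with pytest.raises(ValueError, match="unknown nerve kind"):
            rv.synthesize_nerve(train, 5.0, "sciatic")

    def test_phrenic_bursts_span_inspiration(self):
        train = _steady_train(period=0.5, fi=0.4, duration=5.0)
        sig = rv.synthesize_nerve(train, 5.0, "phrenic-like",
                                  burst_amplitude=2.0, noise_sd=0.0)
        mid_insp = train.onsets[2] + 0.1
        mid_exp = train.end_inspirations[2] + 0.1
        assert sig.sample_previous([mid_insp])[0] == pytest.approx(2.0)
        assert sig.sample_previous([mid_exp])[0] == pytest.approx(0.0)

    def test_vagal_modulation_mean_preserved(self):
        train = _steady_train(duration=20.0)
        sig = rv.synthesize_nerve(train, 20.0, "cardiac-vagal-like",
                                  tonic_level=2.0, mod_fraction=0.5,
                                  noise_sd=0.0)
        assert np.isclose(sig.values.mean(), 2.0, rtol=1e-2)
        assert np.isclose(np.ptp(sig.values), 2.0 * 0.5, rtol=1e-2)


class TestBuildSession:
    def test_gain_schedule_sets_ground_truth_depths(self):
        sched = rv.photostim_schedule(gain=1.5, mhr_shift=-35.0)
        _, truth = rv.build_session(sched, channels=(), seed=0)
        d = rv.CardiacParams().resp_mod_depth
        assert truth.true_resphrv["baseline"] == pytest.approx(d)
        assert truth.true_resphrv["stim"] == pytest.approx(1.5 * d)
        assert truth.true_resphrv["recovery"] == pytest.approx(d)
        assert truth.true_mhr["stim"] == pytest.approx(
            truth.true_mhr["baseline"] - 35.0)

    def test_unknown_override_rejected(self):
        sched = rv.EpochSchedule((
            rv.Epoch("a", 0.0, 10.0, {"not_a_param": 1.0}),))
        with pytest.raises(ValueError, match="unknown parameter override"):
            rv.build_session(sched, channels=(), seed=0)

    def test_session_bit_reproducible(self):
        sched = rv.photostim_schedule(pre=20, stim=20, post=20)
        rec1, _ = rv.build_session(sched, seed=5)
        rec2, _ = rv.build_session(sched, seed=5)
        assert np.array_equal(rec1.beats.times, rec2.beats.times)
        for name in rec1.channels:
            assert np.array_equal(rec1.channels[name].values,
                                  rec2.channels[name].values)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rv.EpochSchedule((rv.Epoch("a", 0.0, 10.0),
                              rv.Epoch("b", 5.0, 15.0)))
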