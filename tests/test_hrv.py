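"""Triggered-averaging core: instantaneous HR, RespHRV amplitude,
epoch metrics, stability profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resphrv as rv
from resphrv.hrv import CycleShortfallError


def _steady_train(period=0.5, fi=0.4, duration=60.0, t0=0.0):
    n = int(np.ceil(duration / period))
    on = t0 + np.arange(n) * period
    return rv.BreathTrain(on, on + fi * period, on + period, np.ones(n))


class TestInstantaneousHR:
    @pytest.mark.parametrize("rr, hr", [(0.1, 600.0), (1.0, 60.0)])
    def test_constant_rr(self, rr, hr):
        beats = rv.EventSeries(np.arange(0, 10, rr) + rr)
        sig = rv.instantaneous_hr(beats)
        assert np.allclose(sig.values, hr)
        assert sig.units == "bpm"

    def test_alternating_rr_plateaus_and_time_average(self):
        rrs = np.tile([0.10, 0.12], 50)
        beats = rv.EventSeries(np.concatenate(([0.0], np.cumsum(rrs))))
        sig = rv.instantaneous_hr(beats, out_rate=1000.0)
        assert set(np.round(np.unique(sig.values), 6)) == {500.0, 600.0}
        # oracle: direct sample average over a brute-force step function
        t = sig.times
        idx = np.searchsorted(beats.times, t, "right") - 1
        idx = np.clip(idx, 0, len(beats) - 2)
        oracle = np.mean(60.0 / rrs[idx])
        assert np.isclose(np.mean(sig.values), oracle, rtol=1e-12)
        # and the time average sits at the duration-weighted mean rate
        assert np.isclose(np.mean(sig.values), 60.0 * 100 / rrs.sum(),
                          rtol=0.01)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            rv.instantaneous_hr(rv.EventSeries(np.array([1.0])))


def _step_hr_signal(train, hi=510.0, lo=490.0, rate=1000.0):
    """HR that is `hi` during inspiration and `lo` during expiration."""
    t = np.arange(0.0, train.ends[-1], 1 / rate)
    i = np.clip(np.searchsorted(train.onsets, t, "right") - 1, 0,
                train.n_cycles - 1)
    insp = t < train.end_inspirations[i]
    return rv.SampledSignal(np.where(insp, hi, lo), rate, 0.0, "bpm")


class TestTriggeredAverage:
    def test_constant_hr_flat_bins(self):
        train = _steady_train()
        sig = rv.SampledSignal(np.full(60000, 500.0), 1000.0, 0.0, "bpm")
        ta = rv.triggered_average(sig, train, min_cycles=40)
        assert np.allclose(ta.mean_hr, 500.0)
        assert rv.resphrv_amplitude(ta) == pytest.approx(0.0, abs=1e-9)

    def test_step_modulation_hits_exact_extrema(self):
        train = _steady_train(period=0.5, fi=0.4)
        sig = _step_hr_signal(train)
        ta = rv.triggered_average(sig, train, min_cycles=40)
        assert np.max(ta.mean_hr) == pytest.approx(510.0)
        assert np.min(ta.mean_hr) == pytest.approx(490.0)
        assert rv.resphrv_amplitude(ta, deconvolve=False) == pytest.approx(20.0)

    def test_cycle_shortfall_refused_with_counts(self):
        train = _steady_train(duration=5.0)
        sig = rv.SampledSignal(np.full(5000, 500.0), 1000.0, 0.0, "bpm")
        with pytest.raises(CycleShortfallError, match=r"requires at least 40"):
            rv.triggered_average(sig, train, min_cycles=40)

    def test_depth_recovery_on_noisy_generator_output(self):
        """Depth 13.2 bpm, ~60 averaged cycles, default noise: ± 5%."""
        resp = rv.RespParams()
        train = rv.generate_breath_train(resp, 30.0, seed=3)
        beats = rv.simulate_beats_ipfm(rv.CardiacParams(), train, 30.0, seed=3)
        hr = rv.instantaneous_hr(beats)
        ta = rv.triggered_average(hr, train, min_cycles=40)
        assert ta.n_cycles >= 55
        assert rv.resphrv_amplitude(ta) == pytest.approx(13.2, rel=0.05)

    def test_time_shift_invariance(self):
        train = _steady_train(duration=40.0)
        rng = np.random.default_rng(4)
        vals = 500.0 + rng.normal(0, 5, 40000)
        sig = rv.SampledSignal(vals, 1000.0, 0.0, "bpm")
        ta0 = rv.triggered_average(sig, train, min_cycles=40)
        shift = 123.456
        train_s = rv.BreathTrain(train.onsets + shift,
                                 train.end_inspirations + shift,
                                 train.ends + shift, train.amplitudes)
        sig_s = rv.SampledSignal(vals, 1000.0, shift, "bpm")
        ta1 = rv.triggered_average(sig_s, train_s, min_cycles=40)
        np.testing.assert_allclose(ta1.mean_hr, ta0.mean_hr, atol=1e-9)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(offset=st.floats(-100, 100), scale=st.floats(0.2, 5.0))
    def test_amplitude_affine_equivariance(self, offset, scale):
        """Adding a constant leaves the raw amplitude unchanged;
        rescaling HR rescales it linearly. (The de-smeared estimate is
        deliberately not scale-equivariant: its correction depends on
        the physical beat interval.)"""
        train = _steady_train(duration=40.0)
        rng = np.random.default_rng(8)
        vals = 500.0 + rng.normal(0, 5, 40000)
        base = rv.SampledSignal(vals, 1000.0, 0.0, "bpm")
        moved = rv.SampledSignal(vals * scale + offset, 1000.0, 0.0, "bpm")
        a0 = rv.resphrv_amplitude(rv.triggered_average(base, train,
                                                       min_cycles=40),
                                  deconvolve=False)
        a1 = rv.resphrv_amplitude(rv.triggered_average(moved, train,
                                                       min_cycles=40),
                                  deconvolve=False)
        assert a1 == pytest.approx(a0 * scale, rel=1e-6)

    def test_noiseless_amplitude_converges_to_true_depth(self):
        """≥ 200 cycles, noiseless: bias below 2%."""
        resp = rv.RespParams()
        train = rv.generate_breath_train(resp, 100.0, seed=6)
        card = rv.CardiacParams(hr_noise_sd=0.0)
        beats = rv.simulate_beats_ipfm(card, train, 100.0, seed=6)
        hr = rv.instantaneous_hr(beats)
        ta = rv.triggered_average(hr, train, min_cycles=200)
        assert rv.resphrv_amplitude(ta) == pytest.approx(13.2, rel=0.02)


class TestEpochMetrics:
    def test_constant_rate_epoch(self):
        beats = rv.EventSeries(np.arange(0.1, 60.01, 0.1))
        train = _steady_train(period=0.48, duration=60.0)
        m = rv.epoch_metrics(beats, train, (0.0, 60.0), "freely_moving")
        assert m.mhr == pytest.approx(600.0, rel=1e-6)
        assert m.resp_frequency == pytest.approx(125.0)

    def test_resp_frequency_counts_onsets(self):
        beats = rv.EventSeries(np.arange(0.1, 60.01, 0.1))
        resp = rv.RespParams(base_frequency=125, frequency_cv=0.0)
        train = rv.generate_breath_train(resp, 60.0, seed=0)
        m = rv.epoch_metrics(beats, train, (0.0, 60.0), "freely_moving")
        assert m.resp_frequency == pytest.approx(125.0)

    def test_mhr_matches_rate_time_average(self):
        """mHR of IPFM output tracks the time average of m(t) within 1%."""
        resp = rv.RespParams()
        train = rv.generate_breath_train(resp, 40.0, seed=12)
        card = rv.CardiacParams(hr_noise_sd=0.0)
        beats = rv.simulate_beats_ipfm(card, train, 40.0, seed=12)
        m = rv.epoch_metrics(beats, train, (0.0, 40.0), "freely_moving")
        assert m.mhr == pytest.approx(card.base_hr, rel=0.01)

    def test_policy_shortfall_propagates(self):
        beats = rv.EventSeries(np.arange(0.1, 10.01, 0.1))
        train = _steady_train(duration=10.0)
        with pytest.raises(CycleShortfallError):
            rv.epoch_metrics(beats, train, (0.0, 10.0), "freely_moving")

    def test_unknown_policy_rejected(self):
        beats = rv.EventSeries(np.arange(0.1, 30.01, 0.1))
        train = _steady_train(duration=30.0)
        with pytest.raises(ValueError, match="unknown condition policy"):
            rv.epoch_metrics(beats, train, (0.0, 30.0), "hibernating")

    def test_session_metrics_match_ground_truth(self, freely_moving_session):
        recording, truth = freely_moving_session
        beats = rv.detect_beats(recording.channels["ecg"])
        breaths = rv.segment_breaths(recording.channels["pleth"])
        for label in ("baseline", "stim"):
            ep = recording.schedule[label]
            m = rv.epoch_metrics(beats, breaths, (ep.end - 30.0, ep.end),
                                 "freely_moving", label=label)
            assert m.mhr == pytest.approx(truth.true_mhr[label], rel=0.01)
            assert m.resphrv_amplitude == pytest.approx(
                truth.true_resphrv[label], rel=0.08)


class TestStabilityProfile:
    def test_stationary_recording_is_stable(self):
        resp = rv.RespParams()
        train = rv.generate_breath_train(resp, 120.0, seed=2)
        beats = rv.simulate_beats_ipfm(rv.CardiacParams(), train, 120.0,
                                       seed=2)
        hr = rv.instantaneous_hr(beats)
        prof = rv.stability_profile(hr, train, window=30.0, step=10.0,
                                    min_cycles=40)
        assert prof.cv < 0.10
        assert prof.stable

    def test_gain_step_shows_two_plateaus(self):
        sched = rv.EpochSchedule((
            rv.Epoch("lo", 0.0, 60.0),
            rv.Epoch("hi", 60.0, 120.0, {"gain": 2.0})))
        rec, _ = rv.build_session(sched, channels=(), seed=4)
        hr = rv.instantaneous_hr(rec.beats)
        prof = rv.stability_profile(hr, rec.breaths, window=30.0, step=30.0,
                                    min_cycles=40)
        first, last = prof.amplitudes[0], prof.amplitudes[-1]
        assert last / first == pytest.approx(2.0, rel=0.15)

    def test_constant_hr_all_windows_zero(self):
        train = _steady_train(duration=90.0)
        sig = rv.SampledSignal(np.full(90000, 480.0), 1000.0, 0.0, "bpm")
        prof = rv.stability_profile(sig, train, window=30.0, step=15.0,
                                    min_cycles=40)
        np.testing.assert_allclose(prof.amplitudes, 0.0, atol=1e-9)

    def test_window_longer_than_recording_rejected(self):
        train = _steady_train(duration=20.0)
        sig = rv.SampledSignal(np.full(20000, 480.0), 1000.0, 0.0, "bpm")
        with pytest.raises(ValueError):
            rv.stability_profile(sig, train, window=60.0, step=10.0)
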