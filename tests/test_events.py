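import numpy as np
import pytest

from neoquant import events, preprocess, synthgen


class TestRmsEnvelope:
    def test_constant_signal_gives_constant_envelope(self):
        env = events.rms_envelope(np.full(5000, -3.0), 1000.0)
        assert np.allclose(env, 3.0)

    def test_unit_sinusoid_envelope_is_rms_of_sine(self):
        fs = 1000.0
        t = np.arange(int(fs * 10)) / fs
        x = np.sin(2 * np.pi * 20 * t)
        env = events.rms_envelope(x, fs, window_ms=200)  # 4 whole periods
        core = env[1000:-1000]
        assert np.allclose(core, 1 / np.sqrt(2), rtol=0.01)

    def test_amplitude_doubling_doubles_envelope(self, rng):
        fs = 1000.0
        x = np.sin(2 * np.pi * 15 * np.arange(10_000) / fs)
        x2 = x.copy()
        x2[4000:6000] *= 2
        e1 = events.rms_envelope(x, fs)
        e2 = events.rms_envelope(x2, fs)
        assert np.allclose(e2[4500:5500], 2 * e1[4500:5500], rtol=0.02)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            events.rms_envelope(np.ones(100), 1000.0, window_ms=500)


class TestThresholdFit:
    def test_gaussian_noise_threshold_matches_moment_oracle(self, rng):
        # envelope of white noise is approximately Gaussian; the fitted
        # mu + k*sigma must agree with moments estimated from the mode side
        env = events.rms_envelope(rng.standard_normal(200_000), 1000.0)
        k = 2.0
        thr = events.fit_rms_threshold(env, k=k)
        mode = np.median(env)  # symmetric-enough: mode ~ median
        left = env[env <= mode]
        sigma_hat = np.sqrt(np.mean((left - mode) ** 2))
        oracle = mode + k * sigma_hat
        assert abs(thr - oracle) / oracle < 0.10

    def test_bimodal_envelope_threshold_separates_modes(self, rng):
        silence = rng.normal(1.0, 0.1, 50_000)
        active = rng.normal(5.0, 0.5, 5_000)
        env = np.abs(np.concatenate([silence, active]))
        for k in (1.0, 2.0, 3.0):
            thr = events.fit_rms_threshold(env, k=k)
            # strictly between the silence and event modes, clear of the
            # silence bulk (mu + k*sigma with sigma ~ 0.1)
            assert 1.0 + 0.05 * k < thr < 4.5

    def test_k_zero_returns_fitted_mean(self, rng):
        env = np.abs(rng.normal(3.0, 0.3, 100_000))
        thr = events.fit_rms_threshold(env, k=0.0)
        assert abs(thr - 3.0) < 0.15

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError):
            events.fit_rms_threshold(np.full(1000, 2.0))


class TestDetectOscillations:
    def _noise_bursts(self, burst_spec, fs=1000.0, dur=60.0, seed=0):
        """Gaussian noise with 15 Hz bursts at given (start, stop, amp)."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(fs * dur))
        t = np.arange(x.size) / fs
        for t0, t1, amp in burst_spec:
            sel = (t >= t0) & (t < t1)
            x[sel] += amp * np.sin(2 * np.pi * 15 * t[sel])
        return x

    def test_subthreshold_noise_yields_no_events(self, rng):
        x = rng.standard_normal(60_000)
        det = events.detect_oscillations(x, 1000.0)
        assert det == []

    def test_bursts_within_200ms_are_merged(self):
        x = self._noise_bursts([(10, 11.2, 15), (11.3, 12.5, 15)])
        det = events.detect_oscillations(x, 1000.0)
        assert len(det) == 1
        assert det[0].start_s < 10.5 and det[0].stop_s > 12.0

    def test_sub_second_burst_excluded(self):
        x = self._noise_bursts([(10, 10.8, 15)])
        det = events.detect_oscillations(x, 1000.0)
        assert det == []

    def test_detected_events_satisfy_type_invariants(self, rng):
        # fuzz: arbitrary noisy signals never yield invalid events
        for seed in range(5):
            x = self._noise_bursts(
                [(5, 7, 10), (20, 23, 20), (40, 41.5, 12)], seed=seed
            )
            det = events.detect_oscillations(x, 1000.0)
            for a, b in zip(det, det[1:]):
                assert b.start_s - a.stop_s >= events.MERGE_GAP_S
            for e in det:
                assert e.duration_s > 1.0
                assert e.peak_amplitude > 0

    def test_raising_k_never_increases_event_count(self):
        x = self._noise_bursts([(5, 7, 8), (20, 23, 4), (40, 42, 2)])
        counts = [
            len(events.detect_oscillations(x, 1000.0, k=k))
            for k in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRecoveryOnSyntheticRecordings:
    def test_default_snr_sensitivity_precision_and_boundaries(
        self, short_recording
    ):
        rec, truth = short_recording
        x = preprocess.bandpass(rec.samples[0], rec.fs, 1.0, 100.0)
        det = events.detect_oscillations(x, rec.fs)
        scores = events.match_events(
            det, [(e.start_s, e.stop_s) for e in truth.events]
        )
        assert scores["sensitivity"] >= 0.9
        assert scores["precision"] >= 0.9
        assert scores["mean_boundary_error_s"] < 0.1

    def test_event_rate_zero_gives_stationary_noise(self):
        spec = synthgen.CohortSpec(duration_s=120.0)
        rec, truth = synthgen.gen_recording(spec, event_rate_per_min=0, seed=1)
        assert len(truth) == 0

    def test_summary_occurrence_matches_planted_rate(self, short_recording):
        rec, truth = short_recording
        x = preprocess.bandpass(rec.samples[0], rec.fs, 1.0, 100.0)
        det = events.detect_oscillations(x, rec.fs)
        s = events.summarize_events(det, rec.duration_s)
        assert abs(s["occurrence_per_min"] - 4.0) / 4.0 <= 0.1


class TestSummaries:
    def test_occurrence_is_count_per_minute(self):
        from neoquant.core import OscillationEvent

        evs = [
            OscillationEvent("ch0", i * 10.0, i * 10.0 + 1.5, 10.0, 5.0)
            for i in range(8)
        ]
        s = events.summarize_events(evs, 120.0)
        assert s["occurrence_per_min"] == pytest.approx(4.0)
        assert s["mean_duration_s"] == pytest.approx(1.5)
        assert s["active_fraction"] == pytest.approx(8 * 1.5 / 120.0)

    def test_empty_event_list_flags_absent_means(self):
        s = events.summarize_events([], 60.0)
        assert s["occurrence_per_min"] == 0.0
        assert s["mean_duration_s"] is None
        assert s["mean_amplitude_uv"] is None
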