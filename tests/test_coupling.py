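import numpy as np
import pytest

from neoquant import coupling, synthgen
from neoquant.core import EventTruth, SpikeSeries, TruthEvent


class TestBandPhase:
    def test_phase_advances_linearly_at_carrier_frequency(self):
        fs, f0 = 1000.0, 21.0
        t = np.arange(int(fs * 10)) / fs
        x = np.cos(2 * np.pi * f0 * t)
        phi = np.unwrap(coupling.band_phase(x, fs, (12, 30)))
        slope = np.polyfit(t[1000:-1000], phi[1000:-1000], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f0, rel=0.01)

    def test_phase_zero_at_signal_maxima(self):
        fs = 1000.0
        t = np.arange(int(fs * 10)) / fs
        x = np.cos(2 * np.pi * 20 * t)
        phi = coupling.band_phase(x, fs, (12, 30))
        peaks = np.flatnonzero(
            (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
        ) + 1
        assert np.max(np.abs(phi[peaks[5:-5]])) < 0.1

    def test_shifted_cosine_constant_phase_offset(self):
        fs, f0 = 1000.0, 20.0
        t = np.arange(int(fs * 10)) / fs
        shift = np.pi / 3
        a = coupling.band_phase(np.cos(2 * np.pi * f0 * t), fs, (12, 30))
        b = coupling.band_phase(
            np.cos(2 * np.pi * f0 * t - shift), fs, (12, 30)
        )
        d = np.angle(np.exp(1j * (a - b)))[1000:-1000]
        assert np.allclose(d, shift, atol=0.02)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            coupling.band_phase(np.zeros(1000), 100.0, (30, 60))


class TestPpc:
    def test_identical_phases_give_one(self):
        assert coupling.ppc(np.full(10, 1.3)) == pytest.approx(1.0)

    def test_antipodal_pair_gives_minus_one(self):
        assert coupling.ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [3, 4, 7, 12])
    def test_equally_spaced_phases_give_minus_one_over_n_minus_1(self, n):
        phases = np.linspace(0, 2 * np.pi, n, endpoint=False)
        assert coupling.ppc(phases) == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_closed_form_equals_pairwise_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 2000))
            ph = rng.uniform(-np.pi, np.pi, n)
            assert coupling.ppc(ph) == pytest.approx(
                coupling.ppc_pairwise(ph), abs=1e-10
            )

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0, 4.0])
    def test_von_mises_samples_recover_analytic_ppc(self, kappa):
        # average independent n=2000 estimates so the Monte-Carlo error of
        # the check itself is well below the 0.02 band
        estimates = [
            coupling.ppc(
                synthgen.vonmises_phases(kappa, 2000, seed=100 * int(kappa) + d)
            )
            for d in range(10)
        ]
        assert np.mean(estimates) == pytest.approx(
            coupling.vonmises_ppc(kappa), abs=0.02
        )

    def test_subsampling_is_unbiased(self, rng):
        ph = synthgen.vonmises_phases(2.0, 2000, seed=9)
        full = coupling.ppc(ph)
        subs = [
            coupling.ppc(rng.choice(ph, 200, replace=False))
            for _ in range(200)
        ]
        se = np.std(subs) / np.sqrt(len(subs))
        assert abs(np.mean(subs) - full) < 2 * se + 1e-3

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            coupling.ppc(np.array([0.5]))


class TestSpikeTriggeredPower:
    def test_random_spikes_on_stationary_noise_give_zero(self, rng):
        fs, dur = 1000.0, 120.0
        x = rng.standard_normal(int(fs * dur))
        spk = SpikeSeries(np.sort(rng.uniform(1, dur - 1, 500)), dur)
        res = coupling.spike_triggered_relative_power(x, fs, spk)
        assert abs(res.st_rel_power.mean()) < 0.1

    def test_tone_bursts_around_spikes_peak_at_carrier(self, rng):
        fs, dur = 1000.0, 120.0
        x = rng.standard_normal(int(fs * dur)) * 0.5
        times = np.arange(1.0, dur - 1.0, 0.6)
        for s in times:
            i = int(s * fs)
            tt = np.arange(200) / fs
            x[i - 100 : i + 100] += 2 * np.sin(2 * np.pi * 20 * tt) * np.hanning(200)
        spk = SpikeSeries(times, dur)
        res = coupling.spike_triggered_relative_power(x, fs, spk)
        assert res.frequencies[np.argmax(res.st_rel_power)] == pytest.approx(20.0)
        assert res.band_summary("beta") > res.band_summary("gamma")

    def test_locked_beats_jittered(self, rng):
        fs, dur = 1000.0, 240.0
        x = rng.standard_normal(int(fs * dur))
        times = np.arange(1.0, dur - 1.0, 0.6)
        for s in times:
            i = int(s * fs)
            tt = np.arange(300) / fs
            x[i - 150 : i + 150] += 2 * np.sin(2 * np.pi * 20 * tt) * np.hanning(300)
        locked = SpikeSeries(times, dur)
        jittered = SpikeSeries(
            np.sort(
                np.clip(times + rng.uniform(-0.1, 0.1, times.size), 1, dur - 1)
            ),
            dur,
        )
        rl = coupling.spike_triggered_relative_power(x, fs, locked)
        rj = coupling.spike_triggered_relative_power(x, fs, jittered)
        assert rl.band_summary("beta") > rj.band_summary("beta")

    def test_spikes_without_complete_windows_are_skipped(self, rng):
        fs, dur = 1000.0, 10.0
        x = rng.standard_normal(int(fs * dur))
        spk = SpikeSeries(np.array([0.05, 5.0, 9.99]), dur)
        res = coupling.spike_triggered_relative_power(x, fs, spk)
        assert res.n_spikes == 1 and res.n_skipped == 2

    def test_no_valid_spike_rejected(self, rng):
        x = rng.standard_normal(1000)
        spk = SpikeSeries(np.array([0.01]), 1.0)
        with pytest.raises(ValueError):
            coupling.spike_triggered_relative_power(x, 1000.0, spk)


class TestGeneratedLocking:
    def test_locked_spiketrain_ppc_matches_kappa(self, short_recording):
        rec, truth = short_recording
        kappa = 2.0
        spk = synthgen.gen_spiketrain(
            truth, 0.5, kappa, rec.duration_s, fs=rec.fs,
            lfp=rec.samples[0], band="beta", seed=21,
        )
        # the von Mises law holds for spikes emitted during oscillatory
        # events (outside them there is no carrier to lock to)
        in_event = np.zeros(spk.n_spikes, dtype=bool)
        for e in truth.events:
            in_event |= (spk.times_s >= e.start_s) & (spk.times_s < e.stop_s)
        from neoquant.core import SpikeSeries
        locked = SpikeSeries(spk.times_s[in_event], spk.duration_s)
        phases = coupling.phases_at_spikes(
            rec.samples[0], rec.fs, locked, (15, 40)
        )
        # thinning acceptance follows the von Mises density; the empirical
        # PPC converges to the analytic value within sampling error
        assert coupling.ppc(phases) == pytest.approx(
            coupling.vonmises_ppc(kappa), abs=0.08
        )

    def test_kappa_zero_spiketrain_is_unlocked(self, short_recording):
        rec, truth = short_recording
        spk = synthgen.gen_spiketrain(
            truth, 0.7, 0.0, rec.duration_s, fs=rec.fs,
            lfp=rec.samples[0], band="beta", seed=2,
        )
        phases = coupling.phases_at_spikes(
            rec.samples[0], rec.fs, spk, (15, 40)
        )
        assert abs(coupling.ppc(phases)) < 0.02

    def test_uniform_phases_give_near_zero_ppc_at_large_n(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 5000)
        assert abs(coupling.ppc(ph)) < 0.01

    def test_event_locked_mode_requires_events(self):
        with pytest.raises(ValueError):
            synthgen.gen_spiketrain(
                EventTruth(events=[]), 0.0, 2.0, 60.0,
                lfp=np.zeros(60_000), band="beta", seed=0,
            )
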