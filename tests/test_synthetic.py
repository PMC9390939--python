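"""Generator contracts: annotation bookkeeping, spectral content, mixing."""

import numpy as np
import pytest
from scipy.signal import hilbert, periodogram, welch

from fpcgbench import synthetic as syn


def _spectral_peak(segment, fs=1000.0, nfft=2 ** 16):
    f, p = periodogram(segment, fs=fs, nfft=nfft)
    return f[np.argmax(p)]


class TestHeartSoundTrains:
    def test_fetal_event_count_and_spacing(self):
        ref = syn.generate_fetal_pcg(duration_s=300.0, fs=1000.0, seed=0)
        s1 = ref.event_times("S1")
        assert len(s1) == 700  # 300 s * 140 bpm / 60
        assert np.allclose(np.diff(s1), 60.0 / 140.0, atol=1e-9)
        s2 = ref.event_times("S2")
        assert np.allclose(s2 - s1, 0.140, atol=1e-9)

    def test_labels_alternate_and_times_increase(self, fetal_60s):
        labels = [lab for _, lab in fetal_60s.events]
        assert labels == ["S1", "S2"] * (len(labels) // 2)
        times = fetal_60s.event_times()
        assert np.all(np.diff(times) > 0)
        assert times[0] >= 0 and times[-1] <= fetal_60s.duration_s

    def test_zero_duration_is_empty(self):
        ref = syn.generate_fetal_pcg(duration_s=0.0, fs=1000.0, seed=0)
        assert len(ref.samples) == 0 and ref.events == []

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="4x-carrier"):
            syn.generate_fetal_pcg(duration_s=1.0, fs=150.0, seed=0)
        with pytest.raises(ValueError):
            syn.generate_fetal_pcg(duration_s=1.0, fs=-1.0, seed=0)

    @pytest.mark.parametrize("label,expected,half_win", [
        ("S1", 36.89, 0.100), ("S2", 55.18, 0.100)])
    def test_fetal_carrier_frequencies(self, fetal_60s, label, expected,
                                       half_win):
        """An isolated sound's zero-padded spectrum peaks at its carrier."""
        t0 = fetal_60s.event_times(label)[10]
        lo, hi = int((t0 - half_win) * 1000), int((t0 + half_win) * 1000)
        peak = _spectral_peak(fetal_60s.samples[lo:hi])
        assert abs(peak - expected) < 0.25

    def test_fetal_amplitude_ratio(self, fetal_60s):
        env = np.abs(hilbert(fetal_60s.samples))
        a1 = np.median(env[(fetal_60s.event_times("S1") * 1000).astype(int)])
        a2 = np.median(env[(fetal_60s.event_times("S2") * 1000).astype(int)])
        assert a1 / a2 == pytest.approx(1.7, rel=0.02)

    def test_maternal_event_count_and_interval(self):
        mat = syn.generate_maternal_hs(duration_s=300.0, fs=1000.0, seed=0)
        s1 = mat.event_times("S1")
        assert len(s1) == 350  # 300 s * 70 bpm / 60
        gaps = mat.event_times("S2") - s1
        assert np.allclose(gaps, 0.331, atol=1e-9)

    def test_maternal_band_power(self, maternal_60s):
        """Maternal interference lives in the 10-40 Hz band."""
        f, p = periodogram(maternal_60s.samples, fs=1000.0)
        in_band = p[(f >= 10) & (f <= 40)].sum()
        assert in_band / p.sum() > 0.95

    def test_maternal_ratio_and_carrier(self, maternal_60s):
        env = np.abs(hilbert(maternal_60s.samples))
        s1_idx = (maternal_60s.event_times("S1") * 1000).astype(int)
        s2_idx = (maternal_60s.event_times("S2") * 1000).astype(int)
        ratio = np.median(env[s1_idx]) / np.median(env[s2_idx])
        assert ratio == pytest.approx(1.54, rel=0.02)
        t0 = maternal_60s.event_times("S1")[5]
        seg = maternal_60s.samples[int((t0 - 0.2) * 1000):
                                   int((t0 + 0.2) * 1000)]
        assert abs(_spectral_peak(seg) - 16.93) < 0.25


class TestNoiseModels:
    def test_movement_pulse_durations_and_determinism(self):
        spec = syn.NoiseSpec("movement", pulses_per_min=8.0)
        a = syn.generate_movement_artifacts(spec, duration_s=60.0,
                                            fs=1000.0, seed=5)
        b = syn.generate_movement_artifacts(spec, duration_s=60.0,
                                            fs=1000.0, seed=5)
        assert np.array_equal(a.samples, b.samples)
        # active stretches correspond to pulses of 0.5-1.5 s
        active = np.r_[0, (np.abs(a.samples) > 1e-12).astype(int), 0]
        edges = np.flatnonzero(np.diff(active))
        runs = (edges[1::2] - edges[::2]) / 1000.0
        assert len(runs) > 0
        assert np.all(runs >= 0.45) and np.all(runs <= 1.6)

    def test_movement_band_limited(self):
        spec = syn.NoiseSpec("movement", pulses_per_min=10.0)
        a = syn.generate_movement_artifacts(spec, duration_s=120.0,
                                            fs=1000.0, seed=3)
        f, p = periodogram(a.samples, fs=1000.0)
        assert p[f > 110].sum() / p.sum() < 0.01

    def test_movement_infeasible_rate_rejected(self):
        spec = syn.NoiseSpec("movement", pulses_per_min=200.0)
        with pytest.raises(ValueError, match="infeasible|non-overlap"):
            syn.generate_movement_artifacts(spec, duration_s=10.0,
                                            fs=1000.0, seed=0)

    def test_gaussian_flat_psd_and_determinism(self):
        a = syn.generate_gaussian_noise(duration_s=120.0, fs=1000.0, seed=9)
        b = syn.generate_gaussian_noise(duration_s=120.0, fs=1000.0, seed=9)
        assert np.array_equal(a.samples, b.samples)
        n = len(a.samples)
        assert abs(a.samples.mean()) < 3.0 / np.sqrt(n)
        f, p = welch(a.samples, fs=1000.0, nperseg=4096)
        low = p[(f > 0) & (f <= 100)].mean()
        high = p[(f > 100) & (f <= 200)].mean()
        assert low / high == pytest.approx(1.0, rel=0.1)

    def test_ambient_highpass_response(self):
        """Measured |H|^2 has -3 dB near 100 Hz and >=30 dB attenuation at
        50 Hz relative to 200 Hz."""
        out = syn.generate_ambient_noise(duration_s=120.0, fs=1000.0, seed=4)
        white = np.random.default_rng(4).standard_normal(120000)
        f, p_in = welch(white, fs=1000.0, nperseg=4096)
        _, p_out = welch(out.samples, fs=1000.0, nperseg=4096)
        ratio = p_out / p_in
        h2_50 = np.interp(50.0, f, ratio)
        h2_200 = np.interp(200.0, f, ratio)
        assert 10 * np.log10(h2_200 / h2_50) >= 30.0
        # -3 dB crossing of the power ratio
        idx = np.argmin(np.abs(ratio[(f > 50) & (f < 150)] - 0.5))
        f3 = f[(f > 50) & (f < 150)][idx]
        assert abs(f3 - 100.0) <= 2.0
        again = syn.generate_ambient_noise(duration_s=120.0, fs=1000.0,
                                           seed=4)
        assert np.array_equal(out.samples, again.samples)


class TestMixing:
    @pytest.mark.parametrize("target", [-0.53, -1.20, -3.56, -10.76, 0.0])
    def test_exact_snr(self, fetal_60s, target):
        noise = syn.generate_gaussian_noise(duration_s=60.0, fs=1000.0,
                                            seed=7)
        mixed = syn.mix_at_snr(fetal_60s, [noise],
                               syn.MixSpec(("gaussian",), target))
        resid = mixed.samples - fetal_60s.samples
        achieved = 10 * np.log10(np.sum(fetal_60s.samples ** 2)
                                 / np.sum(resid ** 2))
        assert abs(achieved - target) < 1e-6
        assert mixed.events == fetal_60s.events

    def test_zero_db_means_equal_power(self, fetal_60s):
        noise = syn.generate_gaussian_noise(duration_s=60.0, fs=1000.0,
                                            seed=7)
        _, scaled = syn.mix_at_snr(fetal_60s, [noise],
                                   syn.MixSpec(("gaussian",), 0.0),
                                   return_components=True)
        assert (np.sum(scaled ** 2)
                == pytest.approx(np.sum(fetal_60s.samples ** 2), rel=1e-9))

    def test_snr_shift_scales_amplitude(self, fetal_60s):
        """Dropping the target by 20 dB scales the noise amplitude x10."""
        noise = syn.generate_gaussian_noise(duration_s=60.0, fs=1000.0,
                                            seed=7)
        _, s0 = syn.mix_at_snr(fetal_60s, [noise],
                               syn.MixSpec(("gaussian",), 0.0),
                               return_components=True)
        _, s20 = syn.mix_at_snr(fetal_60s, [noise],
                                syn.MixSpec(("gaussian",), -20.0),
                                return_components=True)
        assert np.allclose(s20, 10.0 * s0, rtol=1e-9)

    def test_superposition(self, gaussian_mix_60s):
        ref, mixed, scaled = gaussian_mix_60s
        assert np.array_equal(mixed.samples, ref.samples + scaled)

    def test_multi_component_weights(self, fetal_60s):
        noises = [syn.generate_gaussian_noise(duration_s=60.0, fs=1000.0,
                                              seed=7),
                  syn.generate_ambient_noise(duration_s=60.0, fs=1000.0,
                                             seed=8)]
        mix = syn.MixSpec(("gaussian", "ambient"), -1.45)
        mixed = syn.mix_at_snr(fetal_60s, noises, mix)
        resid = mixed.samples - fetal_60s.samples
        achieved = 10 * np.log10(np.sum(fetal_60s.samples ** 2)
                                 / np.sum(resid ** 2))
        assert abs(achieved - (-1.45)) < 1e-6

    def test_degenerate_inputs_rejected(self, fetal_60s):
        silent = fetal_60s.with_samples(np.zeros_like(fetal_60s.samples))
        noise = syn.generate_gaussian_noise(duration_s=60.0, fs=1000.0,
                                            seed=7)
        with pytest.raises(ValueError):
            syn.mix_at_snr(silent, [noise], syn.MixSpec(("gaussian",), 0.0))
        with pytest.raises(ValueError):
            syn.mix_at_snr(fetal_60s, [silent],
                           syn.MixSpec(("gaussian",), 0.0))
        with pytest.raises(ValueError):
            syn.mix_at_snr(fetal_60s, [], syn.MixSpec(("gaussian",), 0.0))
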