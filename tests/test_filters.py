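"""Filter-bank contracts: reconstruction, linearity, determinism, and the
denoising sanity of every algorithm at printed settings."""

import numpy as np
import pytest

from fpcgbench import synthetic as syn
from fpcgbench.evaluation import snr_improvement
from fpcgbench.filters import (FilterConfig, apply_filter, awt_denoise,
                               ceemdan_decompose, eemd_decompose,
                               emd_decompose, fir_bandpass, modwt_denoise,
                               reconstruct_from_imfs, savgol_smooth,
                               vmd_decompose)


@pytest.fixture(scope="module")
def noise_4k():
    return np.random.default_rng(0).standard_normal(4096)


@pytest.fixture(scope="module")
def two_tone():
    t = np.arange(0, 5, 0.001)
    return np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 100 * t)


class TestSavgol:
    def test_polynomial_exactness(self):
        t = np.linspace(0, 1, 200)
        poly = 3 * t ** 2 - t + 0.5
        out = savgol_smooth(poly, 21, 3)
        assert np.allclose(out[30:-30], poly[30:-30], atol=1e-10)

    def test_even_window_rounds_up_and_table_setting_accepted(self,
                                                              noise_4k):
        # window 20 / order 7 is a printed setting; 20 becomes 21
        out = savgol_smooth(noise_4k, 20, 7)
        assert np.array_equal(out, savgol_smooth(noise_4k, 21, 7))

    def test_dc_preserved(self):
        assert np.allclose(savgol_smooth(np.ones(100), 15, 4), 1.0)

    def test_bad_order_rejected(self, noise_4k):
        with pytest.raises(ValueError):
            savgol_smooth(noise_4k, 7, 9)


class TestFIR:
    def test_inband_tone_preserved(self):
        fs = 1000.0
        t = np.arange(8000) / fs
        tone = np.sin(2 * np.pi * 60 * t)
        out = fir_bandpass(tone, 90, (20.0, 110.0), fs)
        assert np.max(np.abs(out[2000:6000])) == pytest.approx(1.0, rel=0.05)
        # group-delay compensation keeps the tone phase-aligned
        assert np.corrcoef(out[2000:6000], tone[2000:6000])[0, 1] > 0.999

    def test_dc_rejected(self):
        out = fir_bandpass(np.ones(4000), 90, (20.0, 110.0), 1000.0)
        assert np.max(np.abs(out[1000:3000])) < 0.01

    def test_linearity(self, noise_4k):
        x = noise_4k
        y = np.random.default_rng(1).standard_normal(len(x))
        fa = fir_bandpass(2 * x + 3 * y, 31, (20.0, 110.0), 1000.0)
        fb = (2 * fir_bandpass(x, 31, (20.0, 110.0), 1000.0)
              + 3 * fir_bandpass(y, 31, (20.0, 110.0), 1000.0))
        assert np.allclose(fa, fb, atol=1e-10)

    def test_bad_band_rejected(self, noise_4k):
        with pytest.raises(ValueError):
            fir_bandpass(noise_4k, 31, (20.0, 600.0), 1000.0)


class TestWaveletDenoisers:
    def test_awt_zero_threshold_reconstructs(self, noise_4k):
        out = awt_denoise(noise_4k, "sym4", 3, threshold_scale=0.0)
        rel = np.linalg.norm(out - noise_4k) / np.linalg.norm(noise_4k)
        assert rel < 1e-8

    def test_modwt_zero_threshold_reconstructs(self, noise_4k):
        out = modwt_denoise(noise_4k, "db5", 4, threshold_scale=0.0)
        rel = np.linalg.norm(out - noise_4k) / np.linalg.norm(noise_4k)
        assert rel < 1e-8

    def test_modwt_circular_shift_equivariance(self, noise_4k):
        y1 = modwt_denoise(noise_4k, "db5", 4)
        y2 = modwt_denoise(np.roll(noise_4k, 64), "db5", 4)
        rel = (np.linalg.norm(np.roll(y1, 64) - y2)
               / np.linalg.norm(y1))
        assert rel < 1e-10

    @pytest.mark.parametrize("fn", [awt_denoise, modwt_denoise])
    def test_unknown_wavelet_rejected(self, fn, noise_4k):
        with pytest.raises(ValueError, match="wavelet"):
            fn(noise_4k, "nosuchwavelet", 3)

    def test_awt_improves_snr_on_noisy_sine(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 4, 0.001)
        clean = np.sin(2 * np.pi * 40 * t)
        noise = rng.standard_normal(len(t))
        noise *= np.sqrt(np.sum(clean ** 2) / np.sum(noise ** 2))  # 0 dB
        out = awt_denoise(clean + noise, "sym4", 3)
        assert snr_improvement(clean, clean + noise, out) > 0


class TestEMDFamily:
    def test_emd_completeness_and_pure_tone(self):
        t = np.arange(0, 3, 0.001)
        tone = np.sin(2 * np.pi * 50 * t)
        s = emd_decompose(tone)
        recon = sum(s.modes) + s.residue
        assert (np.linalg.norm(recon - tone) / np.linalg.norm(tone)) < 1e-6
        assert np.sum(s.modes[0] ** 2) / np.sum(tone ** 2) > 0.99

    def test_emd_two_tone_separation(self, two_tone):
        from scipy.signal import periodogram
        s = emd_decompose(two_tone)
        f, p = periodogram(s.modes[0], fs=1000.0)
        assert abs(f[np.argmax(p)] - 100.0) < 2.0

    def test_emd_constant_input(self):
        s = emd_decompose(np.full(1000, 2.5))
        assert len(s.modes) == 0
        assert np.array_equal(s.residue, np.full(1000, 2.5))

    def test_eemd_seeded_determinism(self, two_tone):
        x = two_tone[:2000]
        a = eemd_decompose(x, n_trials=5, noise_std=0.2, seed=9)
        b = eemd_decompose(x, n_trials=5, noise_std=0.2, seed=9)
        assert all(np.array_equal(u, v) for u, v in zip(a.modes, b.modes))
        assert np.array_equal(a.residue, b.residue)

    def test_eemd_zero_noise_equals_emd(self, two_tone):
        x = two_tone[:2000]
        a = eemd_decompose(x, n_trials=5, noise_std=0.0, seed=9)
        b = emd_decompose(x)
        assert all(np.array_equal(u, v) for u, v in zip(a.modes, b.modes))

    def test_ceemdan_completeness(self, two_tone):
        x = two_tone[:2000]
        s = ceemdan_decompose(x, n_trials=4, noise_std=0.2, seed=3)
        recon = sum(s.modes) + s.residue
        assert (np.linalg.norm(recon - x) / np.linalg.norm(x)) < 1e-6

    def test_ceemdan_zero_noise_equals_emd(self, two_tone):
        x = two_tone[:2000]
        a = ceemdan_decompose(x, n_trials=4, noise_std=0.0, seed=3)
        b = emd_decompose(x)
        assert all(np.array_equal(u, v) for u, v in zip(a.modes, b.modes))

    def test_eemd_per_trial_completeness(self):
        """Each perturbed trial decomposes completely; the ensemble mean
        therefore reconstructs the mean perturbed input."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1500)
        from fpcgbench.emd import emd
        modes, residue = emd(x)
        recon = sum(modes) + residue
        assert (np.linalg.norm(recon - x) / np.linalg.norm(x)) < 1e-6


class TestVMD:
    def test_single_mode_captures_sinusoid(self):
        t = np.arange(0, 3, 0.001)
        tone = np.sin(2 * np.pi * 50 * t)
        s = vmd_decompose(tone, n_modes=1)
        assert np.sum((tone - s.modes[0]) ** 2) / np.sum(tone ** 2) < 0.01

    def test_three_tone_reconstruction(self):
        t = np.arange(0, 3, 0.001)
        x = (np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 60 * t)
             + np.sin(2 * np.pi * 150 * t))
        s = vmd_decompose(x, n_modes=3)
        assert np.sum((x - sum(s.modes)) ** 2) / np.sum(x ** 2) < 0.05

    def test_modes_sorted_by_center_frequency(self):
        from scipy.signal import periodogram
        t = np.arange(0, 3, 0.001)
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 120 * t)
        s = vmd_decompose(x, n_modes=2)
        peaks = []
        for m in s.modes:
            f, p = periodogram(m, fs=1000.0)
            peaks.append(f[np.argmax(p)])
        assert peaks == sorted(peaks)


class TestReconstructAndDispatch:
    def test_selection_sums_exactly(self, two_tone):
        s = emd_decompose(two_tone)
        out = reconstruct_from_imfs(s, (2, 3))
        assert np.array_equal(out, s.modes[1] + s.modes[2])

    def test_all_modes_plus_residue_is_input(self, two_tone):
        s = emd_decompose(two_tone)
        out = reconstruct_from_imfs(s, tuple(range(1, len(s.modes) + 1)),
                                    include_residue=True)
        assert np.allclose(out, two_tone, atol=1e-9)

    def test_bad_selection_rejected(self, two_tone):
        s = emd_decompose(two_tone)
        with pytest.raises(ValueError):
            reconstruct_from_imfs(s, (99,))
        with pytest.raises(ValueError):
            reconstruct_from_imfs(s, ())

    def test_dispatch_matches_direct_call(self, noise_4k):
        cfg = FilterConfig("SG", window_length=20, poly_order=7)
        assert np.array_equal(apply_filter(noise_4k, cfg, 1000.0),
                              savgol_smooth(noise_4k, 20, 7))

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig("WIENER")

    def test_length_preserved_everywhere(self, noise_4k):
        for cfg in (FilterConfig("SG"), FilterConfig("FIR"),
                    FilterConfig("AWT"), FilterConfig("MODWT"),
                    FilterConfig("EMD", imf_selection=(1, 2)),
                    FilterConfig("VMD", imf_selection=(1, 2))):
            out = apply_filter(noise_4k, cfg, 1000.0)
            assert len(out) == len(noise_4k)


@pytest.mark.parametrize("config", [
    FilterConfig("SG", window_length=16, poly_order=6),
    FilterConfig("FIR", filter_order=90),
    FilterConfig("AWT", wavelet="coif5", levels=3),
    FilterConfig("MODWT", wavelet="sym3", levels=4),
    FilterConfig("VMD", imf_selection=(1, 2, 3)),
    FilterConfig("EMD", imf_selection=(3, 4, 5)),
    FilterConfig("EEMD", n_trials=10, noise_std=0.3, imf_selection=(4, 5),
                 seed=0),
    FilterConfig("CEEMDAN", n_trials=10, noise_std=0.5,
                 imf_selection=(2, 3), seed=0),
], ids=lambda c: c.algorithm)
def test_denoising_sanity(config):
    """Every algorithm at a printed setting raises SNR on the fetal
    reference plus Gaussian noise at -3 dB, across 5 seeds."""
    for seed in range(5):
        ref = syn.generate_fetal_pcg(duration_s=5.0, fs=1000.0, seed=seed)
        noise = syn.generate_gaussian_noise(duration_s=5.0, fs=1000.0,
                                            seed=100 + seed)
        noisy = syn.mix_at_snr(ref, [noise], syn.MixSpec(("gaussian",), -3.0))
        filtered = apply_filter(noisy.samples, config, 1000.0)
        assert snr_improvement(ref.samples, noisy.samples, filtered) > 0
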