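# fpcgbench

Benchmarking single-channel denoising for **fetal phonocardiography
(fPCG)** — acoustic recordings of fetal heart sounds taken from the
maternal abdomen. fPCG is passive, cheap and suitable for long-term home
monitoring, but the useful signal (the first and second fetal heart
sounds, S1 and S2) is buried under maternal heart sounds, movement
artifacts, broadband ambient noise and Gaussian-like physiological noise.
Choosing a filtering algorithm therefore requires a controlled benchmark
with a known ground truth, which only synthetic signals can provide.

`fpcgbench` is that benchmark as a reusable library and CLI, aimed at
biomedical-signal researchers comparing denoisers:

- **Synthetic signals with ground truth.** Fetal heart sounds are
  Gaussian-modulated sinusoids, `s(t) = A exp(-(t-t0)^2 / 2σ²) sin(2πf
  (t-t0))`, at 140 bpm with S1 at 36.89 Hz, S2 at 55.18 Hz, S1/S2
  amplitude ratio 1.7 and 140 ms S1→S2 spacing; maternal sounds use 70
  bpm, 16.93/30.44 Hz, ratio 1.54, 331 ms spacing. Four interference
  models (maternal sounds, 0.5–1.5 s movement pulses, white Gaussian
  noise, 100 Hz-high-passed ambient noise) are mixed onto the reference at
  an exact target SNR.
- **Eight denoisers** behind one interface: Savitzky–Golay, FIR band-pass
  (20–110 Hz), adaptive wavelet thresholding (AWT), undecimated-wavelet
  thresholding (MODWT), and four mode decompositions — VMD, EMD, EEMD and
  CEEMDAN — where the filtered signal is a chosen subset of intrinsic mode
  functions. The EMD family and VMD are implemented in-package.
- **An S1/S2 detector**: Hilbert envelope → low-pass smoothing → peaks
  above 0.4× the envelope maximum → 100 ms deduplication → restoration of
  lost sub-threshold sounds in over-long gaps → S1/S2 labelling from the
  systolic/diastolic gap asymmetry.
- **Three metrics**: detection accuracy `ACC = 100·TP/(TP+FP+FN)` with
  ±50 ms matching, SNR improvement `SNR_out − SNR_in` where
  `SNR = 10·log10(Σ ref² / Σ (x − ref)²)`, and the mean heart-interval
  error `|ΔT̄i|` between detected and annotated S1–S1 intervals.
- **The comparison statistics**: Shapiro–Wilk normality gate, median/IQR
  descriptives, Kruskal–Wallis omnibus test, Dunn post hoc z-tests with
  Benjamini–Hochberg adjustment, homogeneous subgroups (maximal cliques of
  mutually non-significant algorithms) and Wilcoxon signed-rank tests on
  low/high-noise ACC ratios.

## Worked example

Denoise the low-level Gaussian-noise scenario with CEEMDAN and score it:

```python
import json
from fpcgbench import (generate_fetal_pcg, generate_gaussian_noise,
                       mix_at_snr, MixSpec, FilterConfig, apply_filter,
                       detect_heart_sounds, evaluate_cell)

ref = generate_fetal_pcg(duration_s=60.0, fs=1000.0, seed=1)
noise = generate_gaussian_noise(duration_s=60.0, fs=1000.0, seed=2010)
noisy = mix_at_snr(ref, [noise], MixSpec(("gaussian",), target_snr_db=-1.20))

config = FilterConfig("CEEMDAN", n_trials=10, noise_std=0.4,
                      imf_selection=(2, 3), seed=1)
filtered = apply_filter(noisy.samples, config, fs=1000.0)
detection = detect_heart_sounds(filtered, fs=1000.0)
report = evaluate_cell(ref, noisy.samples, filtered, detection)
print(json.dumps(report.to_dict(), indent=2))
```

prints

```json
{
  "acc_s1": 100.0,
  "acc_s2": 100.0,
  "snr_in_db": -1.1999999999999993,
  "snr_out_db": 4.580616468797817,
  "snr_improvement_db": 5.780616468797816,
  "mean_interval_error_ms": 1.4244604316551353,
  "tp_s1": 140, "fp_s1": 0, "fn_s1": 0,
  "tp_s2": 140, "fp_s2": 0, "fn_s2": 0
}
```

Every one of the 140 S1 and 140 S2 sounds in the 60 s record was found
within ±50 ms of its annotation (`acc_s1`/`acc_s2` = 100%), CEEMDAN with
modes 2+3 raised the SNR by 5.8 dB over the −1.2 dB input, and the
beat-to-beat S1 intervals of the detections deviate from the annotated
ones by 1.4 ms on average.

The same pipeline is available from the shell:

```sh
fpcg simulate --record r01 --noise gaussian --out rec
fpcg filter rec.noisy.wav rec.filt.wav --algorithm CEEMDAN \
     --config '{"n_trials": 10, "noise_std": 0.4, "imf_selection": [2, 3]}'
fpcg detect rec.filt.wav rec.detected.csv
fpcg evaluate rec.ref.wav rec.annotations.csv rec.noisy.wav rec.filt.wav
```

`fpcg benchmark` runs the full study grid — 2 records (r01 low / r02 high
interference) × 15 noise combinations (input SNR −0.53 … −10.76 dB) × 8
algorithms — and `fpcg stats` turns the resulting table into median/IQR
summaries, omnibus p-values and homogeneous subgroups.

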