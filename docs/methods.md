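# Methods

## Signal model

Heart sounds are modelled as Gaussian-modulated sinusoids,

    s(t) = A · exp(−(t − t0)² / 2σ²) · sin(2π f (t − t0)),

centred on the annotated event time `t0`. The width σ is set so that the
−40 dB points of the envelope span the configured sound duration:
σ = W / (2√(2 ln 100)). Defaults:

| train    | rate (bpm) | S1→S2 (ms) | S1/S2 ratio | f_S1 (Hz) | f_S2 (Hz) | S1 dur (ms) | S2 dur (ms) |
|----------|-----------|------------|-------------|-----------|-----------|-------------|-------------|
| fetal    | 140       | 140        | 1.7         | 36.89     | 55.18     | 60          | 40          |
| maternal | 70        | 331        | 1.54        | 16.93     | 30.44     | 180         | 120         |

Fetal durations follow the convention that S1 is the longer sound; the
maternal durations are free parameters chosen so that more than 95% of the
maternal train's power falls in its nominal 10–40 Hz band (shorter sounds
leak low-frequency envelope sidebands below 10 Hz). The first beat starts
at t = 0.2 s so no sound is clipped by the record boundary; the number of
S1 events is ⌊duration · rate/60⌋. Heart-rate variability is off by
default (`jitter_std_ms = 0`, exact reproduction of the printed beat
counts); tests of detector robustness use 10 ms per-beat jitter.

A note on the envelope: with these carriers and durations the
time-bandwidth product f·σ ≈ 0.36, so the analytic-signal envelope peaks
about 2.3% below the modulating Gaussian's amplitude. The bias is equal
for S1 and S2 (both sounds share f·σ), so envelope-based amplitude
*ratios* are unbiased.

## Interference models

- **Maternal heart sounds** — the maternal train above.
- **Movement artifacts** — random non-overlapping pulses of 0.5–1.5 s
  with fixed peak amplitude: Gaussian-windowed noise bursts, low-passed at
  25 Hz (fetal movements) or 100 Hz (maternal movements) with equal
  probability; 8 pulses/min by default. The band edge uses an 8th-order
  zero-phase Butterworth so less than 1% of pulse power leaks above
  110 Hz.
- **White Gaussian noise** — i.i.d. standard normal samples, standing in
  for contractions, respiration, digestive sounds and quantization noise.
- **Ambient noise** — white noise through a causal 5th-order Butterworth
  high-pass with 100 Hz cut-off (speech, doors, coughing).

Components are power-normalized, weighted (equal weights by default —
the relative proportions of co-occurring interference kinds are a free
choice, made symmetric for reproducibility), summed, and globally scaled
so the achieved SNR against the clean reference matches the target
exactly (closed-form scale factor; residual error is float rounding,
< 10⁻⁶ dB). The 30 shipped scenarios pair records r01 (seed 1, lower
interference) and r02 (seed 2, higher interference) with the 15 noise
combinations at input SNRs from −0.53 to −10.76 dB.

## Filter bank

- **SG** — `scipy` Savitzky–Golay; printed even window lengths round up
  to the next odd integer.
- **FIR** — Hamming-window linear-phase band-pass, 20–110 Hz, the "filter
  order" counting taps − 1; the group delay of ⌊order/2⌋ samples is
  compensated so outputs stay time-aligned.
- **AWT** — `pywt` DWT; each detail coefficient is soft-thresholded with
  a universal threshold σ√(2 ln n) whose noise scale σ comes from a
  moving MAD window (1 s at the input rate, halved per decimation level,
  50% overlap, linear interpolation between window centres), tracking
  nonstationary interference.
- **MODWT** — the normalized stationary (undecimated) wavelet transform
  from `pywt` with per-level universal soft thresholds (MAD σ); inputs are
  reflect-padded to a multiple of 2^levels and truncated after inversion.
- **EMD** — in-package: cubic-spline envelopes through local extrema with
  end extrema mirrored past the boundaries; sifting stops at a
  standard-deviation criterion of 0.2 (max 50 sifts); decomposition stops
  when fewer than two maxima/minima remain or at 10 modes.
- **EEMD** — per-index average of EMD modes over noise-perturbed copies;
  `Nstd` scales the added noise relative to std(x). `Nstd = 0` reduces
  exactly to EMD.
- **CEEMDAN** — sequential: stage k perturbs the current residue with the
  k-th EMD mode of paired ± noise realizations and averages the first
  sifted mode; completeness (Σ modes + residue = input) holds exactly by
  construction.
- **VMD** — in-package ADMM in the frequency domain on a mirror-extended
  signal; K = 5 modes, bandwidth penalty α = 2000, dual step τ = 0,
  tolerance 10⁻⁷, deterministic uniformly spaced initial centre
  frequencies; modes are returned sorted by ascending centre frequency and
  a convergence flag is set if the iteration cap (500) is hit.

For the decomposition methods the filtered signal is the sum of a
selected subset of modes (1-based indices, e.g. "2+3"). The per-scenario
winning settings of the original study are shipped as data
(`OPTIMAL_SETTINGS`); a per-cell ACC-maximizing grid search
(`grid_search`, objective: S1 ACC, ties broken by S2 ACC then grid order)
reproduces how those settings were chosen.

## Detection

1. Envelope by Hilbert transform (analytic-signal magnitude).
2. Zero-phase 4th-order Butterworth low-pass at 20 Hz — low enough to
   remove carrier ripple (≥ 33 Hz), high enough to keep the 140 ms S1/S2
   pair resolved as two local maxima.
3. Candidates: envelope local maxima above 0.4 × the envelope maximum.
4. Deduplication: peaks with successive spacings under 100 ms form
   clusters (transitive closure); the largest-amplitude peak per cluster
   is kept. Idempotent.
5. Restoration of lost sub-threshold sounds. A gap is scanned when it
   exceeds *min gap + median gap* of the deduplicated train. In an intact
   rhythm this limit sits strictly between the diastolic gap and the gap
   a lost sound leaves behind (≈ systole + diastole): at 140 bpm the
   diastole is 288.6 ms and the limit ≈ 354 ms, with comfortable margins
   across 110–160 bpm. A "twice the shortest interval" limit (280 ms at
   140 bpm) falls *below* the diastole and floods normal diastoles with
   spurious restorations whenever residual noise leaves envelope bumps
   there. Inside a flagged gap the highest envelope local maximum is
   restored, provided it exceeds 0.1 × max(env) (ignores numerical
   ripple in silent gaps) and keeps 100 ms — the deduplication spacing —
   to both gap ends. Up to 10 passes, so multiple consecutive losses are
   recovered.
6. Labelling from the systolic/diastolic asymmetry (systole < diastole):
   gaps below the midpoint of their 10th/90th percentiles count as
   systolic; a peak closing a diastole is S1, one opening a diastole is
   S2, and ambiguous neighbourhoods alternate from the previous label.
   On an intact rhythm this is exactly "peaks flanking the longest
   interval are S2|S1, the rest alternate"; unlike a single global
   alternation it confines the damage of an isolated missed or spurious
   peak to its neighbourhood instead of flipping the parity of every
   later label (which would turn one defect in a 300 s record into an
   ~50% accuracy collapse).

## Evaluation

- Matching: greedy nearest-neighbour within ±50 ms, one-to-one, ties to
  the earlier reference event. TP + FN always equals the reference event
  count. (Greedy can differ from optimal-cardinality matching on
  adversarial chained configurations — about 0.1% of random small cases —
  but never on trains spaced wider than twice the tolerance.)
- ACC = 100·TP/(TP+FP+FN), per sound type; undefined (reported missing)
  when all counts are zero.
- SNR = 10·log₁₀(Σ ref² / Σ (x − ref)²); a zero residual is capped at
  +300 dB and flagged rather than reported infinite. Improvement is
  SNR_out − SNR_in.
- Heart-interval error: mean |ΔTi| over consecutive S1–S1 intervals of
  the matched beats, in ms — invariant to a global time shift of the
  detections; reported missing with fewer than two matched beats.

## Statistics

Shapiro–Wilk (3 ≤ n ≤ 5000) gates the use of nonparametric descriptives
(median, quartiles by linear interpolation). Kruskal–Wallis (tie
corrected; H = 0, p = 1 for all-identical data) compares the eight
algorithms per metric and noise level; significant families get Dunn
z-tests on pooled mid-ranks with the Σ(t³−t)/(12(N−1)) tie correction and
Benjamini–Hochberg adjustment over the 28 pairs. Homogeneous subgroups
are the maximal cliques of the non-significance graph at α = 0.05, so an
algorithm can belong to several overlapping subgroups. The interference
-level effect is tested on per-scenario ACC ratios (low/high) with a
two-sided Wilcoxon signed-rank test against a median of one; an all-ones
ratio vector is degenerate and reported as p = 1 with a warning.

## Test and script problem sizes

Unit and property tests run on 2–60 s signals at 1 kHz. The clean-signal
perfection property uses 20 seeded (rate, jitter) draws of 30 s at
110–160 bpm. The CEEMDAN Gaussian-noise check and the acceptance script
use 60 s segments — the study's conclusions at that cell are insensitive
to record length, and ensemble decompositions dominate the run time. The
noise-level monotonicity property runs 10 seeds × 4 single-interference
scenarios × 2 records on 20 s signals with per-cell grid search over the
five direct-filtering algorithms (SG, FIR, AWT, MODWT, EMD); the
ensemble/variational methods are exercised by their own correctness and
sanity tests instead, as their contribution to that particular ordering
adds nothing methodologically.

## Known limitations

- Synthetic maternal/fetal morphology only: constant rates by default, no
  gestational-age dependence, no murmurs, no respiration or contraction
  dynamics beyond the Gaussian-noise surrogate. Passing benchmarks here
  demonstrates algorithmic behaviour under controlled interference, not
  clinical performance on real abdominal recordings.
- The EMD-family and VMD implementations follow the standard published
  procedures but are not bit-compatible with any other toolbox; printed
  mode selections ("2+3") refer to *this* decomposition's mode ordering.
- Detection assumes a quasi-periodic two-sound rhythm; it is not designed
  for arrhythmic or murmur-dominated signals.
- SNR improvements of mode-selection methods are bounded by how cleanly
  interference separates into modes; no post-selection refinement (e.g.
  interval thresholding within modes) is applied.
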