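"""Synthetic fetal phonocardiography signals and controlled interference.

Reference fetal and maternal heart-sound trains are built from Gaussian
modulated sinusoids: each S1/S2 sound is ``A * exp(-(t-t0)^2 / (2 sigma^2))
* sin(2 pi f (t-t0))`` centred on its annotated time, with ``sigma`` chosen
so the -40 dB envelope width equals the configured sound duration.  Four
interference models (maternal heart sounds, movement-artifact pulses, white
Gaussian noise, high-passed ambient noise) can be mixed onto a reference at
an exact target signal-to-noise ratio.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "HeartSoundParams",
    "AnnotatedSignal",
    "NoiseSpec",
    "MixSpec",
    "FETAL_PARAMS",
    "MATERNAL_PARAMS",
    "generate_fetal_pcg",
    "generate_maternal_hs",
    "generate_movement_artifacts",
    "generate_gaussian_noise",
    "generate_ambient_noise",
    "mix_at_snr",
]

# -40 dB amplitude point: exp(-(W/2)^2 / (2 sigma^2)) = 0.01
_ENVELOPE_WIDTH_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(100.0)))

NOISE_KINDS = ("mHS", "movement", "gaussian", "ambient")


@dataclass(frozen=True)
class HeartSoundParams:
    """Parameters of one Gaussian-modulated-sinusoid heart-sound train.

    ``s1_s2_interval_ms`` is the S1-onset to S2-onset spacing within one
    beat; ``amp_ratio_s1_s2`` the S1/S2 peak-envelope ratio.  ``jitter_std_ms``
    adds independent zero-mean Gaussian jitter to each beat onset (default 0,
    i.e. a perfectly regular rhythm).  ``start_offset_s`` shifts the first
    beat away from t=0 so no sound is clipped by the record boundary.
    """

    rate_bpm: float
    s1_s2_interval_ms: float
    amp_ratio_s1_s2: float
    f_s1_hz: float
    f_s2_hz: float
    s1_duration_ms: float
    s2_duration_ms: float
    base_amplitude: float = 1.0
    jitter_std_ms: float = 0.0
    start_offset_s: float = 0.2

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0:
            raise ValueError("rate_bpm must be positive")
        if not self.s1_s2_interval_ms < 60000.0 / self.rate_bpm:
            raise ValueError("S1-S2 interval must fit inside one beat period")
        if self.amp_ratio_s1_s2 <= 0:
            raise ValueError("amp_ratio_s1_s2 must be positive")


#: Fetal reference train: 40-week fetus, 140 bpm, S1/S2 ratio 1.7,
#: carriers 36.89 / 55.18 Hz, 140 ms S1-S2 spacing.
FETAL_PARAMS = HeartSoundParams(
    rate_bpm=140.0,
    s1_s2_interval_ms=140.0,
    amp_ratio_s1_s2=1.7,
    f_s1_hz=36.89,
    f_s2_hz=55.18,
    s1_duration_ms=60.0,
    s2_duration_ms=40.0,
)

#: Maternal heart sounds: 70 bpm, ratio 1.54, carriers 16.93 / 30.44 Hz,
#: 331 ms spacing.  Durations chosen so >95% of the train's power sits in
#: the 10-40 Hz maternal band.
MATERNAL_PARAMS = HeartSoundParams(
    rate_bpm=70.0,
    s1_s2_interval_ms=331.0,
    amp_ratio_s1_s2=1.54,
    f_s1_hz=16.93,
    f_s2_hz=30.44,
    s1_duration_ms=180.0,
    s2_duration_ms=120.0,
)


@dataclass
class AnnotatedSignal:
    """A sampled waveform plus ground-truth event annotations.

    ``events`` is an ordered list of ``(time_s, label)`` with labels in
    {"S1", "S2"}; for pure-noise signals it is empty.
    """

    samples: np.ndarray
    fs: float
    events: list[tuple[float, str]] = field(default_factory=list)
    params: object | None = None
    seed: int | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def event_times(self, label: str | None = None) -> np.ndarray:
        if label is None:
            return np.array([t for t, _ in self.events])
        return np.array([t for t, lab in self.events if lab == label])

    def with_samples(self, samples: np.ndarray) -> "AnnotatedSignal":
        return AnnotatedSignal(samples=np.asarray(samples, dtype=float),
                               fs=self.fs, events=list(self.events),
                               params=self.params, seed=self.seed)


@dataclass(frozen=True)
class NoiseSpec:
    """One of the four interference models.

    movement: fixed-amplitude random pulses of 0.5-1.5 s, band-limited to
    0-25 Hz (fetal movements) or 0-100 Hz (maternal movements).
    ambient: white noise through a causal 5th-order Butterworth high-pass.
    """

    kind: str
    pulse_amplitude: float = 1.0
    pulses_per_min: float = 8.0
    hpf_order: int = 5
    hpf_cutoff_hz: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; "
                             f"expected one of {NOISE_KINDS}")


@dataclass(frozen=True)
class MixSpec:
    """How to combine noise components and scale them onto a reference."""

    noise_kinds: tuple[str, ...]
    target_snr_db: float
    component_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.noise_kinds) <= 4:
            raise ValueError("between 1 and 4 noise kinds required")
        for k in self.noise_kinds:
            if k not in NOISE_KINDS:
                raise ValueError(f"unknown noise kind {k!r}")
        if self.component_weights is not None:
            w = np.asarray(self.component_weights, dtype=float)
            if len(w) != len(self.noise_kinds):
                raise ValueError("one weight per noise kind required")
            if np.any(w <= 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("weights must be positive and sum to 1")

    def weights(self) -> np.ndarray:
        if self.component_weights is None:
            return np.full(len(self.noise_kinds), 1.0 / len(self.noise_kinds))
        return np.asarray(self.component_weights, dtype=float)


def _check_fs(fs: float, max_carrier_hz: float) -> None:
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    if fs < 4.0 * max_carrier_hz:
        raise ValueError(
            f"fs={fs} Hz violates the 4x-carrier rule for {max_carrier_hz} Hz"
        )


def _gauss_sound(t_local: np.ndarray, amp: float, f_hz: float,
                 sigma_s: float) -> np.ndarray:
    env = amp * np.exp(-(t_local ** 2) / (2.0 * sigma_s ** 2))
    return env * np.sin(2.0 * np.pi * f_hz * t_local)


def _generate_heart_sounds(params: HeartSoundParams, duration_s: float,
                           fs: float, seed: int | None) -> AnnotatedSignal:
    _check_fs(fs, max(params.f_s1_hz, params.f_s2_hz))
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    n = round(duration_s * fs)
    samples = np.zeros(n)
    if n == 0:
        return AnnotatedSignal(samples, fs, [], params, seed)

    rng = np.random.default_rng(seed)
    period_s = 60.0 / params.rate_bpm
    n_beats = int(math.floor(duration_s * params.rate_bpm / 60.0))
    onsets = params.start_offset_s + period_s * np.arange(n_beats)
    if params.jitter_std_ms > 0:
        onsets = onsets + rng.normal(0.0, params.jitter_std_ms / 1000.0,
                                     size=n_beats)

    sig1 = params.s1_duration_ms / 1000.0 * _ENVELOPE_WIDTH_TO_SIGMA
    sig2 = params.s2_duration_ms / 1000.0 * _ENVELOPE_WIDTH_TO_SIGMA
    a1 = params.base_amplitude
    a2 = params.base_amplitude / params.amp_ratio_s1_s2
    s1s2 = params.s1_s2_interval_ms / 1000.0

    events: list[tuple[float, str]] = []
    for t1 in onsets:
        for t0, label, amp, f_hz, sig in (
            (t1, "S1", a1, params.f_s1_hz, sig1),
            (t1 + s1s2, "S2", a2, params.f_s2_hz, sig2),
        ):
            if not 0.0 <= t0 <= duration_s:
                continue
            lo = max(0, int((t0 - 5 * sig) * fs))
            hi = min(n, int((t0 + 5 * sig) * fs) + 1)
            t_local = np.arange(lo, hi) / fs - t0
            samples[lo:hi] += _gauss_sound(t_local, amp, f_hz, sig)
            events.append((t0, label))
    events.sort(key=lambda e: e[0])
    return AnnotatedSignal(samples, fs, events, params, seed)


def generate_fetal_pcg(params: HeartSoundParams = FETAL_PARAMS, *,
                       duration_s: float = 300.0, fs: float = 1000.0,
                       seed: int | None = None) -> AnnotatedSignal:
    """Generate the clean reference fetal PCG train with annotations."""
    return _generate_heart_sounds(params, duration_s, fs, seed)


def generate_maternal_hs(params: HeartSoundParams = MATERNAL_PARAMS, *,
                         duration_s: float = 300.0, fs: float = 1000.0,
                         seed: int | None = None) -> AnnotatedSignal:
    """Generate the maternal heart-sound interference train."""
    return _generate_heart_sounds(params, duration_s, fs, seed)


def generate_movement_artifacts(spec: NoiseSpec | None = None, *,
                                duration_s: float = 300.0, fs: float = 1000.0,
                                seed: int | None = None) -> AnnotatedSignal:
    """Random non-overlapping movement-artifact pulses.

    Each pulse is a Gaussian-windowed band-limited noise burst of fixed peak
    amplitude lasting 0.5-1.5 s.  Fetal-type pulses are low-passed at 25 Hz,
    maternal-type at 100 Hz; the type of each pulse is drawn with equal
    probability.
    """
    if spec is None:
        spec = NoiseSpec("movement")
    if spec.kind != "movement":
        raise ValueError("spec.kind must be 'movement'")
    if fs <= 200:
        raise ValueError("fs must exceed 200 Hz for movement artifacts")
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    n = round(duration_s * fs)
    samples = np.zeros(n)
    if n == 0:
        return AnnotatedSignal(samples, fs, [], spec, seed)

    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    n_pulses = int(math.floor(duration_s * spec.pulses_per_min / 60.0))
    if n_pulses * 1.5 > 0.8 * duration_s:
        raise ValueError(
            "pulse rate too high: non-overlapping placement is infeasible")

    placed: list[tuple[float, float]] = []
    durations = rng.uniform(0.5, 1.5, size=n_pulses)
    is_maternal = rng.random(n_pulses) < 0.5
    for dur, maternal in zip(durations, is_maternal):
        for _ in range(1000):
            start = rng.uniform(0.0, duration_s - dur)
            if all(start + dur <= a or start >= a + d for a, d in placed):
                placed.append((start, dur))
                break
        else:
            raise ValueError("could not place non-overlapping pulses")
        cutoff = 100.0 if maternal else 25.0
        m = int(dur * fs)
        burst = rng.standard_normal(m)
        sos = sps.butter(8, cutoff, btype="low", fs=fs, output="sos")
        burst = sps.sosfiltfilt(sos, burst)
        t_local = (np.arange(m) - m / 2) / fs
        sigma = dur / 6.0
        burst *= np.exp(-(t_local ** 2) / (2.0 * sigma ** 2))
        peak = np.max(np.abs(burst))
        if peak > 0:
            burst *= spec.pulse_amplitude / peak
        i0 = int(start * fs)
        samples[i0:i0 + m] += burst[: n - i0]
    return AnnotatedSignal(samples, fs, [], spec, seed)


def generate_gaussian_noise(*, duration_s: float = 300.0, fs: float = 1000.0,
                            seed: int | None = None) -> AnnotatedSignal:
    """Zero-mean unit-variance white Gaussian noise."""
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal(round(duration_s * fs))
    return AnnotatedSignal(samples, fs, [], NoiseSpec("gaussian", seed=seed),
                           seed)


def generate_ambient_noise(*, duration_s: float = 300.0, fs: float = 1000.0,
                           seed: int | None = None, order: int = 5,
                           cutoff_hz: float = 100.0) -> AnnotatedSignal:
    """Broadband ambient noise: white noise through a causal Butterworth
    high-pass (default 5th order, 100 Hz cut-off)."""
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(round(duration_s * fs))
    sos = sps.butter(order, cutoff_hz, btype="high", fs=fs, output="sos")
    samples = sps.sosfilt(sos, white)
    spec = NoiseSpec("ambient", hpf_order=order, hpf_cutoff_hz=cutoff_hz,
                     seed=seed)
    return AnnotatedSignal(samples, fs, [], spec, seed)


def combine_noises(noises: list[AnnotatedSignal],
                   weights: np.ndarray) -> np.ndarray:
    """Power-normalize each component, weight, and sum."""
    total = np.zeros_like(noises[0].samples)
    for noise, w in zip(noises, weights):
        p = float(np.mean(noise.samples ** 2))
        if p <= 0:
            raise ValueError("zero-power noise component")
        total += math.sqrt(w / p) * noise.samples
    return total


def mix_at_snr(ref: AnnotatedSignal, noises: list[AnnotatedSignal],
               mix: MixSpec, *, return_components: bool = False):
    """Add combined interference to the reference at an exact target SNR.

    SNR is the ratio of reference power to residual (= noise) power in dB;
    the combined noise is globally rescaled so the achieved value equals
    ``mix.target_snr_db`` up to floating-point rounding.  Annotations are
    carried through unchanged.  With ``return_components=True`` the scaled
    noise array is returned alongside the mixed signal.
    """
    if not noises:
        raise ValueError("at least one noise component required")
    for noise in noises:
        if noise.fs != ref.fs or len(noise.samples) != len(ref.samples):
            raise ValueError("all signals must share fs and length")
    p_ref = float(np.mean(ref.samples ** 2))
    if p_ref <= 0:
        raise ValueError("zero-power reference")
    combined = combine_noises(noises, mix.weights())
    p_comb = float(np.mean(combined ** 2))
    if p_comb <= 0:
        raise ValueError("zero-power combined noise")
    gain = math.sqrt(p_ref * 10.0 ** (-mix.target_snr_db / 10.0) / p_comb)
    scaled = gain * combined
    mixed = AnnotatedSignal(ref.samples + scaled, ref.fs, list(ref.events),
                            params=mix, seed=ref.seed)
    if return_components:
        return mixed, scaled
    return mixed
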