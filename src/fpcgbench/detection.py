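"""S1/S2 heart-sound detection from a (filtered) PCG waveform.

The procedure: (a) Hilbert-transform envelope, (b) zero-phase low-pass
smoothing, (c) local maxima above 0.4x the envelope maximum become
candidate sounds, (d) peaks closer than 100 ms are deduplicated keeping
the largest per cluster, (e) sub-threshold sounds are restored inside any
inter-peak gap longer than twice the shortest interval, (f) peaks are
labelled S1/S2 using the physiological asymmetry that the systolic S1->S2
interval is shorter than the diastolic S2->S1 interval: the peaks flanking
the longest interval are S2 (left) and S1 (right), the rest alternate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PeakTrain",
    "DetectionConfig",
    "DetectionResult",
    "compute_envelope",
    "smooth_envelope",
    "threshold_candidates",
    "deduplicate_peaks",
    "restore_missed_peaks",
    "classify_s1_s2",
    "detect_heart_sounds",
]


@dataclass
class PeakTrain:
    """Detected peaks: strictly increasing times, envelope amplitudes and
    optional alternating S1/S2 labels."""

    times: np.ndarray
    amplitudes: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def times_for(self, label: str) -> np.ndarray:
        if self.labels is None:
            return np.array([])
        return self.times[[lab == label for lab in self.labels]]


@dataclass(frozen=True)
class DetectionConfig:
    threshold_frac: float = 0.4
    min_interval_ms: float = 100.0
    envelope_lpf_hz: float = 20.0
    restore_min_frac: float = 0.1
    max_restore_passes: int = 10


@dataclass
class DetectionResult:
    raw_envelope: np.ndarray
    smoothed_envelope: np.ndarray
    threshold_value: float
    candidates: PeakTrain
    deduplicated: PeakTrain
    restored: PeakTrain
    final: PeakTrain
    message: str = ""


def compute_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert-transform envelope)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("signal too short for an envelope")
    return np.abs(sps.hilbert(x))


def smooth_envelope(env: np.ndarray, cutoff_hz: float,
                    fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of the envelope."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(env, dtype=float))


def threshold_candidates(env: np.ndarray, fs: float,
                         threshold_frac: float = 0.4) -> PeakTrain:
    """Local maxima of the envelope above ``threshold_frac * max(env)``."""
    env = np.asarray(env, dtype=float)
    if len(env) == 0:
        raise ValueError("empty envelope")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    thr = threshold_frac * float(np.max(env))
    idx, _ = sps.find_peaks(env)
    idx = idx[env[idx] > thr]
    return PeakTrain(idx / fs, env[idx])


def deduplicate_peaks(train: PeakTrain,
                      min_interval_ms: float = 100.0) -> PeakTrain:
    """Remove peaks closer than the minimum interval.

    Peaks whose successive spacings fall below the interval form clusters
    (transitive closure); the highest-amplitude peak of each cluster is
    kept.  Idempotent.
    """
    if len(train) <= 1:
        return PeakTrain(train.times.copy(), train.amplitudes.copy())
    min_s = min_interval_ms / 1000.0
    keep_t, keep_a = [], []
    start = 0
    for i in range(1, len(train) + 1):
        boundary = (i == len(train)
                    or train.times[i] - train.times[i - 1] >= min_s)
        if boundary:
            cluster = slice(start, i)
            j = start + int(np.argmax(train.amplitudes[cluster]))
            keep_t.append(train.times[j])
            keep_a.append(train.amplitudes[j])
            start = i
    return PeakTrain(np.array(keep_t), np.array(keep_a))


def restore_missed_peaks(train: PeakTrain, env: np.ndarray, fs: float,
                         min_frac: float = 0.1,
                         margin_ms: float = 100.0,
                         max_passes: int = 10) -> PeakTrain:
    """Re-insert sub-threshold sounds inside over-long gaps.

    A gap is over-long when it exceeds the shortest inter-peak interval
    plus the median interval of the input train: in an intact S1/S2 rhythm
    that limit sits between the diastolic gap and the gap a lost sound
    leaves behind (roughly systole plus diastole), so normal diastoles are
    never scanned while single losses always are.  Inside each flagged gap
    the highest envelope local maximum is restored, provided it exceeds
    ``min_frac * max(env)`` (ignoring numerical ripple in silent
    intervals) and keeps ``margin_ms`` clearance to both gap ends (the
    same spacing the deduplication rule enforces).  Passes repeat until a
    fixed point or ``max_passes``.
    """
    if len(train) < 2:
        warnings.warn("fewer than 2 peaks; nothing to restore")
        return PeakTrain(train.times.copy(), train.amplitudes.copy())
    env = np.asarray(env, dtype=float)
    gaps0 = np.diff(train.times)
    limit = float(np.min(gaps0) + np.median(gaps0))
    floor = min_frac * float(np.max(env))
    margin_s = margin_ms / 1000.0
    peak_idx, _ = sps.find_peaks(env)
    peak_idx = peak_idx[env[peak_idx] > floor]

    times = list(train.times)
    amps = list(train.amplitudes)
    for _ in range(max_passes):
        inserted = False
        gaps = np.diff(times)
        for g in np.nonzero(gaps > limit)[0]:
            lo = (times[g] + margin_s) * fs
            hi = (times[g + 1] - margin_s) * fs
            inside = peak_idx[(peak_idx > lo) & (peak_idx < hi)]
            if len(inside) == 0:
                continue
            best = inside[np.argmax(env[inside])]
            times.append(best / fs)
            amps.append(env[best])
            inserted = True
        if not inserted:
            break
        order = np.argsort(times)
        times = [times[i] for i in order]
        amps = [amps[i] for i in order]
    return PeakTrain(np.array(times), np.array(amps))


def classify_s1_s2(train: PeakTrain) -> PeakTrain:
    """Label peaks using the systolic/diastolic gap asymmetry.

    The systolic S1->S2 interval is shorter than the diastolic S2->S1
    interval, so the peak opening a long (diastolic) interval is S2 and
    the peak closing it is S1 — on an intact rhythm this is exactly the
    longest-interval anchor with alternating labels outward.  Labels are
    assigned from each peak's flanking gap pattern (gaps shorter than the
    midpoint of the 10th/90th gap percentiles count as systolic), falling
    back to alternation where both flanks agree, so an isolated missed or
    spurious peak perturbs labels only locally instead of flipping the
    parity of the rest of the train.
    """
    if len(train) < 3:
        raise ValueError("need at least 3 peaks to orient S1/S2 labels")
    gaps = np.diff(train.times)
    p10, p90 = np.percentile(gaps, [10, 90])
    tau = 0.5 * (p10 + p90)
    systolic = gaps < tau
    n = len(train)
    labels: list[str] = [""] * n
    labels[0] = "S1" if systolic[0] else "S2"
    for i in range(1, n - 1):
        before, after = systolic[i - 1], systolic[i]
        if after and not before:
            labels[i] = "S1"
        elif before and not after:
            labels[i] = "S2"
        else:  # ambiguous neighbourhood: alternate from the previous label
            labels[i] = "S2" if labels[i - 1] == "S1" else "S1"
    labels[-1] = "S2" if systolic[-1] else "S1"
    return PeakTrain(train.times.copy(), train.amplitudes.copy(), labels)


def detect_heart_sounds(x: np.ndarray, fs: float,
                        config: DetectionConfig | None = None
                        ) -> DetectionResult:
    """Full detection pipeline; intermediates are retained in the result."""
    if config is None:
        config = DetectionConfig()
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input signal")
    raw = compute_envelope(x)
    if not np.any(raw):
        empty = PeakTrain(np.array([]), np.array([]))
        return DetectionResult(raw, raw.copy(), 0.0, empty, empty, empty,
                               empty, message="no peaks: all-zero input")
    smoothed = smooth_envelope(raw, config.envelope_lpf_hz, fs)
    threshold_value = config.threshold_frac * float(np.max(smoothed))
    candidates = threshold_candidates(smoothed, fs, config.threshold_frac)
    dedup = deduplicate_peaks(candidates, config.min_interval_ms)
    if len(dedup) >= 2:
        restored = restore_missed_peaks(dedup, smoothed, fs,
                                        min_frac=config.restore_min_frac,
                                        margin_ms=config.min_interval_ms,
                                        max_passes=config.max_restore_passes)
    else:
        restored = dedup
    message = ""
    if len(restored) >= 3:
        final = classify_s1_s2(restored)
    else:
        final = restored
        message = "classification skipped: fewer than 3 peaks"
    return DetectionResult(raw, smoothed, threshold_value, candidates,
                           dedup, restored, final, message)
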