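"""Scoring of filtered signals: detection accuracy, SNR, interval error.

Detected sounds are matched one-to-one to reference annotations within a
+/-50 ms window; accuracy is ACC = 100 * TP / (TP + FP + FN).  Signal
quality is measured as SNR of the reference against the residual (input or
filtered minus reference), and filtering benefit as SNR_out - SNR_in.  The
heart-interval error is the mean absolute difference between consecutive
S1-to-S1 intervals of the detections and of the reference, over matched
beats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionResult, PeakTrain
from .synthetic import AnnotatedSignal

__all__ = [
    "MatchCounts",
    "EvaluationReport",
    "match_events",
    "accuracy",
    "snr_db",
    "snr_improvement",
    "mean_interval_error",
    "evaluate_cell",
]

SNR_CAP_DB = 300.0


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int
    tolerance_ms: float
    matched_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class EvaluationReport:
    acc_s1: float | None
    acc_s2: float | None
    snr_in_db: float
    snr_out_db: float
    snr_improvement_db: float
    mean_interval_error_ms: float | None
    counts_s1: MatchCounts
    counts_s2: MatchCounts
    snr_capped: bool = False

    def to_dict(self) -> dict:
        return {
            "acc_s1": self.acc_s1,
            "acc_s2": self.acc_s2,
            "snr_in_db": self.snr_in_db,
            "snr_out_db": self.snr_out_db,
            "snr_improvement_db": self.snr_improvement_db,
            "mean_interval_error_ms": self.mean_interval_error_ms,
            "tp_s1": self.counts_s1.tp, "fp_s1": self.counts_s1.fp,
            "fn_s1": self.counts_s1.fn,
            "tp_s2": self.counts_s2.tp, "fp_s2": self.counts_s2.fp,
            "fn_s2": self.counts_s2.fn,
        }


def match_events(detected_times: np.ndarray, reference_times: np.ndarray,
                 tolerance_ms: float = 50.0) -> MatchCounts:
    """Greedy nearest-neighbour one-to-one matching within a tolerance.

    Pairs are accepted in order of increasing time difference; ties go to
    the earlier reference event.  Unmatched detections are FP, unmatched
    reference events FN.
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance_ms must be positive")
    det = np.asarray(detected_times, dtype=float)
    ref = np.asarray(reference_times, dtype=float)
    tol = tolerance_ms / 1000.0
    pairs = []
    lo = np.searchsorted(ref, det - tol, side="left")
    hi = np.searchsorted(ref, det + tol, side="right")
    for i, td in enumerate(det):
        for j in range(lo[i], hi[i]):
            pairs.append((abs(td - ref[j]), j, i))
    pairs.sort()
    used_det: set[int] = set()
    used_ref: set[int] = set()
    matched = []
    for _, j, i in pairs:
        if i in used_det or j in used_ref:
            continue
        used_det.add(i)
        used_ref.add(j)
        matched.append((i, j))
    tp = len(matched)
    return MatchCounts(tp, len(det) - tp, len(ref) - tp, tolerance_ms,
                       tuple(sorted(matched)))


def accuracy(counts: MatchCounts) -> float | None:
    """ACC = 100 * TP / (TP + FP + FN); None when all counts are zero."""
    total = counts.tp + counts.fp + counts.fn
    if total == 0:
        return None
    return 100.0 * counts.tp / total


def snr_db(reference: np.ndarray, other: np.ndarray,
           cap_db: float = SNR_CAP_DB) -> tuple[float, bool]:
    """10 log10 of reference power over residual power, capped for a zero
    residual.  Returns ``(value_db, capped)``."""
    ref = np.asarray(reference, dtype=float)
    oth = np.asarray(other, dtype=float)
    if len(ref) != len(oth):
        raise ValueError("signals must have equal length")
    p_ref = float(np.sum(ref ** 2))
    if p_ref <= 0:
        raise ValueError("all-zero reference")
    p_res = float(np.sum((oth - ref) ** 2))
    if p_res <= 0:
        return cap_db, True
    value = 10.0 * math.log10(p_ref / p_res)
    if value > cap_db:
        return cap_db, True
    return value, False


def snr_improvement(reference: np.ndarray, noisy: np.ndarray,
                    filtered: np.ndarray) -> float:
    """SNR_out - SNR_in in dB."""
    out, _ = snr_db(reference, filtered)
    inp, _ = snr_db(reference, noisy)
    return out - inp


def mean_interval_error(detected_s1: np.ndarray, reference_s1: np.ndarray,
                        tolerance_ms: float = 50.0) -> float | None:
    """Mean |T_i(detected) - T_i(reference)| over consecutive matched
    S1-to-S1 intervals, in ms; None with fewer than 2 matched beats."""
    counts = match_events(detected_s1, reference_s1, tolerance_ms)
    if counts.tp < 2:
        return None
    det = np.asarray(detected_s1, dtype=float)
    ref = np.asarray(reference_s1, dtype=float)
    pairs = sorted(counts.matched_pairs, key=lambda p: p[1])
    det_t = np.array([det[i] for i, _ in pairs])
    ref_t = np.array([ref[j] for _, j in pairs])
    dt = np.diff(det_t) - np.diff(ref_t)
    return float(np.mean(np.abs(dt))) * 1000.0


def evaluate_cell(reference: AnnotatedSignal, noisy: np.ndarray,
                  filtered: np.ndarray, detection: DetectionResult,
                  tolerance_ms: float = 50.0) -> EvaluationReport:
    """Bind the three metrics into one report for a benchmark cell."""
    ref_s1 = reference.event_times("S1")
    ref_s2 = reference.event_times("S2")
    det_s1 = detection.final.times_for("S1")
    det_s2 = detection.final.times_for("S2")
    counts_s1 = match_events(det_s1, ref_s1, tolerance_ms)
    counts_s2 = match_events(det_s2, ref_s2, tolerance_ms)
    snr_in, cap_in = snr_db(reference.samples, noisy)
    snr_out, cap_out = snr_db(reference.samples, filtered)
    return EvaluationReport(
        acc_s1=accuracy(counts_s1),
        acc_s2=accuracy(counts_s2),
        snr_in_db=snr_in,
        snr_out_db=snr_out,
        snr_improvement_db=snr_out - snr_in,
        mean_interval_error_ms=mean_interval_error(det_s1, ref_s1,
                                                   tolerance_ms),
        counts_s1=counts_s1,
        counts_s2=counts_s2,
        snr_capped=cap_in or cap_out,
    )
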