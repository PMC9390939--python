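"""Eight single-channel denoising algorithms with a uniform contract.

Smoothers/filters: Savitzky-Golay (SG), linear-phase FIR band-pass (FIR),
adaptive wavelet thresholding with a moving noise-estimate window (AWT),
and undecimated-wavelet thresholding (MODWT).  Decomposers: VMD, EMD, EEMD
and CEEMDAN, which split the signal into intrinsic mode functions; a
denoised signal is the sum of a selected subset of modes.

All operations return a waveform of the input's length; ``apply_filter``
dispatches on a :class:`FilterConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from . import emd as _emd
from . import vmd as _vmd

__all__ = [
    "IMFSet",
    "FilterConfig",
    "ALGORITHMS",
    "savgol_smooth",
    "fir_bandpass",
    "awt_denoise",
    "modwt_denoise",
    "emd_decompose",
    "eemd_decompose",
    "ceemdan_decompose",
    "vmd_decompose",
    "reconstruct_from_imfs",
    "apply_filter",
]

ALGORITHMS = ("SG", "FIR", "AWT", "MODWT", "VMD", "EMD", "EEMD", "CEEMDAN")


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residue from a decomposition."""

    modes: list[np.ndarray]
    residue: np.ndarray
    method: str
    converged: bool = True

    def __len__(self) -> int:
        return len(self.modes)


@dataclass(frozen=True)
class FilterConfig:
    """Algorithm tag plus the parameters that algorithm reads.

    Unused fields are ignored by the dispatcher.  ``imf_selection`` holds
    1-based mode indices for the decomposition methods (the printed "2+3"
    style selections).
    """

    algorithm: str
    window_length: int = 20              # SG
    poly_order: int = 7                  # SG
    filter_order: int = 31               # FIR
    band: tuple[float, float] = (20.0, 110.0)   # FIR
    wavelet: str = "sym4"                # AWT / MODWT
    levels: int = 3                      # AWT / MODWT
    n_trials: int = 50                   # EEMD / CEEMDAN
    noise_std: float = 0.2               # EEMD / CEEMDAN
    seed: int | None = None              # EEMD / CEEMDAN
    imf_selection: tuple[int, ...] = (1, 2, 3)   # VMD / EMD-family
    n_modes: int = 5                     # VMD
    vmd_alpha: float = 2000.0            # VMD
    max_imfs: int = 10

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm tag {self.algorithm!r}")
        if any(i < 1 for i in self.imf_selection):
            raise ValueError("imf_selection indices are 1-based (>= 1)")
        if self.n_trials < 1 or self.noise_std < 0:
            raise ValueError("n_trials >= 1 and noise_std >= 0 required")


def savgol_smooth(x: np.ndarray, window_length: int,
                  poly_order: int) -> np.ndarray:
    """Savitzky-Golay smoothing; even windows round up to the next odd."""
    x = np.asarray(x, dtype=float)
    if window_length % 2 == 0:
        window_length += 1
    if not 0 <= poly_order < window_length:
        raise ValueError("require 0 <= poly_order < window_length")
    if window_length > len(x):
        raise ValueError("window longer than the signal")
    return sps.savgol_filter(x, window_length, poly_order)


def fir_bandpass(x: np.ndarray, filter_order: int,
                 band: tuple[float, float], fs: float) -> np.ndarray:
    """Linear-phase windowed-sinc band-pass with group-delay compensation."""
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if filter_order < 1:
        raise ValueError("filter_order must be >= 1")
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band edges must satisfy 0 < lo < hi < fs/2")
    numtaps = filter_order + 1
    if numtaps < 3:
        numtaps = 3
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                      window="hamming")
    delay = (numtaps - 1) // 2
    padded = np.concatenate([x, np.zeros(numtaps)])
    y = sps.lfilter(taps, 1.0, padded)
    return y[delay: delay + len(x)]


def _soft(c: np.ndarray, thr: np.ndarray | float) -> np.ndarray:
    return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)


def _mad_sigma(d: np.ndarray) -> float:
    return float(np.median(np.abs(d - np.median(d))) / 0.6745)


def awt_denoise(x: np.ndarray, wavelet: str, levels: int,
                window_length: int = 1000,
                threshold_scale: float = 1.0) -> np.ndarray:
    """Adaptive wavelet thresholding.

    Decomposes to ``levels`` with the DWT, then soft-thresholds each detail
    coefficient using a universal threshold whose noise scale is estimated
    in a moving window (50% overlap) around that coefficient, so the
    threshold tracks nonstationary interference.  ``window_length`` is in
    input samples; ``threshold_scale=0`` reduces to perfect reconstruction.
    """
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if wavelet not in pywt.wavelist():
        raise ValueError(f"unknown wavelet {wavelet!r}")
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    out = [coeffs[0]]
    for j, d in enumerate(coeffs[1:]):
        # detail level j=0 is the coarsest; decimation factor halves window
        w = max(8, window_length // 2 ** (levels - j))
        hop = max(1, w // 2)
        centers, sigmas = [], []
        for start in range(0, max(1, len(d) - w // 2), hop):
            seg = d[start: start + w]
            if len(seg) < 4:
                continue
            centers.append(start + len(seg) / 2)
            sigmas.append(_mad_sigma(seg))
        if not centers:
            centers, sigmas = [len(d) / 2], [_mad_sigma(d)]
        sigma_i = np.interp(np.arange(len(d)), centers, sigmas)
        thr = threshold_scale * sigma_i * np.sqrt(2.0 * np.log(max(len(d), 2)))
        out.append(_soft(d, thr))
    y = pywt.waverec(out, wavelet)
    return y[: len(x)]


def modwt_denoise(x: np.ndarray, wavelet: str, levels: int,
                  threshold_scale: float = 1.0) -> np.ndarray:
    """Undecimated (maximal-overlap) wavelet thresholding.

    Uses the normalized stationary wavelet transform, whose per-level
    coefficient arrays keep the input length; details are soft-thresholded
    with a per-level universal threshold (MAD noise estimate).
    """
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if wavelet not in pywt.wavelist():
        raise ValueError(f"unknown wavelet {wavelet!r}")
    n = len(x)
    block = 2 ** levels
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x
    coeffs = pywt.swt(xp, wavelet, level=levels, trim_approx=True, norm=True)
    thresholded = [coeffs[0]]
    for d in coeffs[1:]:
        thr = threshold_scale * _mad_sigma(d) * np.sqrt(2.0 * np.log(len(d)))
        thresholded.append(_soft(d, thr))
    y = pywt.iswt(thresholded, wavelet, norm=True)
    return y[:n]


def emd_decompose(x: np.ndarray, max_imfs: int = 10,
                  sift_tolerance: float = 0.2) -> IMFSet:
    modes, residue = _emd.emd(x, max_imfs=max_imfs, sd_thresh=sift_tolerance)
    return IMFSet(modes, residue, "EMD")


def eemd_decompose(x: np.ndarray, n_trials: int = 50, noise_std: float = 0.2,
                   seed: int | None = None, max_imfs: int = 10) -> IMFSet:
    modes, residue = _emd.eemd(x, n_trials=n_trials, noise_std=noise_std,
                               seed=seed, max_imfs=max_imfs)
    return IMFSet(modes, residue, "EEMD")


def ceemdan_decompose(x: np.ndarray, n_trials: int = 50,
                      noise_std: float = 0.2, seed: int | None = None,
                      max_imfs: int = 10) -> IMFSet:
    modes, residue = _emd.ceemdan(x, n_trials=n_trials, noise_std=noise_std,
                                  seed=seed, max_imfs=max_imfs)
    return IMFSet(modes, residue, "CEEMDAN")


def vmd_decompose(x: np.ndarray, n_modes: int = 5,
                  bandwidth_alpha: float = 2000.0, tau: float = 0.0,
                  tol: float = 1e-7) -> IMFSet:
    modes, residue, converged = _vmd.vmd(x, n_modes=n_modes,
                                         alpha=bandwidth_alpha, tau=tau,
                                         tol=tol)
    return IMFSet(modes, residue, "VMD", converged=converged)


def reconstruct_from_imfs(imfset: IMFSet,
                          imf_selection: tuple[int, ...] | list[int],
                          include_residue: bool = False) -> np.ndarray:
    """Sum the 1-based selected modes (optionally plus the residue)."""
    if len(imf_selection) == 0 and not include_residue:
        raise ValueError("empty IMF selection")
    for i in imf_selection:
        if not 1 <= i <= len(imfset.modes):
            raise ValueError(
                f"IMF index {i} out of range 1..{len(imfset.modes)}")
    y = np.zeros_like(imfset.residue)
    for i in imf_selection:
        y = y + imfset.modes[i - 1]
    if include_residue:
        y = y + imfset.residue
    return y


def _select_available(imfset: IMFSet,
                      selection: tuple[int, ...]) -> tuple[int, ...]:
    """Clip a printed selection to the modes a decomposition produced."""
    avail = tuple(i for i in selection if i <= len(imfset.modes))
    return avail if avail else tuple(range(1, len(imfset.modes) + 1))


def apply_filter(x: np.ndarray, config: FilterConfig,
                 fs: float) -> np.ndarray:
    """Run the configured algorithm on ``x``; same-length output."""
    a = config.algorithm
    if a == "SG":
        return savgol_smooth(x, config.window_length, config.poly_order)
    if a == "FIR":
        return fir_bandpass(x, config.filter_order, config.band, fs)
    if a == "AWT":
        return awt_denoise(x, config.wavelet, config.levels)
    if a == "MODWT":
        return modwt_denoise(x, config.wavelet, config.levels)
    if a == "VMD":
        imfset = vmd_decompose(x, n_modes=config.n_modes,
                               bandwidth_alpha=config.vmd_alpha)
    elif a == "EMD":
        imfset = emd_decompose(x, max_imfs=config.max_imfs)
    elif a == "EEMD":
        imfset = eemd_decompose(x, n_trials=config.n_trials,
                                noise_std=config.noise_std, seed=config.seed,
                                max_imfs=config.max_imfs)
    else:  # CEEMDAN
        imfset = ceemdan_decompose(x, n_trials=config.n_trials,
                                   noise_std=config.noise_std,
                                   seed=config.seed, max_imfs=config.max_imfs)
    if len(imfset.modes) == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    return reconstruct_from_imfs(imfset,
                                 _select_available(imfset,
                                                   config.imf_selection))
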