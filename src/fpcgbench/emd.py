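"""Empirical mode decomposition and its ensemble variants.

Plain EMD sifts intrinsic mode functions (IMFs) out of a signal by
repeatedly subtracting the mean of cubic-spline envelopes through the local
maxima and minima.  EEMD averages EMD modes over an ensemble of white-noise
perturbed copies of the input; CEEMDAN extracts modes sequentially, at each
stage perturbing the current residue with the matching EMD mode of paired
(+/-) noise realizations, which keeps the decomposition complete: the sum
of all modes plus the final residue reconstructs the input exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["emd", "eemd", "ceemdan"]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    dx = np.diff(x)
    sign = np.sign(dx)
    # propagate signs over zero-slope plateaus so plateau edges register
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    change = np.diff(sign)
    maxima = np.nonzero(change < 0)[0] + 1
    minima = np.nonzero(change > 0)[0] + 1
    return maxima, minima


def _mirrored_spline(idx: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through (idx, x[idx]) with end extrema mirrored past
    the boundaries, evaluated on 0..n-1."""
    t = idx.astype(float)
    v = x[idx]
    # mirror up to two extrema across each edge
    k = min(2, len(t) - 1)
    t_pre = -t[1:k + 1][::-1]
    v_pre = v[1:k + 1][::-1]
    t_post = 2 * (n - 1) - t[-k - 1:-1][::-1]
    v_post = v[-k - 1:-1][::-1]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    # guard against coincident knots after mirroring
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], vv[keep])(np.arange(n))


def _sift_once(h: np.ndarray) -> np.ndarray | None:
    """One sifting pass; None when too few extrema remain."""
    maxima, minima = _local_extrema(h)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    n = len(h)
    upper = _mirrored_spline(maxima, h, n)
    lower = _mirrored_spline(minima, h, n)
    return h - 0.5 * (upper + lower)


def _extract_imf(x: np.ndarray, sd_thresh: float,
                 max_siftings: int) -> np.ndarray | None:
    """Sift a single IMF out of ``x`` (None if ``x`` is already a residue)."""
    h = _sift_once(x)
    if h is None:
        return None
    for _ in range(max_siftings - 1):
        h_new = _sift_once(h)
        if h_new is None:
            break
        denom = np.sum(h ** 2) + 1e-300
        sd = float(np.sum((h - h_new) ** 2) / denom)
        h = h_new
        if sd < sd_thresh:
            break
    return h


def emd(x: np.ndarray, max_imfs: int = 10, sd_thresh: float = 0.2,
        max_siftings: int = 50) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``x`` into IMFs and a monotone/low-extrema residue.

    Returns ``(imfs, residue)`` with ``sum(imfs) + residue == x`` exactly
    (each IMF is subtracted from the running residue as extracted).
    """
    x = np.asarray(x, dtype=float)
    imfs: list[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        imf = _extract_imf(residue, sd_thresh, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return imfs, residue


def _pad_stack(per_trial: list[list[np.ndarray]], n: int) -> np.ndarray:
    """Stack ragged per-trial IMF lists into (trials, modes, n), zero-padded."""
    k = max(len(tr) for tr in per_trial)
    out = np.zeros((len(per_trial), k, n))
    for i, tr in enumerate(per_trial):
        for j, m in enumerate(tr):
            out[i, j] = m
    return out


def eemd(x: np.ndarray, n_trials: int = 50, noise_std: float = 0.2,
         seed: int | None = None, max_imfs: int = 10,
         sd_thresh: float = 0.2) -> tuple[list[np.ndarray], np.ndarray]:
    """Ensemble EMD: average EMD modes over noise-perturbed copies.

    ``noise_std`` is the added white-noise standard deviation as a fraction
    of std(x).  ``noise_std = 0`` reduces exactly to plain EMD.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    x = np.asarray(x, dtype=float)
    if noise_std == 0:
        return emd(x, max_imfs=max_imfs, sd_thresh=sd_thresh)
    rng = np.random.default_rng(seed)
    eps = noise_std * float(np.std(x))
    trials, resids = [], []
    for _ in range(n_trials):
        noisy = x + eps * rng.standard_normal(len(x))
        imfs, res = emd(noisy, max_imfs=max_imfs, sd_thresh=sd_thresh)
        trials.append(imfs if imfs else [np.zeros_like(x)])
        resids.append(res)
    stacked = _pad_stack(trials, len(x))
    mean_imfs = list(stacked.mean(axis=0))
    return mean_imfs, np.mean(resids, axis=0)


def ceemdan(x: np.ndarray, n_trials: int = 50, noise_std: float = 0.2,
            seed: int | None = None, max_imfs: int = 10,
            sd_thresh: float = 0.2) -> tuple[list[np.ndarray], np.ndarray]:
    """Complete ensemble EMD with adaptive noise (paired realizations).

    Stage k perturbs the current residue with the k-th EMD mode of each of
    ``n_trials`` paired +/- white-noise realizations (scaled by
    ``noise_std`` times the residue's std) and averages the first sifted
    mode.  Modes are subtracted sequentially, so completeness holds exactly.
    ``noise_std = 0`` reduces to plain EMD.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    x = np.asarray(x, dtype=float)
    if noise_std == 0:
        return emd(x, max_imfs=max_imfs, sd_thresh=sd_thresh)

    rng = np.random.default_rng(seed)
    n = len(x)
    # paired +/- realizations, each decomposed once up front
    noise_modes: list[list[np.ndarray]] = []
    for _ in range(n_trials):
        w = rng.standard_normal(n)
        for signed in (w, -w):
            modes, _ = emd(signed, max_imfs=max_imfs, sd_thresh=sd_thresh)
            noise_modes.append(modes)

    imfs: list[np.ndarray] = []
    residue = x.copy()
    stage = 0
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break
        eps = noise_std * float(np.std(residue))
        first_modes = []
        for modes in noise_modes:
            if stage < len(modes):
                w_k = modes[stage]
                s = float(np.std(w_k))
                perturbed = residue + (eps / s) * w_k if s > 0 else residue
            else:
                perturbed = residue
            m = _extract_imf(perturbed, sd_thresh, max_siftings=50)
            first_modes.append(m if m is not None else np.zeros(n))
        imf = np.mean(first_modes, axis=0)
        if not np.any(imf):
            break
        imfs.append(imf)
        residue = residue - imf
        stage += 1
    return imfs, residue
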