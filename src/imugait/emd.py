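"""Empirical mode decomposition and drift-free integration.

Double-integrating trunk acceleration to get centre-of-mass displacement
accumulates low-frequency drift. The pipeline removes it by decomposing the
cumulative integral into intrinsic mode functions (IMFs) by EMD, scoring
each component's persistence with the rescaled-range Hurst exponent, and
discarding components with an exponent above a cutoff (default 0.8):
drift and slow trends are highly persistent (H near 1), genuine oscillatory
gait/sway content is not.

The decomposition is the classic sifting scheme: cubic-spline envelopes
through the local extrema, mean-envelope subtraction until a Cauchy-type
criterion is met, mirror extension of extrema at the edges to curb end
effects.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take midpoints)."""
    d = np.sign(np.diff(x))
    # collapse flat runs so plateau shoulders register as one extremum
    nz = d != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    d_filled = d.copy()
    last = 0.0
    for i in range(len(d_filled)):
        if d_filled[i] == 0:
            d_filled[i] = last
        else:
            last = d_filled[i]
    dd = np.diff(d_filled)
    maxima = np.where(dd < 0)[0] + 1
    minima = np.where(dd > 0)[0] + 1
    return maxima, minima


def _mirror_envelope(x: np.ndarray, idx: np.ndarray, n: int, n_mirror: int = 2) -> CubicSpline:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    t = idx.astype(float)
    v = x[idx]
    left_t = 2 * t[0] - t[1 : n_mirror + 1][::-1] if len(t) > 1 else np.array([-1.0])
    left_v = v[1 : n_mirror + 1][::-1] if len(t) > 1 else v[:1]
    right_t = 2 * t[-1] - t[-n_mirror - 1 : -1][::-1] if len(t) > 1 else np.array([float(n)])
    right_v = v[-n_mirror - 1 : -1][::-1] if len(t) > 1 else v[-1:]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], vv[keep])


def emd(
    x: np.ndarray,
    max_imfs: int = 12,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> np.ndarray:
    """Decompose ``x`` into IMFs plus a residual.

    Returns an array of shape (n_components, len(x)) whose rows sum to
    ``x``; the last row is the residual. Sifting of each mode stops when
    the normalised squared change between iterations (Cauchy criterion)
    drops below ``sd_threshold``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    grid = np.arange(n)
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 3:
            break
        h = residual.copy()
        for _ in range(max_siftings):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _mirror_envelope(h, maxima, n)(grid)
            lower = _mirror_envelope(h, minima, n)(grid)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h**2)
            sd = np.sum(mean_env**2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    imfs.append(residual)
    return np.vstack(imfs)


def hurst_exponent(x: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst exponent estimate.

    Windows are log-spaced between 8 samples and n/2; the exponent is the
    slope of log(R/S) against log(window). Near 0.5 for white noise, near
    1 for trends, below 0.5 for anti-persistent series. A constant series
    returns 1.0 by convention (a pure trend).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 64:
        raise ValueError("Hurst estimation requires at least 64 samples")
    if np.ptp(x) == 0:
        return 1.0
    sizes = np.unique(np.floor(np.logspace(np.log10(8), np.log10(n // 2), 12)).astype(int))
    log_rs, log_w = [], []
    for w in sizes:
        k = n // w
        if k < 1:
            continue
        segs = x[: k * w].reshape(k, w)
        means = segs.mean(axis=1, keepdims=True)
        z = np.cumsum(segs - means, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = segs.std(axis=1, ddof=0)
        ok = s > 0
        if not ok.any():
            continue
        rs = np.mean(r[ok] / s[ok])
        if rs > 0:
            log_rs.append(np.log(rs))
            log_w.append(np.log(w))
    if len(log_rs) < 2:
        return 1.0
    slope = np.polyfit(log_w, log_rs, 1)[0]
    return float(np.clip(slope, 0.0, 1.2))


def emd_drift_free_integral(
    x: np.ndarray,
    fs: float,
    hurst_cutoff: float = 0.8,
    return_removed: bool = False,
):
    """Cumulatively integrate ``x`` and strip drift by EMD + Hurst pruning.

    The cumulative trapezoidal integral is decomposed into IMFs; every
    component (including the residual) with Hurst exponent above
    ``hurst_cutoff`` is removed and the remainder summed. If EMD yields no
    usable decomposition the function falls back to subtracting a 2nd-order
    polynomial trend, with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * fs:
        raise ValueError("drift-free integration requires at least 4 seconds of signal")
    y = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    if np.ptp(y) == 0:
        out = y
        removed: list[int] = []
        return (out, removed) if return_removed else out
    try:
        comps = emd(y)
    except Exception:  # pragma: no cover - defensive
        comps = None
    if comps is None or comps.shape[0] < 2:
        warnings.warn("EMD produced no decomposition; falling back to polynomial detrend")
        t = np.arange(len(y))
        out = y - np.polyval(np.polyfit(t, y, 2), t)
        removed = []
        return (out, removed) if return_removed else out
    removed = []
    kept = np.zeros_like(y)
    for i, comp in enumerate(comps):
        try:
            h = hurst_exponent(comp)
        except ValueError:
            h = 1.0
        if h > hurst_cutoff:
            removed.append(i)
        else:
            kept += comp
    if len(removed) == comps.shape[0]:
        # everything classified as trend: keep the highest-frequency IMF so the
        # output is not identically zero
        removed = removed[1:]
        kept = comps[0]
    return (kept, removed) if return_removed else kept
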