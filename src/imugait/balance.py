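"""Static postural-balance features from AP/ML trunk acceleration.

Each quiet-standing condition of the Berg Balance Scale yields 23 features
from the unfiltered, gravity-free anteroposterior and mediolateral
accelerations: per-axis spectral descriptors (F50 %, F95 %, spectral
centroid), per-axis time-domain descriptors (maximum, mean and RMS of the
rectified signal, jerk, mean sway velocity, total acceleration path) and
the geometry of the covariance ellipse covering 95 % of the planar sway
(area, both principal-axis lengths, and each axis' angle to its anatomical
direction).

Spectral features use a plain one-sided periodogram with the DC bin
excluded and no taper (a rectangular window keeps line spectra exact).
The ellipse semi-axes are sqrt(q * lambda_i) with lambda_i the covariance
eigenvalues and q the chi-square(2 dof) quantile at the coverage
probability (5.991 at 95 %); a small-sample F-statistic scaling is
available as an option.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.signal import periodogram

from .config import PipelineConfig, DEFAULT_CONFIG
from .emd import emd_drift_free_integral

#: Ordered names of the 23 per-condition balance features.
BALANCE_FEATURE_NAMES = (
    "F50_AP", "F50_ML", "F95_AP", "F95_ML", "SC_AP", "SC_ML",
    "MaxAcc_AP", "MaxAcc_ML", "MeanAcc_AP", "MeanAcc_ML", "RMS_AP", "RMS_ML",
    "EllipseAngle_AP", "EllipseAngle_ML", "EllipseArea",
    "EllipseAxis_AP", "EllipseAxis_ML",
    "Jerk_AP", "Jerk_ML", "SwayV_AP", "SwayV_ML", "SPathA_AP", "SPathA_ML",
)

BALANCE_FEATURE_UNITS = {
    "F50": "Hz", "F95": "Hz", "SC": "Hz",
    "MaxAcc": "m/s^2", "MeanAcc": "m/s^2", "RMS": "m/s^2",
    "EllipseAngle": "deg", "EllipseArea": "m^2/s^4", "EllipseAxis": "m/s^2",
    "Jerk": "m/s^3", "SwayV": "m/s", "SPathA": "m/s^2",
}


def spectral_features(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(F50, F95, SC) of a zero-mean series.

    F50/F95 are the smallest frequencies at which the cumulative one-sided
    power reaches 50 %/95 % of the total; SC is the power-weighted mean
    frequency. An all-zero signal has no spectrum and returns NaNs.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * fs:
        raise ValueError("spectral features require at least 4 seconds of signal")
    x = x - x.mean()
    if np.ptp(x) == 0:
        return (np.nan, np.nan, np.nan)
    f, p = periodogram(x, fs=fs, window="boxcar", detrend=False)
    f, p = f[1:], p[1:]  # exclude DC
    total = p.sum()
    if total <= 0:
        return (np.nan, np.nan, np.nan)
    cum = np.cumsum(p) / total
    # tolerance so exact ties (e.g. two equal-power lines) resolve to the
    # lower frequency
    f50 = float(f[np.searchsorted(cum, 0.50 - 1e-9)])
    f95 = float(f[np.searchsorted(cum, 0.95 - 1e-9)])
    sc = float((f * p).sum() / total)
    return f50, f95, sc


def time_features(
    x: np.ndarray, fs: float, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[float, float, float, float, float, float]:
    """(MaxAcc, MeanAcc, RMS, Jerk, SwayV, SPathA) of one sway axis.

    Computed on the mean-subtracted signal: max and mean of the rectified
    signal, RMS, jerk as the RMS (or mean absolute, by config) of the
    central-difference derivative, mean sway velocity as the mean absolute
    drift-free integral, and the total acceleration path as the summed
    absolute first difference.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("time features require at least 2 samples")
    x = x - x.mean()
    max_acc = float(np.max(np.abs(x)))
    mean_acc = float(np.mean(np.abs(x)))
    rms = float(np.sqrt(np.mean(x**2)))
    deriv = np.gradient(x) * fs
    jerk = float(np.mean(np.abs(deriv))) if config.jerk_mean_absolute else float(
        np.sqrt(np.mean(deriv**2))
    )
    if np.ptp(x) == 0:
        sway_v = 0.0
    elif len(x) >= 4 * fs:
        vel = emd_drift_free_integral(x, fs, config.hurst_cutoff)
        sway_v = float(np.mean(np.abs(vel)))
    else:
        from scipy.integrate import cumulative_trapezoid
        from scipy.signal import detrend

        vel = detrend(cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0))
        sway_v = float(np.mean(np.abs(vel)))
    spath = float(np.sum(np.abs(np.diff(x))))
    return max_acc, mean_acc, rms, jerk, sway_v, spath


def ellipse_features(
    a_ap: np.ndarray,
    a_ml: np.ndarray,
    coverage: float = 0.95,
    use_f_statistic: bool = False,
) -> dict[str, float]:
    """Coverage-ellipse geometry of the planar (AP, ML) sway.

    Eigendecomposition of the 2x2 sample covariance gives principal
    directions; semi-axes are sqrt(q * lambda_i). Axes are matched to the
    anatomical direction their eigenvector is closest to; the angle
    reported for each axis is the acute angle (degrees) between that
    eigenvector and its anatomical direction. Rank-deficient sway gives a
    zero minor axis and zero area with a warning.
    """
    a_ap = np.asarray(a_ap, dtype=float)
    a_ml = np.asarray(a_ml, dtype=float)
    if len(a_ap) != len(a_ml) or len(a_ap) < 10:
        raise ValueError("ellipse features require equal-length series of >= 10 samples")
    n = len(a_ap)
    cov = np.cov(np.vstack([a_ap, a_ml]))
    lam, vec = np.linalg.eigh(cov)          # ascending eigenvalues
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 1e-30 * max(lam[1], 1.0):
        warnings.warn("rank-deficient sway covariance; ellipse degenerates to a line")
    if use_f_statistic:
        q = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(coverage, 2, n - 2)
    else:
        q = stats.chi2.ppf(coverage, df=2)
    semi = np.sqrt(q * lam)
    area = float(np.pi * semi[0] * semi[1])

    # eigenvector order: rows of `vec.T` correspond to lam; component 0 is AP
    v_major, v_minor = vec[:, 1], vec[:, 0]
    # match each eigenvector to the anatomical axis it is closest to
    if abs(v_major[0]) >= abs(v_major[1]):
        v_ap, a_ap_len = v_major, 2 * semi[1]
        v_ml, a_ml_len = v_minor, 2 * semi[0]
    else:
        v_ap, a_ap_len = v_minor, 2 * semi[0]
        v_ml, a_ml_len = v_major, 2 * semi[1]
    ang_ap = np.degrees(np.arccos(np.clip(abs(v_ap[0]), 0, 1)))
    ang_ml = np.degrees(np.arccos(np.clip(abs(v_ml[1]), 0, 1)))
    return {
        "EllipseArea": area,
        "EllipseAxis_AP": float(a_ap_len),
        "EllipseAxis_ML": float(a_ml_len),
        "EllipseAngle_AP": float(ang_ap),
        "EllipseAngle_ML": float(ang_ml),
    }


def bbs_condition_features(
    a_ap: np.ndarray,
    a_ml: np.ndarray,
    fs: float,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """All 23 balance features for one static condition.

    Uses the unfiltered gravity-free AP/ML accelerations. A window shorter
    than 5 s is skipped (every feature NaN); a flat window yields zero
    time-domain features and missing spectral features, but always the full
    23 named slots.
    """
    out = {name: np.nan for name in BALANCE_FEATURE_NAMES}
    a_ap = np.asarray(a_ap, dtype=float)
    a_ml = np.asarray(a_ml, dtype=float)
    if len(a_ap) < 5 * fs:
        warnings.warn("static window shorter than 5 s; condition skipped")
        return out
    for axis, x in (("AP", a_ap), ("ML", a_ml)):
        try:
            f50, f95, sc = spectral_features(x, fs)
        except ValueError:
            f50 = f95 = sc = np.nan
        out[f"F50_{axis}"], out[f"F95_{axis}"], out[f"SC_{axis}"] = f50, f95, sc
        mx, mn, rms, jerk, swv, sp = time_features(x, fs, config)
        out[f"MaxAcc_{axis}"] = mx
        out[f"MeanAcc_{axis}"] = mn
        out[f"RMS_{axis}"] = rms
        out[f"Jerk_{axis}"] = jerk
        out[f"SwayV_{axis}"] = swv
        out[f"SPathA_{axis}"] = sp
    if np.ptp(a_ap) == 0 and np.ptp(a_ml) == 0:
        out.update(
            EllipseArea=0.0, EllipseAxis_AP=0.0, EllipseAxis_ML=0.0,
            EllipseAngle_AP=0.0, EllipseAngle_ML=0.0,
        )
    else:
        out.update(
            ellipse_features(
                a_ap - a_ap.mean(), a_ml - a_ml.mean(),
                coverage=config.ellipse_coverage,
                use_f_statistic=config.ellipse_use_f_statistic,
            )
        )
    return out
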