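"""Inverted-pendulum step-length estimation.

During walking the body's centre of mass vaults over the stance leg like an
inverted pendulum, rising and falling by h each step. With pendulum length
L (lower-back sensor to ground), geometry gives the uncorrected step length

    Lhat_step = 2 * sqrt(2*L*h - h^2).

The rigid-pendulum assumption systematically mis-estimates true step
length, so a calibrated linear correction in shoe size S is added:

    L_step = Lhat_step + K * S,

where K is fitted per speed condition by least squares against a gold
standard, K = (S'S)^-1 S'(L* - Lhat). The shipped defaults (K = 1.13 at
self-selected speed, 1.50 at fast speed) are healthy-cohort values and are
known not to transfer to impaired gait; recalibrate for any new cohort.
K absorbs whatever unit the cohort's shoe sizes are recorded in.

h is obtained per step as the peak-to-trough excursion of the vertical
displacement, itself the EMD-drift-free double integral of the vertical
acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .emd import emd_drift_free_integral
from .events import GaitEvents


class ModelError(ValueError):
    """The pendulum geometry is violated (h >= L or negative radicand)."""


@dataclass
class StepLengthModel:
    """Pendulum length, correction constant and shoe size for one subject."""

    L: float
    K: float
    S: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ModelError("pendulum length L must be positive")


@dataclass
class VerticalExcursion:
    """Drift-free vertical velocity/displacement and per-step height change."""

    v_v: np.ndarray
    disp: np.ndarray
    h: np.ndarray                 # per-step CoM height change (m), NaN if undefined
    hurst_removed_v: list
    hurst_removed_d: list


def vertical_excursion(
    av: np.ndarray,
    fs: float,
    events: GaitEvents,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> VerticalExcursion:
    """Double-integrate vertical acceleration with drift removal at each stage.

    Velocity is the drift-free integral of the acceleration, displacement
    the drift-free integral of that velocity; per-step h is the
    peak-to-trough displacement inside each inter-contact interval.
    """
    v_v, rem_v = emd_drift_free_integral(av, fs, config.hurst_cutoff, return_removed=True)
    disp, rem_d = emd_drift_free_integral(v_v, fs, config.hurst_cutoff, return_removed=True)
    h = step_height(disp, events, fs)
    return VerticalExcursion(v_v, disp, h, rem_v, rem_d)


def step_height(disp: np.ndarray, events: GaitEvents, fs: float) -> np.ndarray:
    """Per-step peak-to-trough vertical displacement (m).

    h(i) = max(disp) - min(disp) on [tIC(i), tIC(i+1)); steps whose window
    holds fewer than 3 samples get NaN. The last contact has no following
    contact, so the result has n_steps - 1 entries.
    """
    disp = np.asarray(disp, dtype=float)
    tic = events.t_ic
    out = np.full(max(len(tic) - 1, 0), np.nan)
    for i in range(len(tic) - 1):
        lo = int(np.round(tic[i] * fs))
        hi = int(np.round(tic[i + 1] * fs)) + 1
        seg = disp[lo:hi]
        if len(seg) >= 3:
            out[i] = float(seg.max() - seg.min())
    return out


def pendulum_step_length(h, L: float):
    """Uncorrected inverted-pendulum step length 2*sqrt(2*L*h - h^2).

    Accepts a scalar or array h; h must lie in [0, L). NaN entries pass
    through as NaN.
    """
    h_arr = np.asarray(h, dtype=float)
    valid = ~np.isnan(h_arr)
    if np.any((h_arr[valid] < 0) | (h_arr[valid] >= L)):
        raise ModelError("step height h must lie in [0, L)")
    rad = 2.0 * L * h_arr - h_arr**2
    out = 2.0 * np.sqrt(rad)
    return float(out) if np.isscalar(h) else out


def corrected_step_length(h, L: float, K: float, S: float):
    """Final step length Lhat + K*S (m)."""
    base = pendulum_step_length(h, L)
    return base + K * S


def step_velocity(step_length, step_time):
    """Per-step velocity V(i) = L_step(i) / T_step(i) (m/s)."""
    return np.asarray(step_length, dtype=float) / np.asarray(step_time, dtype=float)


def calibrate_k(l_true, l_hat, shoe_size) -> float:
    """Least-squares correction constant K = (S'S)^-1 S'(L* - Lhat).

    Vectors run over the pooled steps (or subjects) of one speed
    condition. Raises on degenerate designs (all shoe sizes zero).
    """
    l_true = np.asarray(l_true, dtype=float)
    l_hat = np.asarray(l_hat, dtype=float)
    s = np.asarray(shoe_size, dtype=float)
    if not (len(l_true) == len(l_hat) == len(s)):
        raise ValueError("calibration vectors must have equal length")
    if len(s) < 2:
        raise ValueError("calibration requires at least 2 entries")
    sts = float(s @ s)
    if sts == 0:
        raise ValueError("degenerate design: shoe-size vector is all zeros")
    return float(s @ (l_true - l_hat) / sts)
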