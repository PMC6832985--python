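"""Gait-event detection from preprocessed vertical acceleration.

Initial contacts (heel strikes, IC) and end contacts (toe-offs, EC) are
found with a continuous wavelet transform scheme: the 10 Hz low-passed,
gravity-free vertical acceleration is cumulatively integrated, then
smooth-differentiated by a CWT with the first Gaussian-derivative wavelet
(gaus1) — the local minima of that output are IC candidates. Differentiating
again with the second Gaussian derivative (gaus2, the Mexican hat) yields
maxima that are EC candidates. EC peaks at or below 20 % of the mean peak
magnitude are discarded, and a candidate IC closer than 0.25 s or farther
than 2.25 s from the previous retained IC is treated as false and removed.
The wavelet scale is set from the dominant step frequency through
scale = Fc * fs / f_dom, where Fc is the wavelet centre frequency.

The 2 Hz low-passed yaw assigns alternating side labels: trunk rotation
about the vertical axis changes sign with the swinging leg, so the sign of
filtered yaw at each IC separates the two sides. Labels are abstract
{A, B}; mapping onto {left, right} is a configuration choice because the
device sign convention is not knowable from the data alone.

Temporal gait parameters follow the standard per-cycle definitions:
stance(i) = tEC(i+1) - tIC(i), stride(i) = tIC(i+2) - tIC(i),
step(i) = tIC(i+1) - tIC(i), swing(i) = stride(i) - stance(i); the step
count is the number of initial contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable
import warnings

import numpy as np
import pandas as pd
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import argrelextrema, periodogram

from .config import PipelineConfig, DEFAULT_CONFIG


@dataclass
class GaitEvents:
    """Ordered contact events for one walking window."""

    t_ic: np.ndarray
    t_ec: np.ndarray
    side: np.ndarray  # per-IC labels in {"A", "B"}
    f_dom: float = np.nan
    scale_ic: float = np.nan
    scale_ec: float = np.nan

    def __post_init__(self) -> None:
        self.t_ic = np.asarray(self.t_ic, dtype=float)
        self.t_ec = np.asarray(self.t_ec, dtype=float)
        self.side = np.asarray(self.side, dtype=object)

    @property
    def n_steps(self) -> int:
        """Step count = number of initial contacts."""
        return len(self.t_ic)

    def shifted(self, dt: float) -> "GaitEvents":
        return GaitEvents(self.t_ic + dt, self.t_ec + dt, self.side.copy(),
                          self.f_dom, self.scale_ic, self.scale_ec)

    def to_frame(self) -> pd.DataFrame:
        n = max(len(self.t_ic), len(self.t_ec))
        pad = lambda a: np.concatenate([a, np.full(n - len(a), np.nan)])
        side = np.concatenate([self.side, np.full(n - len(self.side), None)])
        return pd.DataFrame({"t_ic": pad(self.t_ic), "t_ec": pad(self.t_ec), "side": side})


@dataclass
class TemporalParams:
    """Per-cycle temporal gait parameters (seconds)."""

    t_stance: np.ndarray
    t_stride: np.ndarray
    t_step: np.ndarray
    t_swing: np.ndarray
    n_steps: int
    step_side: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def dominant_frequency(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 5.0)
) -> float:
    """Frequency of maximum power spectral density within ``band`` (Hz)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("dominant_frequency requires at least 2 seconds of signal")
    f, p = periodogram(x - x.mean(), fs=fs)
    m = (f >= band[0]) & (f <= band[1])
    if not m.any() or not np.any(p[m] > 0):
        return float(np.mean(band))
    return float(f[m][np.argmax(p[m])])


def scale_from_frequency(wavelet: str, fs: float, f_dom: float) -> float:
    """Default scale-selection strategy: scale = Fc * fs / f_dom."""
    return pywt.central_frequency(wavelet) * fs / f_dom


def _cwt_derivative(x: np.ndarray, scale: float, wavelet: str, fs: float) -> np.ndarray:
    """Smooth-differentiate ``x`` via a single-scale CWT.

    The raw correlation sign is kept: for the odd gaus1 kernel the output
    approximates -d/dt of the Gaussian-smoothed signal, which is the
    convention under which local minima of the differentiated vertical
    velocity coincide with the upward heel-strike acceleration peaks.
    """
    coef, _ = pywt.cwt(x, [scale], wavelet, sampling_period=1.0 / fs)
    return coef[0]


def detect_contacts(
    av_f: np.ndarray,
    fs: float,
    config: PipelineConfig = DEFAULT_CONFIG,
    scale_strategy: Callable[[str, float, float], float] = scale_from_frequency,
    f_dom: float | None = None,
) -> GaitEvents:
    """Detect IC/EC events in a preprocessed vertical-acceleration window.

    Event times are in seconds relative to the start of the window. The
    wavelet scales follow the dominant step frequency, estimated from the
    window itself unless ``f_dom`` is supplied (useful for windows too
    short for a reliable spectrum, e.g. turning intervals). When no initial
    contacts survive the pruning rules an empty result is returned with a
    warning rather than raising, so that callers can keep processing the
    rest of a session.
    """
    av_f = np.asarray(av_f, dtype=float)
    if len(av_f) < 4 or np.ptp(av_f) == 0:
        return GaitEvents(np.array([]), np.array([]), np.array([], dtype=object))
    if f_dom is None:
        try:
            f_dom = dominant_frequency(av_f, fs, config.dominant_band_hz)
        except ValueError:
            warnings.warn("window too short for dominant-frequency estimation; no events")
            return GaitEvents(np.array([]), np.array([]), np.array([], dtype=object))

    scale_ic = scale_strategy("gaus1", fs, f_dom)
    scale_ec = scale_strategy("gaus2", fs, f_dom)

    v = cumulative_trapezoid(av_f, dx=1.0 / fs, initial=0.0)
    # an IC/EC extremum must dominate a neighbourhood of about a third of
    # the step period; this keeps one extremum per step at any cadence while
    # rejecting ripples much faster than the gait rhythm
    order = max(2, int(round(0.35 * fs / f_dom)))
    d1 = _cwt_derivative(v, scale_ic, "gaus1", fs)
    ic_idx = argrelextrema(d1, np.less, order=order)[0]

    d2 = _cwt_derivative(d1, scale_ec, "gaus2", fs)
    ec_idx = argrelextrema(d2, np.greater, order=order)[0]

    # EC peak rule: keep only peaks above 20 % of the mean peak magnitude
    if len(ec_idx):
        mags = np.abs(d2[ec_idx])
        ec_idx = ec_idx[mags > config.ec_peak_fraction * mags.mean()]

    # drop events inside the edge-guard band (wavelet edge effects)
    guard = config.edge_guard_s
    t_all = np.arange(len(av_f)) / fs
    t_max = t_all[-1]
    ic_idx = ic_idx[(t_all[ic_idx] >= guard) & (t_all[ic_idx] <= t_max - guard)]
    ec_idx = ec_idx[(t_all[ec_idx] >= guard) & (t_all[ec_idx] <= t_max - guard)]

    # false-IC pruning, greedy left to right: trust the earliest IC, drop any
    # subsequent IC whose lag from the previous retained IC is out of range
    t_ic: list[float] = []
    for i in ic_idx:
        ti = t_all[i]
        if t_ic:
            lag = ti - t_ic[-1]
            if lag < config.ic_min_gap_s or lag > config.ic_max_gap_s:
                continue
        t_ic.append(ti)
    t_ic_arr = np.asarray(t_ic)

    # pair each IC with the subsequent EC
    t_ec_all = t_all[ec_idx]
    t_ec: list[float] = []
    for ti in t_ic_arr:
        later = t_ec_all[t_ec_all > ti]
        if len(later):
            t_ec.append(float(later[0]))
    t_ec_arr = np.unique(t_ec)

    if len(t_ic_arr) == 0:
        warnings.warn("no initial contacts detected in window")
    side = np.array(["A"] * len(t_ic_arr), dtype=object)
    return GaitEvents(t_ic_arr, t_ec_arr, side, f_dom, scale_ic, scale_ec)


def assign_sides(
    events: GaitEvents, yaw_f: np.ndarray, fs: float
) -> GaitEvents:
    """Label each IC with a side from the sign of 2 Hz low-passed yaw.

    side = A where yaw_f at the IC is >= 0, else B. If more than 20 % of
    consecutive labels fail to alternate, labels are replaced by forced
    alternation seeded from the majority-consistent start (trunk yaw can be
    weak or noisy in slow gait; strict alternation is the physiological
    prior).
    """
    yaw_f = np.asarray(yaw_f, dtype=float)
    if events.n_steps == 0:
        return events
    idx = np.clip(np.round(events.t_ic * fs).astype(int), 0, len(yaw_f) - 1)
    labels = np.where(yaw_f[idx] >= 0, "A", "B").astype(object)
    if events.n_steps >= 2:
        violations = np.mean(labels[1:] == labels[:-1])
        if violations > 0.20:
            counts = {"A": 0, "B": 0}
            for i, lab in enumerate(labels):
                expect_even = lab  # label consistent with starting at lab
                if i % 2 == 0:
                    counts[lab] += 1
                else:
                    counts["B" if lab == "A" else "A"] += 1
            start = "A" if counts["A"] >= counts["B"] else "B"
            other = "B" if start == "A" else "A"
            labels = np.array(
                [start if i % 2 == 0 else other for i in range(events.n_steps)],
                dtype=object,
            )
    return GaitEvents(events.t_ic, events.t_ec, labels,
                      events.f_dom, events.scale_ic, events.scale_ec)


def temporal_params(events: GaitEvents) -> TemporalParams:
    """Per-cycle stance/stride/step/swing times from the event lists.

    Requires at least 3 ICs and 2 ECs; otherwise returns empty parameter
    arrays (with the step count still reported).
    """
    tic, tec = events.t_ic, events.t_ec
    n_steps = len(tic)
    empty = np.array([])
    if len(tic) < 3 or len(tec) < 2:
        return TemporalParams(empty, empty, empty, empty, n_steps)
    n_cycles = min(len(tic) - 2, len(tec) - 1)
    i = np.arange(n_cycles)
    t_stance = tec[i + 1] - tic[i]
    t_stride = tic[i + 2] - tic[i]
    t_step = tic[i + 1] - tic[i]
    t_swing = t_stride - t_stance
    side = events.side[:n_cycles] if len(events.side) >= n_cycles else events.side
    return TemporalParams(t_stance, t_stride, t_step, t_swing, n_steps, side)
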