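"""Synthetic lumbar-IMU signal generators with exact ground truth.

No public dataset accompanies the algorithms, so every detector in this
package is validated against generated signals whose events are known by
construction:

* walking -- the vertical centre-of-mass displacement is a train of smooth
  per-step arches (height h per step, minima at the programmed initial
  contacts), its second derivative gives the vertical acceleration, a short
  Ricker-shaped transient is added at each heel strike, and yaw oscillates
  at half the step frequency phase-locked to the stepping side;
* quiet standing -- band-limited planar Gaussian sway with the sample
  covariance driven exactly to a programmed matrix;
* timed-up-and-go -- scripted Hann-shaped pitch bursts at the sit-stand
  transitions, yaw bursts at the turns, and walking segments generated by
  the walking model in between.

Everything is assembled back into the sensor frame (units g and deg/s,
gravity and a programmed static tilt included) so the generated recordings
exercise the full preprocessing chain. All generators are deterministic in
their seed. Transition onsets in the ground truth are defined at a fixed
fraction of the peak angular velocity (10 % for sit-stand transitions,
15 % for turns), the standard movement-onset convention also used by the
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .config import GRAVITY_MS2, PipelineConfig, DEFAULT_CONFIG
from .preprocess import Annotation, RawRecording, SubjectMeta


@dataclass
class GroundTruth:
    """Programmed truth accompanying a generated recording."""

    t_ic: np.ndarray = field(default_factory=lambda: np.array([]))
    t_ec: np.ndarray = field(default_factory=lambda: np.array([]))
    side: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    step_h: np.ndarray = field(default_factory=lambda: np.array([]))
    step_length: np.ndarray = field(default_factory=lambda: np.array([]))
    f_step: float = np.nan
    disp: Optional[np.ndarray] = None
    sway_cov: Optional[np.ndarray] = None
    sway_band: Optional[tuple] = None
    tug_phases: Optional[dict] = None      # phase -> (t_i, t_ii, t_iii)
    tug_peaks: Optional[dict] = None       # phase -> peak angular velocity
    walk_step_count: Optional[int] = None
    turn_step_counts: Optional[dict] = None
    duration: float = np.nan


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3 - 2 * u)


def _ricker(t: np.ndarray, sigma: float) -> np.ndarray:
    z = (t / sigma) ** 2
    return (1 - z) * np.exp(-z / 2)


def _sensor_frame(
    aAP: np.ndarray, aML: np.ndarray, aV: np.ndarray,
    theta_x: float, theta_z: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map anatomical dynamic accelerations (m/s^2) to sensor axes (g).

    Exact algebraic inverse of the two-rotation tilt correction, with
    gravity added to the vertical channel.
    """
    g_ap, g_ml = aAP / GRAVITY_MS2, aML / GRAVITY_MS2
    g_v = aV / GRAVITY_MS2 + 1.0
    sx, cx = np.sin(theta_x), np.cos(theta_x)
    sz, cz = np.sin(theta_z), np.cos(theta_z)
    ax = -cx * g_ml + sx * g_v
    a_prov = sx * g_ml + cx * g_v
    az = sz * a_prov - cz * g_ap
    ay = cz * a_prov + sz * g_ap
    return ax, ay, az


def _walk_profile(
    t: np.ndarray,
    t_ic: np.ndarray,
    h_per_step: np.ndarray,
    f_step: float,
    hs_amp: float,
    hs_sigma: float,
):
    """Displacement, vertical acceleration and yaw for a walking bout.

    The displacement is a train of sin^2 arches, one per step interval,
    vanishing with zero slope at every initial contact; the vertical
    acceleration is its (analytic) second derivative plus a Ricker-shaped
    heel-strike transient at each contact. Each run of consecutive contacts
    additionally gets a lead arch over the step period preceding its first
    contact (the step that brought the walker into the bout), so every
    counted contact is a two-sided displacement minimum. Yaw alternates at
    half the step frequency, positive at even-indexed contacts (side A).
    """
    disp = np.zeros_like(t)
    av = np.zeros_like(t)
    period = 1.0 / f_step

    def _arch(ta: float, tb: float, h: float) -> None:
        """One mid-stance arch: disp rises 0 -> h -> 0 over [ta, tb)."""
        T = tb - ta
        u = (t - ta) / T
        m = (u >= 0) & (u < 1)
        disp[m] += h * np.sin(np.pi * u[m]) ** 2
        # d^2/dt^2 [ h sin^2(pi u / T) ] = h/2 (2 pi / T)^2 cos(2 pi u / T)
        av[m] += h * 0.5 * (2 * np.pi / T) ** 2 * np.cos(2 * np.pi * u[m])

    def _ramp(ta: float, tb: float, h: float, rising: bool, t_arch: float) -> None:
        """C^2 quintic blend between a plateau at h and a contact at zero.

        First and second derivatives vanish at the plateau end; at the
        contact end the curvature matches the adjacent arch's (2 pi^2
        h / t_arch^2), so the acceleration is continuous everywhere and the
        profile double-integrates back to the displacement cleanly. The
        blend is monotone, so it contributes no contact-like minima.
        """
        T = tb - ta
        # phi(u) = 1 + a3 u^3 + a4 u^4 + a5 u^5 with phi(1) = phi'(1) = 0
        # and phi''(1) = c (curvature of the neighbouring arch in u units)
        c = 2 * np.pi**2 * (T / t_arch) ** 2
        a5 = (c - 12) / 2
        a4 = 3 - 2 * a5
        a3 = -4 + a5
        u = (t - ta) / T
        m = (u >= 0) & (u < 1)
        # um runs plateau (0) -> contact (1)
        um = 1 - u[m] if rising else u[m]
        phi = 1 + a3 * um**3 + a4 * um**4 + a5 * um**5
        phi2 = (6 * a3 * um + 12 * a4 * um**2 + 20 * a5 * um**3) / T**2
        disp[m] += h * phi
        av[m] += h * phi2

    # split contacts into runs of consecutive steps
    runs: list[tuple[int, int]] = []
    start = 0
    for k in range(1, len(t_ic) + 1):
        if k == len(t_ic) or t_ic[k] - t_ic[k - 1] > 1.6 * period:
            runs.append((start, k - 1))
            start = k
    # arches between consecutive contacts (each stretched to its own
    # interval); runs are entered by descending from a standing plateau and
    # left by rising back to one
    spans: list[tuple[float, float, float, float]] = []
    for r, (a, b) in enumerate(runs):
        t0, t_last = t_ic[a], t_ic[b]
        gap_prev = t0 - t_ic[a - 1] if a > 0 else np.inf
        gap_next = t_ic[b + 1] - t_last if b + 1 < len(t_ic) else np.inf
        t_entry = min(0.5 * period, gap_prev / 2)
        t_exit = min(0.5 * period, gap_next / 2)
        arch_in = t_ic[a + 1] - t_ic[a] if b > a else period
        arch_out = t_ic[b] - t_ic[b - 1] if b > a else period
        _ramp(t0 - t_entry, t0, h_per_step[a], rising=False, t_arch=arch_in)
        for k in range(a, b):
            _arch(t_ic[k], t_ic[k + 1], h_per_step[k])
        _ramp(t_last, t_last + t_exit, h_per_step[b], rising=True, t_arch=arch_out)
        spans.append((t0 - t_entry, t_last + t_exit, h_per_step[a], h_per_step[b]))
    # plateau baseline outside the runs (blended linearly between levels)
    if spans:
        prev_end, prev_h = t[0], spans[0][2]
        for lead, trail, h_in, h_out in spans + [(t[-1] + 1, 0.0, prev_h, 0.0)]:
            m = (t >= prev_end) & (t < min(lead, t[-1] + 1))
            if m.any():
                if lead > prev_end:
                    disp[m] += prev_h + (h_in - prev_h) * (t[m] - prev_end) / (lead - prev_end)
                else:
                    disp[m] += prev_h
            prev_end, prev_h = trail, h_out
    for tk in t_ic:
        near = np.abs(t - tk) < 6 * hs_sigma
        av[near] += hs_amp * _ricker(t[near] - tk, hs_sigma)
    yaw = np.zeros_like(t)
    if len(t_ic):
        t0, t_last = t_ic[0], t_ic[-1]
        span = (t >= t0 - 1.0 / f_step) & (t <= t_last + 1.5 / f_step)
        yaw[span] = np.cos(np.pi * f_step * (t[span] - t0))
        ramp_in = _smoothstep((t - (t0 - 1.0 / f_step)) * f_step * 2)
        ramp_out = _smoothstep(((t_last + 1.5 / f_step) - t) * f_step * 2)
        yaw *= ramp_in * ramp_out
    return disp, av, yaw


def gen_walk(
    f_step: float = 1.8,
    n_steps: int = 20,
    h_amp: float = 0.05,
    L: float = 1.0,
    asym: float = 0.0,
    noise_sd: float = 0.08,
    seed: int = 0,
    fs: float = 31.25,
    tail_s: float = 0.1,
    yaw_amp: float = 10.0,
    hs_amp: float = 1.5,
    hs_sigma: float = 0.025,
    theta_x_deg: float = 2.0,
    theta_z_deg: float = 1.0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one straight-line walking trial.

    Defaults emulate a self-selected-speed walk: cadence 1.8 steps/s,
    5 cm centre-of-mass vertical excursion, modest sensor noise
    (0.08 m/s^2) and a small residual mounting tilt. ``asym`` scales the
    arch height of alternating steps by (1 +/- asym). Walking spans
    essentially the whole trial, as an annotated walking bout does: the
    lead-in step and the short tail after the last arch both lie inside
    the detector's edge-guard band.
    """
    if not (0.5 <= f_step <= 4.0):
        raise ValueError("f_step must lie in [0.5, 4] Hz")
    if not (0 < h_amp < L):
        raise ValueError("h_amp must lie in (0, L)")
    rng = np.random.default_rng(seed)
    # first counted contact: its entry ramp starts inside the 0.25 s guard
    t_first = 0.25 + 0.4 / f_step
    # snap contacts to the sample grid so truth is exact in samples
    t_ic = np.round((t_first + np.arange(n_steps) / f_step) * fs) / fs
    duration = t_ic[-1] + 0.5 / f_step + tail_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    h_per_step = h_amp * (1.0 + asym * (-1.0) ** np.arange(n_steps))
    disp, av, yaw_unit = _walk_profile(t, t_ic, h_per_step, f_step, hs_amp, hs_sigma)
    yaw = yaw_amp * yaw_unit

    ap = 0.6 * np.sin(2 * np.pi * f_step * t) * (disp > 1e-9)
    ml = 0.3 * np.sin(np.pi * f_step * t) * (disp > 1e-9)
    pitch = 4.0 * np.sin(2 * np.pi * f_step * t) * (disp > 1e-9)

    ax, ay, az = _sensor_frame(
        ap, ml, av, np.deg2rad(theta_x_deg), np.deg2rad(theta_z_deg)
    )
    g_noise = noise_sd / GRAVITY_MS2
    rec = RawRecording(
        t=t,
        ax=ax + rng.normal(0, g_noise, n),
        ay=ay + rng.normal(0, g_noise, n),
        az=az + rng.normal(0, g_noise, n),
        gx=pitch + rng.normal(0, 0.3, n),
        gy=yaw + rng.normal(0, 0.3, n),
        gz=rng.normal(0, 0.3, n),
        fs_nominal=fs,
    )
    # per-step truth: arch height and the uncorrected pendulum step length
    step_h = h_per_step.copy()
    step_len = 2.0 * np.sqrt(np.clip(2 * L * step_h - step_h**2, 0, None))
    side = np.array(["A" if k % 2 == 0 else "B" for k in range(n_steps)], dtype=object)
    t_ec = t_ic + 0.65 / f_step  # nominal toe-off times (not asserted anywhere)
    truth = GroundTruth(
        t_ic=t_ic, t_ec=t_ec, side=side, step_h=step_h, step_length=step_len,
        f_step=f_step, disp=disp, duration=duration,
    )
    return rec, truth


def gen_sway(
    cov: np.ndarray,
    band: tuple[float, float] = (0.1, 3.0),
    duration: float = 30.0,
    seed: int = 0,
    fs: float = 31.25,
    theta_x_deg: float = 1.0,
    theta_z_deg: float = 0.5,
    noise_sd: float = 0.0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate a quiet-standing trial with programmed planar sway.

    AP/ML accelerations are band-limited Gaussian noise whose *sample*
    covariance is driven exactly to ``cov`` (units (m/s^2)^2), so ellipse
    features have a closed-form expectation. A zero matrix produces a flat
    (gravity-only) recording.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise ValueError("cov must be a symmetric 2x2 matrix")
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals < -1e-12):
        raise ValueError("cov must be positive semi-definite")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    if np.all(eigvals <= 1e-15):
        ap = np.zeros(n)
        ml = np.zeros(n)
    else:
        from scipy.signal import butter, filtfilt

        white = rng.standard_normal((2, n))
        lo, hi = band
        b, a = butter(4, [lo, hi], btype="band", fs=fs)
        x = filtfilt(b, a, white, axis=1)
        x -= x.mean(axis=1, keepdims=True)
        sample_cov = np.cov(x)
        l_sample = np.linalg.cholesky(sample_cov)
        # allow rank-deficient targets via eigen square root
        w, v = np.linalg.eigh(cov)
        l_target = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
        y = l_target @ np.linalg.solve(l_sample, x)
        ap, ml = y[0], y[1]

    av = np.zeros(n)
    ax, ay, az = _sensor_frame(ap, ml, av, np.deg2rad(theta_x_deg), np.deg2rad(theta_z_deg))
    g_noise = noise_sd / GRAVITY_MS2
    rec = RawRecording(
        t=t,
        ax=ax + rng.normal(0, g_noise, n),
        ay=ay + rng.normal(0, g_noise, n),
        az=az + rng.normal(0, g_noise, n),
        gx=rng.normal(0, 0.1, n), gy=rng.normal(0, 0.1, n), gz=rng.normal(0, 0.1, n),
        fs_nominal=fs,
    )
    truth = GroundTruth(sway_cov=cov, sway_band=band, duration=duration)
    return rec, truth


@dataclass
class TugScript:
    """Phase plan for a scripted timed-up-and-go trial.

    Durations in seconds, angular-velocity peaks in deg/s. The plan is
    sit -> sit-to-stand -> walk -> turn -> walk -> turn -> stand-to-sit ->
    sit. Steps are placed inside the walk segments (and optionally inside
    the turns, as people step while turning).
    """

    sit_s: float = 1.5
    sts_s: float = 2.0
    sts_peak: float = 55.0
    walk_steps: int = 5
    f_step: float = 1.8
    turn_s: float = 2.2
    turn1_peak: float = 140.0
    turn2_peak: float = 130.0
    turn_steps: int = 2
    sts2_s: float = 2.0
    sts2_peak: float = -50.0
    sit_end_s: float = 1.5
    walk_margin_s: float = 0.45

    def validate(self) -> None:
        for name in ("sit_s", "sts_s", "turn_s", "sts2_s", "sit_end_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.walk_steps < 1:
            raise ValueError("walk_steps must be at least 1")
        if abs(self.turn1_peak) < 1 or abs(self.turn2_peak) < 1:
            raise ValueError("turn peaks must be nonzero")


def _hann_burst(t: np.ndarray, t0: float, dur: float, peak: float) -> np.ndarray:
    u = (t - t0) / dur
    out = np.zeros_like(t)
    m = (u >= 0) & (u <= 1)
    out[m] = peak * np.sin(np.pi * u[m]) ** 2
    return out


def _onset_offset(t0: float, dur: float, frac: float) -> tuple[float, float]:
    """Times where a Hann burst crosses ``frac`` of its peak."""
    x = np.arcsin(np.sqrt(frac)) / np.pi
    return t0 + x * dur, t0 + (1 - x) * dur


def _smoothed_burst_offset(
    t0: float, dur: float, peak: float, fs: float, frac: float
) -> float:
    """Offset landmark of a Hann burst after level-5 wavelet smoothing.

    The segmentation reads transition landmarks off the db5 level-5
    approximation of pitch, which broadens a burst and moves its fractional
    offset crossing later than on the scripted profile. The generator uses
    this smoothed offset to decide when walking resumes, mirroring how a
    subject's first step follows the *observable* end of standing up.
    """
    from .tug import dwt_approximation

    n = max(int(round((t0 + dur + 6.0) * fs)) + 1, int(round(12.0 * fs)))
    tt = np.arange(n) / fs
    mag = np.abs(dwt_approximation(_hann_burst(tt, t0, dur, peak), 5))
    pk = int(np.argmax(mag))
    thr = frac * mag[pk]
    i = pk
    while i < n - 1 and mag[i + 1] >= thr:
        i += 1
    return float(tt[i])


def gen_tug(
    script: TugScript | None = None,
    seed: int = 0,
    fs: float = 31.25,
    noise_sd: float = 0.06,
    h_amp: float = 0.04,
    hs_amp: float = 1.5,
    theta_x_deg: float = 2.0,
    theta_z_deg: float = 1.0,
    landmark_fraction: float = 0.10,
    turn_threshold: float = 0.15,
) -> tuple[RawRecording, GroundTruth]:
    """Generate a scripted timed-up-and-go trial.

    Ground-truth landmarks use the movement-onset convention: stage i/iii
    at the ``landmark_fraction`` (sit-stand transitions) or
    ``turn_threshold`` (turns) crossing of each burst's peak angular
    velocity, stage ii at the peak itself; walking phases span the gaps
    between the surrounding transitions.
    """
    script = script or TugScript()
    script.validate()
    rng = np.random.default_rng(seed)
    f = script.f_step
    period = 1.0 / f
    margin = script.walk_margin_s        # contact clearance from phase boundaries

    def _snap(x):
        return np.round(np.asarray(x) * fs) / fs

    def _cross(frac: float) -> float:
        """Fraction of a Hann burst's duration at which it crosses frac*peak."""
        return float(np.arcsin(np.sqrt(min(frac, 0.99))) / np.pi)

    # ---- timeline, built outwards from the contact train ------------------
    # truth landmarks for the turns use the segmentation's own definition:
    # the crossing of (threshold * trial-max peak) on each turn's profile
    p1, p2 = abs(script.turn1_peak), abs(script.turn2_peak)
    pmax = max(p1, p2)
    x1 = _cross(turn_threshold * pmax / p1)
    x2 = _cross(turn_threshold * pmax / p2)

    t_sts = script.sit_s
    sts_end = t_sts + script.sts_s
    sts_i, sts_iii = _onset_offset(t_sts, script.sts_s, landmark_fraction)

    def _turn_ics(mid: float, lo: float, hi: float) -> np.ndarray:
        k = script.turn_steps
        if k == 0:
            return np.array([])
        spacing = min(period, ((hi - lo) - 0.01) / max(k - 1, 1)) if k > 1 else 0.0
        return _snap(mid + (np.arange(k) - (k - 1) / 2) * spacing)

    # walking resumes relative to the *smoothed* end of standing up (the
    # observable movement offset), keeping the first contact clear of the
    # segmented boundary while leaving no idle gap before the entry ramp
    sts_iii_smooth = _smoothed_burst_offset(
        t_sts, script.sts_s, script.sts_peak, fs, landmark_fraction
    )
    first_step = sts_iii_smooth + 0.30 + max(0.05, 0.5 * period - 0.1)
    walk1_ics = _snap(first_step + np.arange(script.walk_steps) * period)
    tr1_i = walk1_ics[-1] + margin
    turn1_start = tr1_i - x1 * script.turn_s
    tr1_iii = turn1_start + (1 - x1) * script.turn_s
    turn1_ics = _turn_ics(turn1_start + script.turn_s / 2, tr1_i + 0.35, tr1_iii - 0.35)

    walk2_ics = _snap(tr1_iii + margin + np.arange(script.walk_steps) * period)
    tr2_i = walk2_ics[-1] + margin
    turn2_start = tr2_i - x2 * script.turn_s
    tr2_iii = turn2_start + (1 - x2) * script.turn_s
    turn2_ics = _turn_ics(turn2_start + script.turn_s / 2, tr2_i + 0.35, tr2_iii - 0.35)

    sts2_start = turn2_start + script.turn_s + 0.2
    duration = sts2_start + script.sts2_s + script.sit_end_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    # ---- gyro channels ----------------------------------------------------
    pitch = _hann_burst(t, t_sts, script.sts_s, script.sts_peak)
    pitch += _hann_burst(t, sts2_start, script.sts2_s, script.sts2_peak)
    yaw = _hann_burst(t, turn1_start, script.turn_s, script.turn1_peak)
    yaw += _hann_burst(t, turn2_start, script.turn_s, -abs(script.turn2_peak))

    # ---- steps ------------------------------------------------------------
    all_ics = np.sort(np.concatenate([walk1_ics, turn1_ics, walk2_ics, turn2_ics]))
    h_steps = np.full(len(all_ics), h_amp)
    disp, av, yaw_walk = _walk_profile(t, all_ics, h_steps, f, hs_amp, 0.025)
    yaw = yaw + 6.0 * yaw_walk

    # small vertical transient while rising / sitting down
    av += 0.5 * _hann_burst(t, t_sts, script.sts_s, 1.0)
    av -= 0.5 * _hann_burst(t, sts2_start, script.sts2_s, 1.0)

    ap = 0.5 * np.sin(2 * np.pi * script.f_step * t) * (disp > 1e-9)
    ap += 0.8 * _hann_burst(t, t_sts, script.sts_s, 1.0)
    ap -= 0.6 * _hann_burst(t, sts2_start, script.sts2_s, 1.0)
    ml = 0.25 * np.sin(np.pi * script.f_step * t) * (disp > 1e-9)

    ax, ay, az = _sensor_frame(ap, ml, av, np.deg2rad(theta_x_deg), np.deg2rad(theta_z_deg))
    g_noise = noise_sd / GRAVITY_MS2
    rec = RawRecording(
        t=t,
        ax=ax + rng.normal(0, g_noise, n),
        ay=ay + rng.normal(0, g_noise, n),
        az=az + rng.normal(0, g_noise, n),
        gx=pitch + rng.normal(0, 0.25, n),
        gy=yaw + rng.normal(0, 0.25, n),
        gz=rng.normal(0, 0.25, n),
        fs_nominal=fs,
    )

    # ---- ground truth -----------------------------------------------------
    sts2_i, sts2_iii = _onset_offset(sts2_start, script.sts2_s, landmark_fraction)
    phases = {
        "STS": (sts_i, t_sts + script.sts_s / 2, sts_iii),
        "WALK1": (sts_iii, (sts_iii + tr1_i) / 2, tr1_i),
        "TURN1": (tr1_i, turn1_start + script.turn_s / 2, tr1_iii),
        "WALK2": (tr1_iii, (tr1_iii + tr2_i) / 2, tr2_i),
        "TURN2": (tr2_i, turn2_start + script.turn_s / 2, tr2_iii),
        "StS": (sts2_i, sts2_start + script.sts2_s / 2, sts2_iii),
    }
    peaks = {
        "STS": script.sts_peak, "TURN1": script.turn1_peak,
        "TURN2": -abs(script.turn2_peak), "StS": script.sts2_peak,
    }
    truth = GroundTruth(
        t_ic=all_ics,
        side=np.array(["A" if i % 2 == 0 else "B" for i in range(len(all_ics))], dtype=object),
        step_h=h_steps, f_step=script.f_step,
        tug_phases=phases, tug_peaks=peaks,
        walk_step_count=2 * script.walk_steps,
        turn_step_counts={"TURN1": script.turn_steps, "TURN2": script.turn_steps},
        duration=duration, disp=disp,
    )
    return rec, truth


@dataclass
class SessionProfile:
    """Subject-level parameters for a full synthetic session.

    The shoe size is metre-scaled (0.09 ~ a US women's 9 foot length of
    about 25 cm is *not* implied -- the value is simply in the unit the
    default correction constants were calibrated against; K absorbs the
    shoe-size unit and only within-cohort consistency matters).
    """

    meta: SubjectMeta = field(default_factory=lambda: SubjectMeta(
        subject_id="synthetic-001", age=35.0, sex="F", height_cm=170.0,
        weight_kg=68.0, shoe_size=0.09, sensor_to_ground_m=1.05,
    ))
    f_step_ssv: float = 1.8
    f_step_fv: float = 2.2
    h_ssv: float = 0.045
    h_fv: float = 0.055
    n_steps_10mwt: int = 16
    sway_sd_ap: float = 0.12
    sway_sd_ml: float = 0.08
    sway_band: tuple = (0.1, 3.0)
    sway_duration_s: float = 30.0
    natwalk_steps: int = 40


def gen_session(
    profile: SessionProfile | None = None, seed: int = 0, fs: float = 31.25
) -> tuple[dict, list[Annotation], SubjectMeta, dict]:
    """Generate a complete clinical session: 3 x SSV and 3 x FV ten-metre
    walks, the five static balance conditions, two timed-up-and-go trials
    and one naturalistic walking circuit.

    Returns (recordings, annotations, meta, truths): ``recordings`` maps
    trial_id -> RawRecording, ``truths`` maps trial_id -> GroundTruth, and
    each annotation covers its full trial.
    """
    profile = profile or SessionProfile()
    rng = np.random.default_rng(seed)
    recordings: dict[str, RawRecording] = {}
    annotations: list[Annotation] = []
    truths: dict[str, GroundTruth] = {}

    def _add(trial_id: str, test: str, rec: RawRecording, truth: GroundTruth) -> None:
        recordings[trial_id] = rec
        annotations.append(Annotation(trial_id, test, 0.0, float(rec.t[-1])))
        truths[trial_id] = truth

    for cond, f_step, h in (
        ("10MWT_SSV", profile.f_step_ssv, profile.h_ssv),
        ("10MWT_FV", profile.f_step_fv, profile.h_fv),
    ):
        for k in range(3):
            rec, truth = gen_walk(
                f_step=f_step, n_steps=profile.n_steps_10mwt, h_amp=h,
                L=profile.meta.sensor_to_ground_m,
                seed=int(rng.integers(2**31)), fs=fs,
            )
            _add(f"{cond.lower()}-{k + 1}", cond, rec, truth)

    base = np.diag([profile.sway_sd_ap**2, profile.sway_sd_ml**2])
    difficulty = {"BBS_SU": 1.0, "BBS_SEC": 1.3, "BBS_SFT": 1.6, "BBS_ST": 2.0, "BBS_SOL": 2.6}
    for cond, scale in difficulty.items():
        rec, truth = gen_sway(
            cov=base * scale**2, band=profile.sway_band,
            duration=profile.sway_duration_s, seed=int(rng.integers(2**31)), fs=fs,
        )
        _add(cond.lower(), cond, rec, truth)

    for k in range(2):
        rec, truth = gen_tug(
            TugScript(f_step=profile.f_step_ssv), seed=int(rng.integers(2**31)), fs=fs
        )
        _add(f"tug-{k + 1}", "TUG", rec, truth)

    rec, truth = gen_walk(
        f_step=profile.f_step_ssv, n_steps=profile.natwalk_steps,
        h_amp=profile.h_ssv, L=profile.meta.sensor_to_ground_m,
        seed=int(rng.integers(2**31)), fs=fs,
    )
    _add("natwalk-1", "NATWALK", rec, truth)

    return recordings, annotations, profile.meta, truths


def write_session(
    out_dir: str, recordings: dict, annotations: list[Annotation], meta: SubjectMeta
) -> None:
    """Write a generated session in the CSV/YAML formats the reader expects."""
    import os

    import pandas as pd
    import yaml

    os.makedirs(out_dir, exist_ok=True)
    for trial_id, rec in recordings.items():
        rec.to_csv(os.path.join(out_dir, f"{trial_id}.csv"))
    pd.DataFrame(
        [
            {"trial_id": a.trial_id, "test": a.test, "t_start": a.t_start, "t_end": a.t_end}
            for a in annotations
        ]
    ).to_csv(os.path.join(out_dir, "annotations.csv"), index=False)
    with open(os.path.join(out_dir, "subject.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "subject_id": meta.subject_id, "age": meta.age, "sex": meta.sex,
                "height_cm": meta.height_cm, "weight_kg": meta.weight_kg,
                "shoe_size": meta.shoe_size, "sensor_to_ground_m": meta.sensor_to_ground_m,
            },
            fh, sort_keys=False,
        )
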