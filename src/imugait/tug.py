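"""Timed-up-and-go phase segmentation and per-phase features.

The trial is segmented from the gyroscope alone. A level-5 discrete-wavelet
(db5) approximation of the pitch angular velocity isolates the slow trunk
flexion-extension of the sit-to-stand and stand-to-sit transitions: the
first and last prominent extrema of that reconstruction are the two
transitions, with stage landmark ii at the extremum and stages i/iii at the
flanking crossings of 10 % of the extremum amplitude. A level-2
approximation of yaw isolates the two 180-degree turns as the two longest
intervals where its magnitude exceeds 15 % of the trial maximum. The two
walking phases fill the gaps transition -> turn 1 and turn 1 -> turn 2.

Stage windows (i-ii, ii-iii, i-iii) then parameterise the per-phase feature
set: pitch-velocity statistics for the transitions, yaw-magnitude
statistics for the turns, acceleration statistics plus gait events for the
pooled walking phases. Mean angular acceleration over a stage is the net
velocity change divided by the stage duration.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pywt
from scipy.signal import find_peaks

from .config import PipelineConfig, DEFAULT_CONFIG
from .events import GaitEvents, detect_contacts, temporal_params
from .preprocess import AlignedSignal


PHASES = ("STS", "WALK1", "TURN1", "WALK2", "TURN2", "StS")


class SegmentationError(RuntimeError):
    """Phase segmentation failed; the message lists what was found."""


@dataclass
class TugPhases:
    """Landmark triplets (t_i, t_ii, t_iii) in seconds for the six phases."""

    landmarks: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for phase, (ti, tii, tiii) in self.landmarks.items():
            if not (ti < tii < tiii):
                raise SegmentationError(
                    f"phase {phase} landmarks not ordered: {ti}, {tii}, {tiii}"
                )
        order = [self.landmarks[p][0] for p in PHASES if p in self.landmarks]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise SegmentationError("phases are not in temporal order")

    def duration(self, phase: str) -> float:
        ti, _, tiii = self.landmarks[phase]
        return tiii - ti

    def window(self, phase: str) -> tuple[float, float]:
        ti, _, tiii = self.landmarks[phase]
        return ti, tiii

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"phase": p, "t_i": v[0], "t_ii": v[1], "t_iii": v[2]}
                for p, v in self.landmarks.items()
            ]
        )


def dwt_approximation(x: np.ndarray, level: int, wavelet: str = "db5") -> np.ndarray:
    """Reconstruct ``x`` from its level-``level`` approximation coefficients.

    All detail coefficients are zeroed before reconstruction, leaving the
    sub-band below roughly fs / 2^(level+1); the output has the input's
    length. Constants are preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(wavelet)
    if level > pywt.dwt_max_level(len(x), w.dec_len):
        raise ValueError(
            f"input of length {len(x)} too short for a level-{level} {wavelet} approximation"
        )
    coeffs = pywt.wavedec(x, w, level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, w)[: len(x)]


def _flank_crossings(
    x: np.ndarray, peak_idx: int, threshold: float
) -> tuple[int, int]:
    """Nearest indices left/right of ``peak_idx`` where |x| falls to threshold."""
    mag = np.abs(x)
    left = peak_idx
    while left > 0 and mag[left - 1] >= threshold:
        left -= 1
    right = peak_idx
    while right < len(x) - 1 and mag[right + 1] >= threshold:
        right += 1
    return left, right


def detect_phases(
    pitch: np.ndarray,
    yaw: np.ndarray,
    fs: float,
    config: PipelineConfig = DEFAULT_CONFIG,
    min_transition_peak: float = 10.0,
) -> TugPhases:
    """Segment a full trial into the six phases.

    Raises :class:`SegmentationError` when no transition extremum rises
    above the noise floor (``min_transition_peak`` deg/s on the smoothed
    pitch) or fewer than two turning intervals are found.
    """
    pitch = np.asarray(pitch, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    t = np.arange(len(pitch)) / fs

    pitch_a5 = dwt_approximation(pitch - np.median(pitch), 5)
    mag5 = np.abs(pitch_a5)
    if mag5.max() < min_transition_peak:
        raise SegmentationError(
            f"no pitch extremum above the {min_transition_peak} deg/s noise floor; "
            "no sit-stand transitions found"
        )
    peaks, _ = find_peaks(mag5, height=0.3 * mag5.max(), distance=int(1.0 * fs))
    if len(peaks) < 2:
        raise SegmentationError(
            f"expected sit-to-stand and stand-to-sit pitch extrema, found {len(peaks)} "
            f"prominent peak(s)"
        )
    transitions = {}
    for name, idx in (("STS", peaks[0]), ("StS", peaks[-1])):
        amp = mag5[idx]
        lo, hi = _flank_crossings(pitch_a5, idx, config.tug_landmark_fraction * amp)
        transitions[name] = (t[lo], t[idx], t[hi])

    yaw_a2 = dwt_approximation(yaw - np.median(yaw), 2)
    mag2 = np.abs(yaw_a2)
    thr = config.tug_turn_threshold * mag2.max()
    above = mag2 > thr
    # contiguous above-threshold runs
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    runs = sorted(zip(starts, ends), key=lambda r: r[1] - r[0], reverse=True)
    if len(runs) < 2:
        raise SegmentationError(
            f"expected two turning intervals in yaw, found {len(runs)} "
            f"(threshold {thr:.1f} deg/s)"
        )
    (s1, e1), (s2, e2) = sorted(runs[:2])  # order by time, not amplitude
    turns = {}
    for name, (s, e) in (("TURN1", (s1, e1)), ("TURN2", (s2, e2))):
        idx = s + int(np.argmax(mag2[s:e]))
        turns[name] = (t[s], t[idx], t[min(e, len(t) - 1)])

    landmarks = dict(transitions)
    landmarks.update(turns)
    w1_lo, w1_hi = transitions["STS"][2], turns["TURN1"][0]
    w2_lo, w2_hi = turns["TURN1"][2], turns["TURN2"][0]
    if not (w1_lo < w1_hi and w2_lo < w2_hi):
        raise SegmentationError(
            "walking phases are empty: transition and turn intervals overlap"
        )
    landmarks["WALK1"] = (w1_lo, (w1_lo + w1_hi) / 2, w1_hi)
    landmarks["WALK2"] = (w2_lo, (w2_lo + w2_hi) / 2, w2_hi)
    return TugPhases(landmarks)


# ---------------------------------------------------------------------------
# per-phase features

TRANSITION_FEATURES = (
    "RangePitchVel_i_ii", "RangePitchVel_ii_iii", "SDPitchVel_i_iii",
    "MeanPitchVel_i_iii", "MedianPitchVel_i_iii",
    "MaxPitchVel_i_ii", "MaxPitchVel_ii_iii",
    "MeanPitchAcc_i_ii", "MeanPitchAcc_ii_iii",
    "MeanAccAP_i_iii", "SDAccAP_i_iii", "MedianAccAP_i_iii", "Duration",
)
TURN_FEATURES = (
    "NSteps", "MaxYawVel", "MeanYawAcc_i_ii", "MeanYawAcc_ii_iii", "Duration",
)
WALK_FEATURES = (
    "RMSAcc_AP", "RMSAcc_ML", "RMSAcc_V",
    "MeanStepTime", "SDStepTime", "NSteps", "Duration",
)


def _seg(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    i0, i1 = int(np.round(lo * fs)), int(np.round(hi * fs)) + 1
    return x[max(i0, 0) : i1]


def _transition_features(
    sig: AlignedSignal, tri: tuple[float, float, float]
) -> dict[str, float]:
    ti, tii, tiii = tri
    fs = sig.fs
    p_i_ii = _seg(sig.pitch, fs, ti, tii)
    p_ii_iii = _seg(sig.pitch, fs, tii, tiii)
    p_all = _seg(sig.pitch, fs, ti, tiii)
    ap_all = _seg(sig.aAP, fs, ti, tiii)
    return {
        "RangePitchVel_i_ii": float(np.ptp(p_i_ii)),
        "RangePitchVel_ii_iii": float(np.ptp(p_ii_iii)),
        "SDPitchVel_i_iii": float(np.std(p_all, ddof=1)),
        "MeanPitchVel_i_iii": float(np.mean(p_all)),
        "MedianPitchVel_i_iii": float(np.median(p_all)),
        "MaxPitchVel_i_ii": float(np.max(p_i_ii)),
        "MaxPitchVel_ii_iii": float(np.max(p_ii_iii)),
        "MeanPitchAcc_i_ii": float((p_i_ii[-1] - p_i_ii[0]) / (tii - ti)),
        "MeanPitchAcc_ii_iii": float((p_ii_iii[-1] - p_ii_iii[0]) / (tiii - tii)),
        "MeanAccAP_i_iii": float(np.mean(ap_all)),
        "SDAccAP_i_iii": float(np.std(ap_all, ddof=1)),
        "MedianAccAP_i_iii": float(np.median(ap_all)),
        "Duration": tiii - ti,
    }


def _turn_features(
    sig: AlignedSignal, tri: tuple[float, float, float], n_steps: int
) -> dict[str, float]:
    ti, tii, tiii = tri
    fs = sig.fs
    y_i_ii = np.abs(_seg(sig.yaw, fs, ti, tii))
    y_ii_iii = np.abs(_seg(sig.yaw, fs, tii, tiii))
    y_all = np.abs(_seg(sig.yaw, fs, ti, tiii))
    return {
        "NSteps": float(n_steps),
        "MaxYawVel": float(np.max(y_all)),
        "MeanYawAcc_i_ii": float((y_i_ii[-1] - y_i_ii[0]) / (tii - ti)),
        "MeanYawAcc_ii_iii": float((y_ii_iii[-1] - y_ii_iii[0]) / (tiii - tii)),
        "Duration": tiii - ti,
    }


def phase_gait_events(
    sig: AlignedSignal, phases: TugPhases, config: PipelineConfig = DEFAULT_CONFIG
) -> dict[str, GaitEvents]:
    """Run gait-event detection inside each walking and turning window.

    The dominant step frequency is estimated once from the pooled walking
    windows and reused for the short turning windows, whose spectra are
    dominated by the turn itself rather than by stepping.
    """
    from .events import dominant_frequency

    walk_sig = np.concatenate(
        [_seg(sig.aVf, sig.fs, *phases.window(p)) for p in ("WALK1", "WALK2")]
    )
    try:
        f_walk = dominant_frequency(walk_sig, sig.fs, config.dominant_band_hz)
    except ValueError:
        f_walk = None
    out = {}
    for phase in ("WALK1", "WALK2", "TURN1", "TURN2"):
        lo, hi = phases.window(phase)
        ev = detect_contacts(_seg(sig.aVf, sig.fs, lo, hi), sig.fs, config, f_dom=f_walk)
        out[phase] = ev.shifted(lo)
    return out


def tug_features(
    sig: AlignedSignal,
    phases: TugPhases,
    events: dict[str, GaitEvents] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[tuple[str, str], float]:
    """All per-phase features of one trial, keyed by (phase, feature_name).

    ``events`` maps the walking/turning phases to their gait events; when
    omitted it is computed here. A missing phase yields NaN for each of its
    features.
    """
    if events is None:
        events = phase_gait_events(sig, phases, config)
    out: dict[tuple[str, str], float] = {}
    for phase in ("STS", "StS"):
        if phase in phases.landmarks:
            feats = _transition_features(sig, phases.landmarks[phase])
        else:
            feats = {k: np.nan for k in TRANSITION_FEATURES}
        out.update({(phase, k): v for k, v in feats.items()})
    for phase in ("TURN1", "TURN2"):
        if phase in phases.landmarks:
            lo, hi = phases.window(phase)
            ev = events.get(phase)
            n = int(np.sum((ev.t_ic > lo) & (ev.t_ic < hi))) if ev is not None else 0
            feats = _turn_features(sig, phases.landmarks[phase], n)
        else:
            feats = {k: np.nan for k in TURN_FEATURES}
        out.update({(phase, k): v for k, v in feats.items()})

    # pooled walking phases
    if "WALK1" in phases.landmarks and "WALK2" in phases.landmarks:
        step_times = []
        n_steps = 0
        seg_ap, seg_ml, seg_v = [], [], []
        for phase in ("WALK1", "WALK2"):
            lo, hi = phases.window(phase)
            ev = events.get(phase)
            if ev is not None:
                inside = (ev.t_ic > lo) & (ev.t_ic < hi)
                n_steps += int(inside.sum())
                tic = ev.t_ic[inside]
                if len(tic) >= 2:
                    step_times.extend(np.diff(tic))
            seg_ap.append(_seg(sig.aAPf, sig.fs, lo, hi))
            seg_ml.append(_seg(sig.aMLf, sig.fs, lo, hi))
            seg_v.append(_seg(sig.aVf, sig.fs, lo, hi))
        cat = lambda segs: np.concatenate(segs)
        step_times_arr = np.asarray(step_times)
        walk = {
            "RMSAcc_AP": float(np.sqrt(np.mean(cat(seg_ap) ** 2))),
            "RMSAcc_ML": float(np.sqrt(np.mean(cat(seg_ml) ** 2))),
            "RMSAcc_V": float(np.sqrt(np.mean(cat(seg_v) ** 2))),
            "MeanStepTime": float(np.mean(step_times_arr)) if len(step_times_arr) else np.nan,
            "SDStepTime": float(np.std(step_times_arr, ddof=1)) if len(step_times_arr) > 1 else np.nan,
            "NSteps": float(n_steps),
            "Duration": phases.duration("WALK1") + phases.duration("WALK2"),
        }
    else:
        walk = {k: np.nan for k in WALK_FEATURES}
    out.update({("WALK", k): v for k, v in walk.items()})
    return out
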