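"""Reading, resampling and anatomical alignment of lower-back IMU recordings.

A single sensor at the L5 vertebra records triaxial acceleration (in g) and
triaxial angular velocity (in deg/s). Before any gait or balance analysis the
sensor-frame accelerations are rotated into anatomical anteroposterior (AP),
mediolateral (ML) and vertical (V) axes using tilt angles estimated from the
mean (gravity-dominated) acceleration, gravity is subtracted from the
vertical channel, and everything is converted to m/s^2. Walking analyses
additionally use a 4th-order zero-phase Butterworth low-pass at 10 Hz; yaw is
low-passed at 2 Hz before left/right step designation.

Axis convention (at zero tilt): sensor y points up (vertical), sensor z
points posterior (so AP = -z), sensor x points to the subject's right
(so ML = -x). The tilt correction is the small-angle two-rotation scheme

    a^V  =  az*sin(theta_z) + ay*cos(theta_z)
    aAP  = -az*cos(theta_z) + ay*sin(theta_z)
    aML  = -ax*cos(theta_x) + a^V*sin(theta_x)
    aV   =  ax*sin(theta_x) + a^V*cos(theta_x) - 1

with theta_x = arcsin(mean ax) and theta_z = arcsin(mean az) estimated over
a static or full-trial window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .config import GRAVITY_MS2, PipelineConfig, DEFAULT_CONFIG


class FormatError(ValueError):
    """The input file does not have the expected columns/shape."""


class DataError(ValueError):
    """The input data violate a precondition (ordering, length, ...)."""


RECORDING_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]

TEST_LABELS = (
    "10MWT_SSV",
    "10MWT_FV",
    "BBS_SU",
    "BBS_SEC",
    "BBS_SFT",
    "BBS_ST",
    "BBS_SOL",
    "TUG",
    "NATWALK",
)


@dataclass
class RawRecording:
    """One trial of sensor-frame IMU samples.

    Accelerations are in g, angular velocities in deg/s, time in seconds
    from the first sample.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    fs_nominal: float = 31.25

    def __post_init__(self) -> None:
        for name in ("t", "ax", "ay", "az", "gx", "gy", "gz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, c)) != n for c in ("ax", "ay", "az", "gx", "gy", "gz")):
            raise DataError("all channels must have the same length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.fs_nominal <= 0:
            raise DataError("fs_nominal must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in RECORDING_COLUMNS})

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def slice(self, t_start: float, t_end: float) -> "RawRecording":
        """Return the samples with t_start <= t <= t_end (times re-zeroed)."""
        m = (self.t >= t_start) & (self.t <= t_end)
        if m.sum() < 2:
            raise DataError(f"window [{t_start}, {t_end}] contains fewer than 2 samples")
        return RawRecording(
            t=self.t[m] - self.t[m][0],
            ax=self.ax[m], ay=self.ay[m], az=self.az[m],
            gx=self.gx[m], gy=self.gy[m], gz=self.gz[m],
            fs_nominal=self.fs_nominal,
        )


@dataclass
class Annotation:
    """Start/end of one annotated trial or condition."""

    trial_id: str
    test: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.test not in TEST_LABELS:
            raise FormatError(f"unknown test label {self.test!r}; expected one of {TEST_LABELS}")
        if not self.t_start < self.t_end:
            raise DataError("annotation must satisfy t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SubjectMeta:
    """Anthropometrics needed by the step-length model.

    ``sensor_to_ground`` is the pendulum length L in metres (distance from
    the lower-back sensor to the ground during upright standing);
    ``shoe_size`` is the unitless numeric S of the step-length correction.
    Shoe-size units are whatever the calibration cohort used -- the
    correction constant K absorbs the unit, so the only requirement is
    consistency between calibration and application.
    """

    subject_id: str
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    shoe_size: float
    sensor_to_ground_m: float

    def __post_init__(self) -> None:
        for name in ("age", "height_cm", "weight_kg", "shoe_size", "sensor_to_ground_m"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.sensor_to_ground_m >= self.height_cm / 100.0:
            raise DataError("sensor_to_ground_m must be smaller than height")


@dataclass
class AlignedSignal:
    """Tilt-corrected anatomical accelerations and filtered gyro channels.

    aAP/aML/aV are gravity-free anatomical accelerations in m/s^2 on a
    uniform time grid. The primed variants are the 10 Hz low-passed copies
    used by the walking algorithms. ``pitch`` is angular velocity about the
    ML axis and ``yaw`` about the vertical axis (deg/s); ``yaw_f`` is yaw
    low-passed at 2 Hz for left/right designation.
    """

    t: np.ndarray
    fs: float
    aAP: np.ndarray
    aML: np.ndarray
    aV: np.ndarray
    aAPf: np.ndarray
    aMLf: np.ndarray
    aVf: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    yaw_f: np.ndarray
    theta_x: float
    theta_z: float

    def window(self, t_start: float, t_end: float) -> "AlignedSignal":
        m = (self.t >= t_start) & (self.t <= t_end)
        return AlignedSignal(
            t=self.t[m], fs=self.fs,
            aAP=self.aAP[m], aML=self.aML[m], aV=self.aV[m],
            aAPf=self.aAPf[m], aMLf=self.aMLf[m], aVf=self.aVf[m],
            pitch=self.pitch[m], yaw=self.yaw[m], yaw_f=self.yaw_f[m],
            theta_x=self.theta_x, theta_z=self.theta_z,
        )


def read_recording(path: str, fs_nominal: float = 31.25) -> RawRecording:
    """Read a trial CSV with columns t,ax,ay,az,gx,gy,gz.

    Time is converted to seconds from the first sample. Accelerations are
    expected in g, angular velocities in deg/s.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"recording {path} is missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise DataError(f"recording {path} has non-monotonic timestamps")
    return RawRecording(
        t=t - t[0],
        ax=df["ax"].to_numpy(float), ay=df["ay"].to_numpy(float), az=df["az"].to_numpy(float),
        gx=df["gx"].to_numpy(float), gy=df["gy"].to_numpy(float), gz=df["gz"].to_numpy(float),
        fs_nominal=fs_nominal,
    )


def read_annotations(path: str) -> list[Annotation]:
    """Read the annotation CSV (trial_id,test,t_start,t_end)."""
    df = pd.read_csv(path)
    missing = [c for c in ("trial_id", "test", "t_start", "t_end") if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} is missing columns {missing}")
    if df["trial_id"].duplicated().any():
        raise DataError("trial_id values must be unique")
    return [
        Annotation(str(r.trial_id), str(r.test), float(r.t_start), float(r.t_end))
        for r in df.itertuples()
    ]


def read_subject_meta(path: str) -> SubjectMeta:
    """Read subject metadata from YAML or a one-row CSV."""
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
    else:
        d = pd.read_csv(path).iloc[0].to_dict()
    try:
        return SubjectMeta(
            subject_id=str(d["subject_id"]), age=float(d["age"]), sex=str(d["sex"]),
            height_cm=float(d["height_cm"]), weight_kg=float(d["weight_kg"]),
            shoe_size=float(d["shoe_size"]),
            sensor_to_ground_m=float(d["sensor_to_ground_m"]),
        )
    except KeyError as e:
        raise FormatError(f"subject metadata {path} is missing field {e}") from e


def resample_uniform(rec: RawRecording, fs: float) -> RawRecording:
    """Linearly interpolate all channels onto the uniform grid k/fs.

    The grid spans [t0, tN] with length floor((tN - t0) * fs) + 1. Device
    timestamps jitter around the nominal rate, so this is applied before
    any filtering. An already-uniform recording at the target rate is
    returned unchanged.
    """
    if len(rec) < 2:
        raise DataError("resampling requires at least 2 samples")
    t0, tN = rec.t[0], rec.t[-1]
    n = int(np.floor((tN - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    if len(grid) == len(rec.t) and np.allclose(grid, rec.t, atol=1e-12):
        return rec
    channels = {
        c: np.interp(grid, rec.t, getattr(rec, c))
        for c in ("ax", "ay", "az", "gx", "gy", "gz")
    }
    return RawRecording(t=grid - t0, fs_nominal=fs, **channels)


def estimate_tilt(
    rec: RawRecording, window: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Estimate sensor tilt angles (radians) from the mean acceleration.

    Uses the small-angle relations sin(theta_x) ~ mean(ax) and
    sin(theta_z) ~ mean(az), valid because over a long window the dynamic
    accelerations average out and only gravity remains. ``window`` is an
    optional (start, stop) sample range; the default is the full trial.
    """
    sl = slice(*window) if window is not None else slice(None)
    ax = rec.ax[sl]
    az = rec.az[sl]
    if len(ax) < 1:
        raise DataError("tilt window contains no samples")
    mx, mz = float(np.mean(ax)), float(np.mean(az))
    if abs(mx) > 1 or abs(mz) > 1:
        warnings.warn(
            "mean acceleration magnitude exceeds 1 g; clipping tilt estimate "
            "(is the recording really in g units?)",
            stacklevel=2,
        )
        mx, mz = np.clip(mx, -1, 1), np.clip(mz, -1, 1)
    return float(np.arcsin(mx)), float(np.arcsin(mz))


def to_anatomical(
    rec: RawRecording,
    theta_x: float,
    theta_z: float,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> AlignedSignal:
    """Rotate sensor-frame accelerations into AP/ML/V and remove gravity.

    Applies the provisional-vertical two-step tilt correction, subtracts
    1 g from the vertical channel, converts to m/s^2, and attaches the
    low-passed copies used downstream (10 Hz walking accelerations, 2 Hz
    yaw). Gyro channels are mapped to pitch/yaw by the configured axis
    convention.
    """
    sx, cx = np.sin(theta_x), np.cos(theta_x)
    sz, cz = np.sin(theta_z), np.cos(theta_z)
    a_prov_v = rec.az * sz + rec.ay * cz          # provisional vertical, in g
    a_ap = -rec.az * cz + rec.ay * sz
    a_ml = -rec.ax * cx + a_prov_v * sx
    a_v = rec.ax * sx + a_prov_v * cx - 1.0
    aAP = a_ap * GRAVITY_MS2
    aML = a_ml * GRAVITY_MS2
    aV = a_v * GRAVITY_MS2

    fs = rec.fs_nominal
    gyro = {"x": rec.gx, "y": rec.gy, "z": rec.gz}
    pitch = config.gyro_pitch_sign * gyro[config.gyro_pitch_axis]
    yaw = config.gyro_yaw_sign * gyro[config.gyro_yaw_axis]

    aAPf = butterworth_lowpass(aAP, fs, config.lowpass_walk_hz, config.butter_order)
    aMLf = butterworth_lowpass(aML, fs, config.lowpass_walk_hz, config.butter_order)
    aVf = butterworth_lowpass(aV, fs, config.lowpass_walk_hz, config.butter_order)
    yaw_f = butterworth_lowpass(yaw, fs, config.lowpass_yaw_hz, config.butter_order)

    return AlignedSignal(
        t=rec.t.copy(), fs=fs, aAP=aAP, aML=aML, aV=aV,
        aAPf=aAPf, aMLf=aMLf, aVf=aVf,
        pitch=np.asarray(pitch, float), yaw=np.asarray(yaw, float), yaw_f=yaw_f,
        theta_x=theta_x, theta_z=theta_z,
    )


def butterworth_lowpass(
    x: Sequence[float], fs: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Zero-phase filtering preserves event timing, which matters because
    contact times feed the temporal gait parameters directly.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz")
    x = np.asarray(x, dtype=float)
    b, a = butter(order, cutoff, btype="low", fs=fs)
    padlen = min(3 * (max(len(a), len(b)) - 1), len(x) - 1)
    return filtfilt(b, a, x, padlen=padlen)


def preprocess(
    rec: RawRecording,
    config: PipelineConfig = DEFAULT_CONFIG,
    tilt_window: tuple[int, int] | None = None,
) -> AlignedSignal:
    """Full preprocessing chain: resample, tilt-correct, filter."""
    rec = resample_uniform(rec, config.fs)
    theta_x, theta_z = estimate_tilt(rec, tilt_window)
    return to_anatomical(rec, theta_x, theta_z, config)
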