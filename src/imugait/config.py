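"""Pipeline configuration.

All thresholds, filter settings and sign conventions used by the pipeline
live here so a whole session run is reproducible from one YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

#: Standard gravity used to convert accelerations from g to m/s^2.
GRAVITY_MS2 = 9.81


@dataclass
class PipelineConfig:
    """Tunable parameters of the feature-extraction pipeline.

    Parameters
    ----------
    fs : float
        Target uniform sampling rate in Hz. The nominal rate of the
        lower-back sensor is 31.25 Hz; any rate is accepted and every
        algorithm is parameterised by it.
    lowpass_walk_hz : float
        Cutoff of the 4th-order Butterworth low-pass applied to the
        anatomical accelerations for walking tests (10 Hz).
    lowpass_yaw_hz : float
        Cutoff of the 4th-order Butterworth low-pass applied to yaw before
        left/right designation (2 Hz).
    gyro_pitch_axis, gyro_yaw_axis : str
        Which sensor gyro channel carries rotation about the ML axis
        (pitch) and about the vertical axis (yaw). The device drawing does
        not pin these down, so they are configuration, not inference.
    gyro_pitch_sign, gyro_yaw_sign : int
        Sign conventions for the two angular-velocity channels (+1/-1).
    side_a_is_left : bool
        Maps the abstract gait-event side labels {A, B} onto {left, right}.
    dominant_band_hz : tuple
        Search band for the dominant step frequency.
    ic_min_gap_s, ic_max_gap_s : float
        False initial-contact pruning window: an IC closer than the
        minimum, or farther than the maximum, from the previous retained IC
        is discarded.
    ec_peak_fraction : float
        End-contact candidate peaks with magnitude at or below this
        fraction of the mean peak magnitude are discarded.
    edge_guard_s : float
        Events closer than this to a window boundary are discarded
        (wavelet edge effects).
    hurst_cutoff : float
        Intrinsic mode functions with a Hurst exponent above this value are
        treated as drift and removed before integration output is used.
    k_ssv, k_fv : float
        Step-length correction constants for the self-selected and fast
        velocity conditions. These are cohort-specific calibration values
        for healthy adults and do not generalise to impaired gait; use
        ``imugait calibrate`` to re-fit them for a new cohort.
    ellipse_coverage : float
        Coverage probability of the sway ellipse.
    ellipse_use_f_statistic : bool
        If True, scale the ellipse with the small-sample prediction-ellipse
        F statistic instead of the chi-square quantile.
    jerk_mean_absolute : bool
        If True, aggregate jerk as mean absolute derivative instead of RMS.
    tug_turn_threshold : float
        Fraction of the maximum smoothed yaw magnitude that defines a
        turning interval.
    tug_landmark_fraction : float
        Fraction of a transition's peak angular velocity at which the
        flanking landmarks (stages i and iii) are placed.
    strict_feature_count : bool
        If True, drop the TUG walk-phase duration from the registry
        (a reduced 183-feature variant); the default keeps all features.
    per_leg_features : bool
        If True, emit per-leg values instead of averaging sides.
    """

    fs: float = 31.25
    lowpass_walk_hz: float = 10.0
    lowpass_yaw_hz: float = 2.0
    butter_order: int = 4
    gyro_pitch_axis: str = "x"
    gyro_yaw_axis: str = "y"
    gyro_pitch_sign: int = 1
    gyro_yaw_sign: int = 1
    side_a_is_left: bool = True
    dominant_band_hz: tuple = (0.5, 5.0)
    ic_min_gap_s: float = 0.25
    ic_max_gap_s: float = 2.25
    ec_peak_fraction: float = 0.20
    edge_guard_s: float = 0.25
    hurst_cutoff: float = 0.8
    k_ssv: float = 1.13
    k_fv: float = 1.50
    ellipse_coverage: float = 0.95
    ellipse_use_f_statistic: bool = False
    jerk_mean_absolute: bool = False
    tug_turn_threshold: float = 0.15
    tug_landmark_fraction: float = 0.10
    strict_feature_count: bool = False
    per_leg_features: bool = False

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["dominant_band_hz"] = list(d["dominant_band_hz"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d: dict[str, Any] = yaml.safe_load(fh) or {}
        if "dominant_band_hz" in d:
            d["dominant_band_hz"] = tuple(d["dominant_band_hz"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


DEFAULT_CONFIG = PipelineConfig()
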