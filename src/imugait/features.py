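"""Session orchestration and the canonical 184-feature registry.

One complete clinical session comprises three ten-metre walks at
self-selected velocity (SSV) and three at fast velocity (FV), the five
static standing conditions of the Berg Balance Scale (BBS), timed-up-and-go
(TUG) trials and one naturalistic walking circuit. The registry enumerates
184 named features: 23 per BBS condition (115), 12 per 10MWT condition plus
the SSV/FV velocity difference (25), 43 across the TUG phases and the
naturalistic step count (1). Extraction always emits all 184 rows; missing
data produce missing values, never missing rows.

Two naming quirks inherited from the registry's definition are worth
flagging: "Maximum Power Frequency" is the maximum *value* of the vertical
acceleration power spectral density (units (m/s^2)^2/Hz), not a frequency;
and step lengths are reported in centimetres while everything else is SI.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from . import balance, steplength, tug
from .config import PipelineConfig, DEFAULT_CONFIG
from .emd import emd_drift_free_integral
from .events import assign_sides, detect_contacts, temporal_params
from .preprocess import (
    AlignedSignal,
    Annotation,
    RawRecording,
    SubjectMeta,
    preprocess,
)

REGISTRY_VERSION = "1.0"

BBS_CONDITIONS = ("SU", "SEC", "SFT", "ST", "SOL")

TENMWT_FEATURES = (
    ("MeanVerticalDisplacement", "m"),
    ("MeanStanceTime", "s"),
    ("MeanStepTime", "s"),
    ("MeanStrideTime", "s"),
    ("MeanSwingTime", "s"),
    ("MeanStepLength", "cm"),
    ("MaximumPowerFrequency", "(m/s^2)^2/Hz"),
    ("StanceTimeSymmetryRatio", "unitless"),
    ("StepLengthSymmetryRatio", "unitless"),
    ("Duration", "s"),
    ("MeanVelocity", "m/s"),
    ("NSteps", "unitless"),
)

_TUG_UNITS = {
    "RangePitchVel_i_ii": "deg/s", "RangePitchVel_ii_iii": "deg/s",
    "SDPitchVel_i_iii": "deg/s", "MeanPitchVel_i_iii": "deg/s",
    "MedianPitchVel_i_iii": "deg/s", "MaxPitchVel_i_ii": "deg/s",
    "MaxPitchVel_ii_iii": "deg/s", "MeanPitchAcc_i_ii": "deg/s^2",
    "MeanPitchAcc_ii_iii": "deg/s^2", "MeanAccAP_i_iii": "m/s^2",
    "SDAccAP_i_iii": "m/s^2", "MedianAccAP_i_iii": "m/s^2",
    "MaxYawVel": "deg/s", "MeanYawAcc_i_ii": "deg/s^2",
    "MeanYawAcc_ii_iii": "deg/s^2", "NSteps": "unitless", "Duration": "s",
    "RMSAcc_AP": "m/s^2", "RMSAcc_ML": "m/s^2", "RMSAcc_V": "m/s^2",
    "MeanStepTime": "s", "SDStepTime": "s",
}


def feature_registry(strict: bool = False) -> pd.DataFrame:
    """The canonical ordered registry of (test, condition, feature_name, units).

    ``strict=True`` drops the TUG walking-phase duration, giving the
    reduced 183-feature variant.
    """
    rows: list[tuple[str, str, str, str]] = []
    for cond in BBS_CONDITIONS:
        for name in balance.BALANCE_FEATURE_NAMES:
            prefix = name.split("_")[0]
            rows.append(("BBS", cond, name, balance.BALANCE_FEATURE_UNITS[prefix]))
    for cond in ("SSV", "FV"):
        for name, units in TENMWT_FEATURES:
            rows.append(("10MWT", cond, name, units))
    rows.append(("10MWT", "FV-SSV", "VelocityDifference", "m/s"))
    for phase in ("STS", "StS"):
        for name in tug.TRANSITION_FEATURES:
            rows.append(("TUG", phase, name, _TUG_UNITS[name]))
    for phase in ("TURN1", "TURN2"):
        for name in tug.TURN_FEATURES:
            rows.append(("TUG", phase, name, _TUG_UNITS[name]))
    for name in tug.WALK_FEATURES:
        if strict and name == "Duration":
            continue
        rows.append(("TUG", "WALK", name, _TUG_UNITS[name]))
    rows.append(("NATWALK", "-", "NSteps", "unitless"))
    return pd.DataFrame(rows, columns=["test", "condition", "feature_name", "units"])


# ---------------------------------------------------------------------------
# per-test extraction


def _walking_trial_values(
    sig: AlignedSignal,
    duration: float,
    model: steplength.StepLengthModel,
    config: PipelineConfig,
) -> dict[str, float]:
    """The twelve single-trial walking features (before trial averaging)."""
    ev = detect_contacts(sig.aVf, sig.fs, config)
    ev = assign_sides(ev, sig.yaw_f, sig.fs)
    out = {name: np.nan for name, _ in TENMWT_FEATURES}
    out["Duration"] = duration
    out["NSteps"] = float(ev.n_steps)
    if ev.n_steps < 3:
        warnings.warn("fewer than 3 initial contacts in walking trial; gait features missing")
        return out
    tp = temporal_params(ev)
    out["MeanStanceTime"] = float(np.mean(tp.t_stance)) if len(tp.t_stance) else np.nan
    out["MeanStepTime"] = float(np.mean(tp.t_step)) if len(tp.t_step) else np.nan
    out["MeanStrideTime"] = float(np.mean(tp.t_stride)) if len(tp.t_stride) else np.nan
    out["MeanSwingTime"] = float(np.mean(tp.t_swing)) if len(tp.t_swing) else np.nan

    f, p = periodogram(sig.aVf - sig.aVf.mean(), fs=sig.fs)
    out["MaximumPowerFrequency"] = float(p[1:].max())

    try:
        vx = steplength.vertical_excursion(sig.aVf, sig.fs, ev, config)
    except ValueError:
        return out
    h = vx.h
    out["MeanVerticalDisplacement"] = float(np.nanmean(h)) if np.any(~np.isnan(h)) else np.nan
    valid = ~np.isnan(h) & (h < model.L)
    if valid.any():
        l_step = steplength.corrected_step_length(h[valid], model.L, model.K, model.S)
        out["MeanStepLength"] = float(np.mean(l_step)) * 100.0  # cm
        # per-step velocity over steps with a defined step time
        n = min(len(l_step), len(tp.t_step))
        if n:
            out["MeanVelocity"] = float(np.mean(l_step[:n] / tp.t_step[:n]))
        # side-wise means: step i (IC i -> IC i+1) is attributed to IC i's side
        sides = ev.side[: len(h)]
        for key, series in (
            ("StanceTimeSymmetryRatio", tp.t_stance),
            ("StepLengthSymmetryRatio", np.where(valid, steplength.corrected_step_length(
                np.where(valid, h, 0.0), model.L, model.K, model.S), np.nan)),
        ):
            s = np.asarray(series, dtype=float)
            m = min(len(s), len(sides))
            a = s[:m][np.asarray(sides[:m]) == "A"]
            b = s[:m][np.asarray(sides[:m]) == "B"]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) and len(b) and np.mean(b) != 0:
                out[key] = float(np.mean(a) / np.mean(b))
    return out


def extract_10mwt(
    trials: list[tuple[AlignedSignal, float]],
    condition: str,
    model: steplength.StepLengthModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Trial-averaged walking features for one speed condition.

    ``trials`` is a list of (aligned signal, annotated duration) pairs;
    ``condition`` is "SSV" or "FV" and selects nothing here beyond being
    documentation -- the correction constant K is already inside ``model``.
    """
    if not trials:
        return {name: np.nan for name, _ in TENMWT_FEATURES}
    per_trial = [
        _walking_trial_values(sig, dur, model, config) for sig, dur in trials
    ]
    out = {}
    for name, _ in TENMWT_FEATURES:
        vals = np.array([tv[name] for tv in per_trial], dtype=float)
        out[name] = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
    return out


@dataclass
class FeatureTable:
    """Long-format feature table for one subject session."""

    table: pd.DataFrame
    registry_version: str = REGISTRY_VERSION

    def value(self, test: str, condition: str, feature_name: str) -> float:
        m = (
            (self.table.test == test)
            & (self.table.condition == condition)
            & (self.table.feature_name == feature_name)
        )
        return float(self.table.loc[m, "value"].iloc[0])

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        self.table.to_json(path, orient="records", indent=2)


def extract_session(
    recordings: dict[str, RawRecording],
    annotations: list[Annotation],
    meta: SubjectMeta,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FeatureTable:
    """Run the full pipeline over one session and fill the registry.

    ``recordings`` maps trial_id to its recording; every annotation must
    reference a known trial. The output always has one row per registry
    entry (184 by default); conditions without data yield missing values.
    """
    unknown = [a.trial_id for a in annotations if a.trial_id not in recordings]
    if unknown:
        raise KeyError(f"annotations reference unknown trial ids: {unknown}")

    by_test: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_test.setdefault(a.test, []).append(a)

    def _aligned(a: Annotation) -> AlignedSignal:
        rec = recordings[a.trial_id].slice(a.t_start, a.t_end)
        return preprocess(rec, config)

    values: dict[tuple[str, str, str], float] = {}

    # --- 10MWT -------------------------------------------------------------
    velocity: dict[str, float] = {}
    for cond, k in (("SSV", config.k_ssv), ("FV", config.k_fv)):
        anns = by_test.get(f"10MWT_{cond}", [])
        model = steplength.StepLengthModel(
            L=meta.sensor_to_ground_m, K=k, S=meta.shoe_size
        )
        trials = [(_aligned(a), a.duration) for a in anns]
        feats = extract_10mwt(trials, cond, model, config)
        for name, _ in TENMWT_FEATURES:
            values[("10MWT", cond, name)] = feats[name]
        velocity[cond] = feats["MeanVelocity"]
    values[("10MWT", "FV-SSV", "VelocityDifference")] = (
        velocity.get("FV", np.nan) - velocity.get("SSV", np.nan)
    )

    # --- BBS ---------------------------------------------------------------
    for cond in BBS_CONDITIONS:
        anns = by_test.get(f"BBS_{cond}", [])
        if anns:
            sig = _aligned(anns[0])
            feats = balance.bbs_condition_features(sig.aAP, sig.aML, sig.fs, config)
        else:
            feats = {name: np.nan for name in balance.BALANCE_FEATURE_NAMES}
        for name in balance.BALANCE_FEATURE_NAMES:
            values[("BBS", cond, name)] = feats[name]

    # --- TUG ---------------------------------------------------------------
    tug_anns = by_test.get("TUG", [])
    tug_trials: list[dict[tuple[str, str], float]] = []
    for a in tug_anns:
        sig = _aligned(a)
        try:
            phases = tug.detect_phases(sig.pitch, sig.yaw, sig.fs, config)
        except (tug.SegmentationError, ValueError) as e:
            warnings.warn(f"TUG trial {a.trial_id}: segmentation failed ({e})")
            continue
        tug_trials.append(tug.tug_features(sig, phases, config=config))
    registry = feature_registry(strict=config.strict_feature_count)
    for _, row in registry[registry.test == "TUG"].iterrows():
        key = (row.condition, row.feature_name)
        vals = np.array([tt.get(key, np.nan) for tt in tug_trials], dtype=float)
        values[("TUG", row.condition, row.feature_name)] = (
            float(np.nanmean(vals)) if len(vals) and np.any(~np.isnan(vals)) else np.nan
        )

    # --- naturalistic walking ---------------------------------------------
    nat_anns = by_test.get("NATWALK", [])
    counts = []
    for a in nat_anns:
        sig = _aligned(a)
        ev = detect_contacts(sig.aVf, sig.fs, config)
        counts.append(ev.n_steps)
    values[("NATWALK", "-", "NSteps")] = float(np.mean(counts)) if counts else np.nan

    table = registry.copy()
    table.insert(0, "subject_id", meta.subject_id)
    table["value"] = [
        values.get((r.test, r.condition, r.feature_name), np.nan)
        for r in registry.itertuples()
    ]
    table = table[["subject_id", "test", "condition", "feature_name", "value", "units"]]
    return FeatureTable(table)
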