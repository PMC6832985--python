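"""Reading, resampling, tilt correction and filtering."""

import io

import numpy as np
import pytest

from imugait.config import GRAVITY_MS2, PipelineConfig
from imugait.preprocess import (
    Annotation,
    DataError,
    FormatError,
    RawRecording,
    butterworth_lowpass,
    estimate_tilt,
    read_recording,
    resample_uniform,
    to_anatomical,
)

FS = 31.25


def _static_recording(ax, ay, az, n=200, fs=FS):
    t = np.arange(n) / fs
    zeros = np.zeros(n)
    return RawRecording(
        t=t, ax=np.full(n, ax), ay=np.full(n, ay), az=np.full(n, az),
        gx=zeros, gy=zeros, gz=zeros, fs_nominal=fs,
    )


class TestReadRecording:
    def test_parses_toy_csv(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text(
            "t,ax,ay,az,gx,gy,gz\n"
            "0,0,1,0,0,0,0\n0.032,0,1,0,0,0,0\n0.064,0,1,0,0,0,0\n0.096,0,1,0,0,0,0\n"
        )
        rec = read_recording(str(p))
        assert len(rec) == 4
        assert rec.t[0] == 0.0

    def test_missing_gyro_columns_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,ax,ay,az\n0,0,1,0\n0.032,0,1,0\n")
        with pytest.raises(FormatError):
            read_recording(str(p))

    def test_non_monotonic_time_is_data_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "t,ax,ay,az,gx,gy,gz\n0,0,1,0,0,0,0\n0.05,0,1,0,0,0,0\n0.03,0,1,0,0,0,0\n"
        )
        with pytest.raises(DataError):
            read_recording(str(p))

    def test_write_read_round_trip(self, tmp_path, walk_trial):
        rec, _, _ = walk_trial
        p = tmp_path / "trip.csv"
        rec.to_csv(str(p))
        back = read_recording(str(p), rec.fs_nominal)
        for c in ("t", "ax", "ay", "az", "gx", "gy", "gz"):
            np.testing.assert_allclose(getattr(back, c), getattr(rec, c), rtol=0, atol=1e-12)


class TestResample:
    def test_uniform_input_is_unchanged(self):
        rec = _static_recording(0, 1, 0)
        out = resample_uniform(rec, FS)
        np.testing.assert_array_equal(out.t, rec.t)
        np.testing.assert_array_equal(out.ay, rec.ay)

    def test_linear_interpolation_midpoint(self):
        rec = RawRecording(
            t=np.array([0.0, 0.02, 0.06]),
            ax=np.array([0.0, 2.0, 6.0]), ay=np.zeros(3), az=np.zeros(3),
            gx=np.zeros(3), gy=np.zeros(3), gz=np.zeros(3), fs_nominal=25,
        )
        out = resample_uniform(rec, 25.0)
        assert out.ax[1] == pytest.approx(4.0)  # x(0.04) on the 25 Hz grid

    def test_jittered_sinusoid_recovered(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 10, 1 / FS) + rng.uniform(-3e-3, 3e-3, 313)
        t = np.sort(t)
        x = np.sin(2 * np.pi * 1.0 * t)
        rec = RawRecording(t=t, ax=x, ay=x, az=x, gx=x, gy=x, gz=x, fs_nominal=FS)
        out = resample_uniform(rec, FS)
        truth = np.sin(2 * np.pi * 1.0 * (out.t + t[0]))
        assert np.max(np.abs(out.ax - truth)) < 0.01

    def test_idempotence(self, walk_trial):
        rec, _, _ = walk_trial
        once = resample_uniform(rec, FS)
        twice = resample_uniform(once, FS)
        np.testing.assert_array_equal(once.ax, twice.ax)

    def test_too_short_is_data_error(self):
        rec = _static_recording(0, 1, 0, n=2)
        with pytest.raises(DataError):
            resample_uniform(RawRecording(
                t=rec.t[:1], ax=rec.ax[:1], ay=rec.ay[:1], az=rec.az[:1],
                gx=rec.gx[:1], gy=rec.gy[:1], gz=rec.gz[:1]), FS)


class TestTilt:
    def test_level_sensor_has_no_tilt(self):
        tx, tz = estimate_tilt(_static_recording(0, 1, 0))
        assert tx == pytest.approx(0.0)
        assert tz == pytest.approx(0.0)

    @pytest.mark.parametrize("deg,axis", [(5.0, "x"), (8.0, "z")])
    def test_known_rotation_recovered(self, deg, axis):
        s, c = np.sin(np.deg2rad(deg)), np.cos(np.deg2rad(deg))
        rec = _static_recording(s, c, 0) if axis == "x" else _static_recording(0, c, s)
        tx, tz = estimate_tilt(rec)
        got = tx if axis == "x" else tz
        assert np.degrees(got) == pytest.approx(deg, abs=0.01)

    def test_out_of_range_mean_is_clipped_with_warning(self):
        rec = _static_recording(1.5, 0.1, 0)
        with pytest.warns(UserWarning):
            tx, _ = estimate_tilt(rec)
        assert tx == pytest.approx(np.pi / 2)


class TestToAnatomical:
    def test_gravity_exactly_cancelled_when_level(self, config):
        sig = to_anatomical(_static_recording(0, 1, 0), 0.0, 0.0, config)
        for ch in (sig.aAP, sig.aML, sig.aV):
            np.testing.assert_allclose(ch, 0.0, atol=1e-12)

    def test_tilted_gravity_nearly_cancelled(self, config):
        # gravity vector seen by a sensor tilted 5 deg about x and 3 deg about z
        tx, tz = np.deg2rad(5.0), np.deg2rad(3.0)
        gx_ = np.sin(tx)
        gz_ = np.cos(tx) * np.sin(tz)
        gy_ = np.cos(tx) * np.cos(tz)
        rec = _static_recording(gx_, gy_, gz_)
        theta = estimate_tilt(rec)
        sig = to_anatomical(rec, *theta, config)
        assert abs(np.mean(sig.aV)) < 0.05
        assert abs(np.mean(sig.aAP)) < 0.05
        assert abs(np.mean(sig.aML)) < 0.05

    @pytest.mark.parametrize("deg", [2.0, 6.0, 10.0])
    def test_gravity_cancellation_up_to_ten_degrees(self, deg, config):
        tx = np.deg2rad(deg)
        rec = _static_recording(np.sin(tx), np.cos(tx), 0)
        sig = to_anatomical(rec, *estimate_tilt(rec), config)
        for ch in (sig.aV, sig.aAP, sig.aML):
            assert abs(np.mean(ch)) < 0.05

    def test_dynamic_vertical_closed_form(self, config):
        n, fs = 320, FS
        t = np.arange(n) / fs
        ay = 1 + 0.1 * np.sin(2 * np.pi * t)
        rec = RawRecording(t=t, ax=np.zeros(n), ay=ay, az=np.zeros(n),
                           gx=np.zeros(n), gy=np.zeros(n), gz=np.zeros(n), fs_nominal=fs)
        sig = to_anatomical(rec, 0.0, 0.0, config)
        np.testing.assert_allclose(sig.aV, 0.1 * GRAVITY_MS2 * np.sin(2 * np.pi * t), atol=1e-9)


class TestButterworth:
    def test_dc_gain_is_unity(self):
        x = np.full(300, 3.7)
        np.testing.assert_allclose(butterworth_lowpass(x, FS, 10.0), x, atol=1e-9)

    def test_stopband_and_passband_amplitudes(self):
        t = np.arange(0, 60, 1 / FS)
        lo = np.sin(2 * np.pi * 1.0 * t)
        hi = np.sin(2 * np.pi * 14.0 * t)
        y = butterworth_lowpass(lo + hi, FS, 10.0)
        mid = slice(200, -200)
        # residual high-frequency content, isolated by subtracting the slow part
        hi_out = y[mid] - butterworth_lowpass(lo, FS, 10.0)[mid]
        assert np.abs(hi_out).max() < np.abs(hi).max() / 20
        lo_amp = np.sqrt(2 * np.mean(butterworth_lowpass(lo, FS, 10.0)[mid] ** 2))
        assert lo_amp == pytest.approx(1.0, rel=0.02)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.zeros(100), FS, 16.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(500), rng.standard_normal(500)
        lhs = butterworth_lowpass(2.0 * x + 0.5 * y, FS, 10.0)
        rhs = 2.0 * butterworth_lowpass(x, FS, 10.0) + 0.5 * butterworth_lowpass(y, FS, 10.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_filtering_never_adds_energy(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.standard_normal(400)
            y = butterworth_lowpass(x - x.mean(), FS, 10.0)
            assert np.var(y) <= np.var(x) * (1 + 1e-9)


class TestAnnotation:
    def test_rejects_reversed_window(self):
        with pytest.raises(DataError):
            Annotation("a", "TUG", 5.0, 3.0)

    def test_rejects_unknown_test_label(self):
        with pytest.raises(FormatError):
            Annotation("a", "SPRINT", 0.0, 3.0)
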