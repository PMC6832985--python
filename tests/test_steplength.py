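"""Drift-free integration, Hurst estimation and the pendulum step-length model."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from imugait.config import PipelineConfig
from imugait.emd import emd, emd_drift_free_integral, hurst_exponent
from imugait.events import detect_contacts
from imugait.preprocess import preprocess
from imugait.steplength import (
    ModelError,
    calibrate_k,
    corrected_step_length,
    pendulum_step_length,
    step_height,
    vertical_excursion,
)
from imugait.synthetic import gen_walk

FS = 31.25


class TestEmd:
    def test_components_sum_to_signal(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 1.5 * t) + 0.2 * t + 0.3 * rng.standard_normal(len(t))
        comps = emd(x)
        np.testing.assert_allclose(comps.sum(axis=0), x, atol=1e-9)

    def test_drift_free_integral_of_pure_cosine(self):
        t = np.arange(0, 30, 1 / FS)
        out = emd_drift_free_integral(np.cos(2 * np.pi * 2 * t), FS)
        truth = np.sin(2 * np.pi * 2 * t) / (4 * np.pi)
        assert np.corrcoef(out, truth)[0, 1] > 0.99

    def test_linear_drift_removed(self):
        t = np.arange(0, 30, 1 / FS)
        out = emd_drift_free_integral(np.cos(2 * np.pi * 2 * t) + 0.05, FS)
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 0.005

    def test_zero_input_gives_zero_output(self):
        out = emd_drift_free_integral(np.zeros(500), FS)
        np.testing.assert_array_equal(out, 0.0)

    def test_pruning_is_nearly_idempotent(self):
        t = np.arange(0, 30, 1 / FS)
        once = emd_drift_free_integral(np.cos(2 * np.pi * 2 * t) + 0.05, FS)
        # feed the drift-free reconstruction's derivative back through
        deriv = np.gradient(once) * FS
        twice = emd_drift_free_integral(deriv, FS)
        rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert rms < 0.05


class TestHurst:
    def test_white_noise_near_half(self):
        rng = np.random.default_rng(0)
        assert hurst_exponent(rng.standard_normal(4096)) == pytest.approx(0.5, abs=0.1)

    def test_linear_ramp_is_persistent(self):
        assert hurst_exponent(np.linspace(0, 1, 1000)) > 0.9

    def test_alternating_sequence_is_antipersistent(self):
        assert hurst_exponent(np.tile([1.0, -1.0], 500)) < 0.2

    def test_constant_series_is_pure_trend(self):
        assert hurst_exponent(np.full(256, 2.0)) == 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hurst_exponent(np.zeros(32))


class TestStepHeight:
    def test_sinusoidal_displacement_range(self):
        from imugait.events import GaitEvents

        f_step = 2.0
        t = np.arange(0, 10, 1 / FS)
        disp = 0.025 * np.sin(2 * np.pi * f_step * t)
        # one step per half period, contacts at the displacement extrema so
        # each step window spans one peak and one trough
        tic = 0.125 + np.arange(0, 8.5, 0.5 / f_step)
        ev = GaitEvents(tic, tic + 0.1, np.array(["A"] * len(tic), dtype=object))
        h = step_height(disp, ev, FS)
        np.testing.assert_allclose(h, 0.05, rtol=0.02)

    def test_flat_displacement_gives_zero(self):
        from imugait.events import GaitEvents

        tic = np.array([0.5, 1.0, 1.5])
        ev = GaitEvents(tic, tic + 0.1, np.array(["A"] * 3, dtype=object))
        np.testing.assert_array_equal(step_height(np.zeros(100), ev, FS), 0.0)

    def test_generator_height_recovered(self, walk_trial):
        _, truth, sig = walk_trial
        ev = detect_contacts(sig.aVf, sig.fs)
        vx = vertical_excursion(sig.aVf, sig.fs, ev)
        assert 0.04 <= np.nanmean(vx.h) <= 0.06  # programmed 0.05 m

    def test_programmed_three_centimetres(self):
        rec, truth = gen_walk(f_step=1.8, n_steps=20, h_amp=0.03, seed=2)
        sig = preprocess(rec)
        ev = detect_contacts(sig.aVf, sig.fs)
        vx = vertical_excursion(sig.aVf, sig.fs, ev)
        assert 0.025 <= np.nanmean(vx.h) <= 0.035


class TestPendulumModel:
    def test_closed_form_values(self):
        assert pendulum_step_length(0.05, 1.0) == pytest.approx(2 * np.sqrt(0.0975), abs=1e-12)
        assert pendulum_step_length(0.0, 1.0) == 0.0
        assert pendulum_step_length(0.02, 1.0) == pytest.approx(0.39799, abs=5e-6)

    def test_invalid_height_rejected(self):
        with pytest.raises(ModelError):
            pendulum_step_length(1.2, 1.0)
        with pytest.raises(ModelError):
            pendulum_step_length(-0.01, 1.0)

    def test_monotone_in_height(self):
        h = np.linspace(0, 0.9, 200)
        l = pendulum_step_length(h, 1.0)
        assert np.all(np.diff(l) > 0)

    def test_corrected_length_examples(self):
        assert corrected_step_length(0.05, 1.0, 0.0, 5.0) == pytest.approx(0.6244998, abs=1e-6)
        got = corrected_step_length(0.05, 1.0, 1.13, 0.09)
        assert got == pytest.approx(0.6244998 + 0.1017, abs=1e-6)


class TestCalibration:
    def test_planted_constant_recovered_exactly(self):
        s = np.array([8.0, 9.0, 10.0, 11.0])
        l_hat = np.array([0.60, 0.62, 0.64, 0.66])
        assert calibrate_k(l_hat + 1.13 * s, l_hat, s) == pytest.approx(1.13, abs=1e-10)

    def test_zero_residual_gives_zero(self):
        s = np.array([8.0, 9.0, 10.0])
        l = np.array([0.6, 0.7, 0.8])
        assert calibrate_k(l, l, s) == 0.0

    def test_negative_constant(self):
        s = np.array([8.0, 9.0, 10.0, 11.0])
        l_hat = np.array([0.60, 0.62, 0.64, 0.66])
        assert calibrate_k(l_hat - 0.25 * s, l_hat, s) == pytest.approx(-0.25, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            calibrate_k([0.6, 0.7], [0.6, 0.7], [0.0, 0.0])

    def test_noise_free_linear_residual_recovery(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(6, 12, 30)
        l_hat = rng.uniform(0.5, 0.8, 30)
        k = -0.7321
        assert calibrate_k(l_hat + k * s, l_hat, s) == pytest.approx(k, abs=1e-10)


class TestEndToEnd:
    def test_programmed_step_length_recovered(self):
        # programmed 0.65 m steps: 2 sqrt(2 L h - h^2) = 0.65 with L = 1.0
        L = 1.0
        h = L - np.sqrt(L**2 - (0.65 / 2) ** 2)
        lengths = []
        for seed in (0, 1, 2):
            rec, truth = gen_walk(f_step=1.8, n_steps=30, h_amp=h, L=L, seed=seed)
            sig = preprocess(rec)
            ev = detect_contacts(sig.aVf, sig.fs)
            vx = vertical_excursion(sig.aVf, sig.fs, ev)
            valid = ~np.isnan(vx.h)
            lengths.append(np.mean(pendulum_step_length(vx.h[valid], L)))
        assert np.mean(lengths) == pytest.approx(0.65, rel=0.10)

    def test_generator_self_consistency_at_high_rate(self):
        # with no noise or transients the emitted acceleration must double-
        # integrate back to the programmed displacement; checked at a high
        # sampling rate where discretisation is negligible
        fs = 125.0
        rec, truth = gen_walk(noise_sd=0.0, hs_amp=0.0, seed=0, fs=fs)
        sig = preprocess(rec, PipelineConfig(fs=fs))
        v = cumulative_trapezoid(sig.aV, dx=1 / fs, initial=0)
        d = cumulative_trapezoid(v, dx=1 / fs, initial=0)
        diff = d - truth.disp
        diff -= np.polyval(np.polyfit(sig.t, diff, 2), sig.t)
        assert np.sqrt(np.mean(diff**2)) / np.std(truth.disp) < 0.02
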