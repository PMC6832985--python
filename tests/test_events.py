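"""Gait-event detection and temporal parameters."""

import numpy as np
import pytest

from imugait.events import (
    GaitEvents,
    assign_sides,
    detect_contacts,
    dominant_frequency,
    temporal_params,
)
from imugait.preprocess import preprocess
from imugait.synthetic import gen_walk

FS = 31.25


class TestDominantFrequency:
    def test_pure_tone(self):
        t = np.arange(0, 20, 1 / FS)
        f = dominant_frequency(np.sin(2 * np.pi * 1.8 * t), FS)
        assert f == pytest.approx(1.8, abs=1 / 20)

    def test_tone_in_noise(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 1.8 * t)
        noise = rng.standard_normal(len(t)) * np.sqrt(0.5 / 10 ** (10 / 10))
        assert dominant_frequency(x + noise, FS) == pytest.approx(1.8, abs=1 / 30)

    def test_larger_power_wins(self):
        t = np.arange(0, 20, 1 / FS)
        x = 1.0 * np.sin(2 * np.pi * 1.0 * t) + 2.0 * np.sin(2 * np.pi * 2.0 * t)
        assert dominant_frequency(x, FS) == pytest.approx(2.0, abs=1 / 20)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(np.zeros(30), FS)


class TestDetectContacts:
    def test_recovers_programmed_contacts(self, walk_trial):
        _, truth, sig = walk_trial
        ev = detect_contacts(sig.aVf, sig.fs)
        assert ev.n_steps == len(truth.t_ic)
        for ti in truth.t_ic:
            assert np.min(np.abs(ev.t_ic - ti)) <= 2 / sig.fs + 1e-9

    def test_close_pair_pruned_by_refractory_rule(self, walk_trial):
        # inject a sharp dip 0.1 s after a true contact: the spurious IC
        # candidate must be removed by the 0.25 s rule
        _, truth, sig = walk_trial
        ev0 = detect_contacts(sig.aVf, sig.fs)
        av = sig.aVf.copy()
        k = int(round((truth.t_ic[5] + 0.10) * sig.fs))
        w = np.arange(-4, 5)
        av[k + w] += 2.0 * (1 - (w / 1.5) ** 2) * np.exp(-(w**2) / 4.5)
        ev = detect_contacts(av, sig.fs)
        gaps = np.diff(ev.t_ic)
        assert np.all(gaps >= 0.25 - 1e-9)
        assert np.all(gaps <= 2.25 + 1e-9)
        assert ev.n_steps == ev0.n_steps

    def test_constant_input_yields_no_events(self):
        ev = detect_contacts(np.zeros(400), FS)
        assert ev.n_steps == 0
        assert len(ev.t_ec) == 0

    def test_amplitude_invariance(self, walk_trial):
        _, _, sig = walk_trial
        a = detect_contacts(sig.aVf, sig.fs)
        b = detect_contacts(3.7 * sig.aVf, sig.fs)
        np.testing.assert_allclose(a.t_ic, b.t_ic)
        np.testing.assert_allclose(a.t_ec, b.t_ec)

    def test_time_shift_equivariance(self, walk_trial):
        _, _, sig = walk_trial
        k = 16
        shifted = np.concatenate([sig.aVf[:1].repeat(k), sig.aVf[:-k]])
        a = detect_contacts(sig.aVf, sig.fs)
        b = detect_contacts(shifted, sig.fs, f_dom=a.f_dom)
        # compare events away from the window edges
        common_a = a.t_ic[(a.t_ic > 1.0) & (a.t_ic < sig.t[-1] - 1.5)]
        matched = [np.min(np.abs(b.t_ic - (ti + k / sig.fs))) for ti in common_a]
        assert max(matched) <= 1 / sig.fs + 1e-9


class TestAssignSides:
    def _events(self, times):
        return GaitEvents(np.asarray(times), np.asarray(times) + 0.1,
                          np.array(["A"] * len(times), dtype=object))

    def test_phase_locked_yaw_alternates(self):
        tic = 0.5 + np.arange(10) * 0.5
        t = np.arange(0, 8, 1 / FS)
        yaw = np.cos(2 * np.pi * 1.0 * (t - 0.5))  # +1 at even ICs, -1 at odd
        ev = assign_sides(self._events(tic), yaw, FS)
        assert list(ev.side) == ["A", "B"] * 5

    def test_zero_yaw_forces_alternation(self):
        tic = 0.5 + np.arange(8) * 0.5
        ev = assign_sides(self._events(tic), np.zeros(300), FS)
        assert list(ev.side) == ["A", "B"] * 4

    def test_sign_flip_swaps_labels(self):
        tic = 0.5 + np.arange(10) * 0.5
        t = np.arange(0, 8, 1 / FS)
        yaw = np.cos(2 * np.pi * 1.0 * (t - 0.5))
        a = assign_sides(self._events(tic), yaw, FS)
        b = assign_sides(self._events(tic), -yaw, FS)
        swap = {"A": "B", "B": "A"}
        assert [swap[s] for s in a.side] == list(b.side)

    def test_sides_match_generator_truth(self, walk_trial):
        _, truth, sig = walk_trial
        ev = assign_sides(detect_contacts(sig.aVf, sig.fs), sig.yaw_f, sig.fs)
        assert list(ev.side) == list(truth.side)


class TestTemporalParams:
    def test_worked_example(self):
        ev = GaitEvents(
            t_ic=np.array([0.0, 0.55, 1.10, 1.65]),
            t_ec=np.array([0.15, 0.70, 1.25, 1.80]),
            side=np.array(["A", "B", "A", "B"], dtype=object),
        )
        tp = temporal_params(ev)
        assert tp.t_stance[0] == pytest.approx(0.70)
        assert tp.t_stride[0] == pytest.approx(1.10)
        assert tp.t_step[0] == pytest.approx(0.55)
        assert tp.t_swing[0] == pytest.approx(0.40)

    def test_periodic_events(self):
        p = 0.5
        tic = np.arange(8) * p
        ev = GaitEvents(tic, tic + 0.1, np.array(["A"] * 8, dtype=object))
        tp = temporal_params(ev)
        np.testing.assert_allclose(tp.t_step, p)
        np.testing.assert_allclose(tp.t_stride, 2 * p)

    def test_swing_identity_holds_exactly(self, walk_trial):
        _, _, sig = walk_trial
        tp = temporal_params(detect_contacts(sig.aVf, sig.fs))
        np.testing.assert_array_equal(tp.t_swing, tp.t_stride - tp.t_stance)

    def test_step_count_equals_initial_contacts(self, walk_trial):
        _, truth, sig = walk_trial
        ev = detect_contacts(sig.aVf, sig.fs)
        assert temporal_params(ev).n_steps == ev.n_steps == len(truth.t_ic)

    def test_mean_step_time_matches_truth(self, walk_trial):
        _, truth, sig = walk_trial
        tp = temporal_params(detect_contacts(sig.aVf, sig.fs))
        assert np.mean(tp.t_step) == pytest.approx(1 / truth.f_step, abs=1 / sig.fs)

    def test_insufficient_events_give_empty_params(self):
        ev = GaitEvents(np.array([0.0, 0.5]), np.array([0.2]),
                        np.array(["A", "B"], dtype=object))
        tp = temporal_params(ev)
        assert len(tp.t_step) == 0
        assert tp.n_steps == 2


class TestSymmetricTiming:
    def test_symmetric_generator_has_equal_side_stance_times(self):
        rec, truth, = gen_walk(f_step=1.8, n_steps=24, asym=0.0, seed=9)
        sig = preprocess(rec)
        ev = assign_sides(detect_contacts(sig.aVf, sig.fs), sig.yaw_f, sig.fs)
        tp = temporal_params(ev)
        sides = np.asarray(ev.side[: len(tp.t_stance)])
        a = tp.t_stance[sides == "A"].mean()
        b = tp.t_stance[sides == "B"].mean()
        assert abs(a - b) <= 1 / sig.fs
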