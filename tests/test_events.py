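"""Event detection, response classification and the center-stim statistic."""

import numpy as np
import pytest

import polarflip as pf
from conftest import series_from_track
from polarflip.config import AnalysisConfig
from polarflip.events import (
    CenterStimResult,
    RegionActivitySeries,
    center_stim_response,
    classify_persistent,
    classify_transient,
    detect_events,
    estimate_responder_fraction,
)


def grid(t0=-63.0, t1=87.0, dt=3.0):
    return np.arange(t0, t1 + dt / 2, dt)


def make_series(t, front, rear, vel=None):
    front = np.asarray(front, float)
    rear = np.asarray(rear, float)
    s = RegionActivitySeries(
        time_s=t, front=front, rear=rear, middle=(front + rear) / 2,
        whole=(front + rear) / 2,
    )
    v = np.full(t.size, 0.14) if vel is None else np.asarray(vel, float)
    return s, v


class TestDetectEvents:
    def test_linear_rear_rise_crossing(self):
        """Rear 1.00 at t=0 rising to 1.06 at 30 s crosses +1% at exactly 5 s."""
        t = grid()
        rear = 1.0 + np.clip(t, 0, 30) * 0.002
        front = np.full(t.size, 1.2)
        vel = np.full(t.size, 0.1)
        e = detect_events(front, rear, vel, t)
        assert e.t_rear_response_s == pytest.approx(5.0, abs=1e-9)
        assert e.t_front_response_s is None

    def test_velocity_zero_crossing(self):
        t = grid()
        vel = np.interp(t, [-63, 24, 27, 87], [2 / 60, 2 / 60, -2 / 60, -2 / 60])
        e = detect_events(np.full(t.size, 1.2), np.ones(t.size), vel, t)
        assert e.t_stall_s == pytest.approx(25.5, abs=1e-9)

    def test_crosspoint_solves_intersection(self):
        t = grid(t1=120.0)
        front = np.full(t.size, 1.10)
        rear = 1.0 + np.clip(t, 0, None) * 0.002
        e = detect_events(front, rear, np.full(t.size, 0.1), t)
        assert e.t_crosspoint_s == pytest.approx(50.0, abs=1e-9)

    def test_front_decay_crossing(self):
        t = grid()
        front = 1.10 - np.clip(t - 6, 0, None) * 0.0011
        e = detect_events(front, np.ones(t.size), np.full(t.size, 0.1), t)
        # 1% of 1.10 = 0.011 below baseline, reached 10 s after decay onset
        assert e.t_front_response_s == pytest.approx(16.0, abs=1e-9)

    def test_requires_sample_at_zero(self):
        t = grid() + 0.5
        with pytest.raises(ValueError, match="t = 0"):
            detect_events(np.ones(t.size), np.ones(t.size), np.ones(t.size), t)

    def test_requires_common_grid(self):
        t = grid()
        with pytest.raises(ValueError, match="time grid"):
            detect_events(np.ones(t.size), np.ones(t.size - 1)[: t.size - 1], np.ones(t.size), t)

    def test_undetected_events_reported_as_none(self):
        t = grid()
        e = detect_events(
            np.full(t.size, 1.2), np.ones(t.size), np.full(t.size, 0.1), t
        )
        assert e.t_rear_response_s is None
        assert e.t_stall_s is None
        assert e.t_crosspoint_s is None
        assert e.detected_order() == []


class TestClassifyTransient:
    def bump(self, t, amp, start=0.0, end=40.0):
        return np.clip((t - start) / 10, 0, 1) * np.where(t < end, 1, 1) * amp

    def test_small_rise_is_no_response(self):
        t = grid()
        rear = 1.0 + 0.015 * np.clip(t / 10, 0, 1)  # 1.5% < 2%
        s, v = make_series(t, np.full(t.size, 1.2), rear)
        assert classify_transient(s, v).transient_class == "no_response"

    def test_rise_without_front_engagement_is_medium(self):
        t = grid()
        rear = 1.0 + 0.05 * np.clip(t / 10, 0, 1)  # max rear 1.05
        front = np.full(t.size, 1.20)  # gap 0.15 > 0.03
        s, v = make_series(t, front, rear)
        label = classify_transient(s, v)
        assert label.transient_class == "medium"
        assert label.evidence["engagement_gap"] == pytest.approx(0.15)

    def test_engaged_front_with_recovered_direction_is_strong(self):
        t = grid()
        rear = 1.0 + 0.08 * np.clip(t / 10, 0, 1)
        front = 1.20 - 0.11 * np.clip(t / 20, 0, 1)  # min 1.09, gap 0.01
        vel = np.interp(t, [0, 24, 30, 45, 51, 87], [0.1, 0.1, -0.1, -0.1, 0.1, 0.1])
        s, v = make_series(t, front, rear, vel)
        assert classify_transient(s, v).transient_class == "strong"

    def test_sustained_flip_is_reversed(self):
        t = grid()
        rear = 1.0 + 0.25 * np.clip(t / 30, 0, 1)
        front = 1.20 - 0.25 * np.clip(t / 30, 0, 1)
        vel = np.interp(t, [0, 24, 30, 87], [0.1, 0.1, -0.1, -0.1])
        s, v = make_series(t, front, rear, vel)
        assert classify_transient(s, v).transient_class == "reversed"

    def test_insufficient_prestimulus_history_rejected(self):
        t = np.arange(-6, 30, 3.0)
        s, v = make_series(t, np.full(t.size, 1.2), np.ones(t.size))
        with pytest.raises(ValueError, match="pre-stimulus"):
            classify_transient(s, v)

    def test_noise_free_generator_round_trip(self, acq):
        for label in ("no_response", "medium", "strong", "reversed"):
            tr = pf.simulate_cell_track(pf.default_kinetics(label), acq, n_frames=51)
            s, v = series_from_track(tr)
            assert classify_transient(s, v).transient_class == label


class TestClassifyPersistent:
    def test_generator_round_trip(self, acq):
        for label, expect in (("reverser", "reverser"), ("non_reverser", "non_reverser")):
            tr = pf.simulate_cell_track(
                pf.default_kinetics(label), acq, n_frames=61, stim_mode="persistent"
            )
            s, v = series_from_track(tr)
            assert classify_persistent(s, v).persistent_class == expect

    def test_direction_flip_without_activity_flip_is_non_reverser(self):
        t = grid()
        front = np.full(t.size, 1.2)
        rear = np.ones(t.size)
        vel = np.interp(t, [0, 24, 30, 87], [0.1, 0.1, -0.1, -0.1])
        s, v = make_series(t, front, rear, vel)
        assert classify_persistent(s, v).persistent_class == "non_reverser"

    def test_ambiguous_displacement_warns_non_reverser(self):
        t = grid()
        rear = 1.0 + 0.25 * np.clip(t / 30, 0, 1)
        front = 1.20 - 0.25 * np.clip(t / 30, 0, 1)
        vel = np.interp(t, [0, 40, 46, 87], [0.02, 0.02, -0.02, -0.02])
        s, v = make_series(t, front, rear, vel)
        with pytest.warns(UserWarning, match="ambiguous"):
            label = classify_persistent(s, v, cell_length_um=25.0)
        assert label.persistent_class == "non_reverser"


class TestCenterStim:
    def test_constant_trace_gives_unit_ratios(self):
        t = grid()
        res = center_stim_response(np.ones(t.size), t)
        assert res.control_response == pytest.approx(1.0)
        assert res.peak_response == pytest.approx(1.0)

    def test_bump_peaking_at_15s(self):
        t = grid()
        y = 1.0 + 0.1 * np.clip(np.minimum(t / 15, (30 - t) / 15), 0, None)
        res = center_stim_response(y, t)
        assert res.peak_time_s == pytest.approx(15.0)
        assert res.control_response == pytest.approx(1.0)
        assert res.peak_response > 1.0

    def test_incomplete_coverage_rejected(self):
        t = np.arange(-30, 60, 3.0)
        with pytest.raises(ValueError, match="cover"):
            center_stim_response(np.ones(t.size), t)


class TestResponderFraction:
    def make(self, control, peak):
        return [
            CenterStimResult(control_response=c, peak_response=p, peak_time_s=15.0)
            for c, p in zip(control, peak)
        ]

    def test_all_responders_approach_one(self):
        rng = np.random.default_rng(0)
        control = rng.normal(1.0, 0.005, 200)
        peak = rng.normal(1.15, 0.01, 200)
        f_med, f_str, thr = estimate_responder_fraction(self.make(control, peak))
        assert f_med == pytest.approx(1.0, abs=0.02)
        assert f_str == pytest.approx(1.0, abs=0.02)
        assert thr["control_median"] == pytest.approx(1.0, abs=0.01)

    def test_null_cohort_stringent_near_alpha(self):
        rng = np.random.default_rng(1)
        control = rng.normal(1.0, 0.01, 1000)
        peak = rng.normal(1.0, 0.01, 1000)
        f_med, f_str, _ = estimate_responder_fraction(self.make(control, peak))
        assert f_str == pytest.approx(0.05, abs=0.02)
        assert f_med == pytest.approx(0.0, abs=0.06)

    def test_scaling_all_traces_leaves_estimates_unchanged(self):
        t, traces, _ = pf.simulate_center_stim_cohort(100, 0.6, seed=3)
        def estimates(tr):
            res = [center_stim_response(row, t) for row in tr]
            f1, f2, _ = estimate_responder_fraction(res)
            return f1, f2
        base = estimates(traces)
        scaled = estimates(traces * 7.3)
        assert scaled[0] == pytest.approx(base[0], abs=0.02)
        assert scaled[1] == pytest.approx(base[1], abs=0.02)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            estimate_responder_fraction(self.make(np.ones(5) + 1e-3, np.ones(5)))

    def test_degenerate_control_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_responder_fraction(self.make(np.ones(30), np.ones(30)))


def test_config_windows_match_assay_design():
    cfg = AnalysisConfig()
    assert cfg.window_control1_s == (-60.0, -42.0)
    assert cfg.window_control2_s == (-39.0, -21.0)
    assert cfg.window_control3_s == (-18.0, 0.0)
    assert cfg.peak_search_s == (3.0, 33.0)
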