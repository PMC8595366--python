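"""Generator contracts: determinism, ground-truth schedules, rendering model."""

import numpy as np
import pytest

import polarflip as pf
from polarflip.events import detect_events
from polarflip.synthetic import (
    CellKinetics,
    derive_cell_seed,
    simulate_cohort,
    superellipse_mask,
)


def test_zero_velocity_keeps_centroid_constant(acq):
    kin = pf.default_kinetics("no_response", baseline_speed_um_s=0.0)
    tr = pf.simulate_cell_track(kin, acq, n_frames=10, stim_frame=5)
    assert np.allclose(tr.centroid_row, tr.centroid_row[0])
    assert np.allclose(tr.centroid_col, tr.centroid_col[0])


def test_no_response_rear_trace_is_flat(acq):
    tr = pf.simulate_cell_track(pf.default_kinetics("no_response"), acq, n_frames=51)
    assert np.ptp(tr.rear_trace) == 0.0
    assert np.ptp(tr.front_trace) == 0.0


def test_reversed_truth_profiles_cross_at_configured_time(acq, reversed_track):
    """Front and rear profile means intersect at the configured cross-point
    (51 s = between 17 and 18 frames post-stimulus at 3 s/frame)."""
    tr = reversed_track
    diff = tr.front_trace - tr.rear_trace
    post = np.flatnonzero(tr.time_s >= 0)
    sign_change = np.flatnonzero(np.diff(np.sign(diff[post])) < 0)
    k = post[sign_change[0]]
    assert 16 <= k - tr.stim_frame <= 18
    # interpolated crossing is exact
    t0, t1 = tr.time_s[k], tr.time_s[k + 1]
    frac = diff[k] / (diff[k] - diff[k + 1])
    assert t0 + frac * (t1 - t0) == pytest.approx(51.0, abs=1e-9)


def test_ground_truth_event_schedule_realized(acq, reversed_track):
    """Running the detector on the noise-free ground-truth traces recovers the
    configured event schedule exactly (linear interpolation on linear ramps)."""
    tr = reversed_track
    e = detect_events(tr.front_trace, tr.rear_trace, tr.velocity_um_s, tr.time_s)
    kin = tr.kinetics
    assert e.t_rear_response_s == pytest.approx(kin.rear_rise_onset_s, abs=1e-9)
    assert e.t_front_response_s == pytest.approx(kin.front_decay_onset_s, abs=1e-9)
    assert e.t_stall_s == pytest.approx(kin.stall_time_s, abs=1e-9)
    assert e.t_crosspoint_s == pytest.approx(kin.crosspoint_time_s, abs=1e-9)


def test_invalid_class_and_disordered_schedule_rejected():
    with pytest.raises(ValueError, match="invalid class"):
        CellKinetics(class_label="sideways")
    with pytest.raises(ValueError, match="ordered"):
        CellKinetics(class_label="reversed", stall_time_s=60.0)


def test_render_determinism_bit_exact(acq):
    import dataclasses

    noisy = dataclasses.replace(acq, gaussian_sd=50.0, poisson=True)
    kin = pf.default_kinetics("reversed")
    tr = pf.simulate_cell_track(kin, noisy, n_frames=5, stim_frame=2)
    fs1, m1 = pf.render_frames(tr, noisy, seed=42)
    fs2, m2 = pf.render_frames(tr, noisy, seed=42)
    assert np.array_equal(fs1.channel_a, fs2.channel_a)
    assert np.array_equal(fs1.channel_b, fs2.channel_b)
    assert np.array_equal(m1, m2)
    fs3, _ = pf.render_frames(tr, noisy, seed=43)
    assert not np.array_equal(fs1.channel_a, fs3.channel_a)


def test_noise_free_flat_field_uniform_activity_gives_unit_ratio(acq):
    kin = pf.default_kinetics("no_response", front_rear_ratio0=1.0, rear_baseline=1.0)
    tr = pf.simulate_cell_track(kin, acq, n_frames=2, stim_frame=1)
    fs, masks = pf.render_frames(tr, acq, seed=0)
    d = fs.channel_a[0] - acq.dark_offset
    a = fs.channel_b[0] - acq.dark_offset
    ratio = a[masks[0]] / d[masks[0]]
    assert np.allclose(ratio, 1.0, atol=1e-12)


def test_ratio_bias_field_multiplies_measured_ratio(acq):
    import dataclasses

    nr, nc = acq.field_shape
    bias = np.linspace(0.9, 1.1, nr)[:, None] * np.ones((1, nc))
    acq_b = dataclasses.replace(acq, ratio_bias_field=bias)
    kin = pf.default_kinetics("no_response", front_rear_ratio0=1.0, rear_baseline=1.0)
    tr = pf.simulate_cell_track(kin, acq_b, n_frames=2, stim_frame=1)
    fs, masks = pf.render_frames(tr, acq_b, seed=0)
    m = masks[0]
    d = fs.channel_a[0] - acq.dark_offset
    a = fs.channel_b[0] - acq.dark_offset
    assert np.allclose((a / d)[m], bias[m], atol=1e-12)


def test_render_rejects_track_outside_field(acq):
    kin = pf.default_kinetics("no_response")
    tr = pf.simulate_cell_track(kin, acq, n_frames=5, stim_frame=2, start_row=30.0)
    with pytest.raises(ValueError, match="outside the field"):
        pf.render_frames(tr, acq)


def test_superellipse_mask_is_elongated_along_rows():
    m = superellipse_mask((64, 64), (32, 32), (20, 8))
    rows, cols = np.nonzero(m)
    assert rows.max() - rows.min() > cols.max() - cols.min()


class TestCohort:
    def test_single_class_mix(self, acq):
        scenes = simulate_cohort({"reversed": 1.0}, 5, acq, seed=1, render=False)
        assert len(scenes) == 5
        assert all(s.kinetics.class_label == "reversed" for s in scenes)

    def test_n_one_records_master_derived_seed(self, acq):
        scenes = simulate_cohort({"no_response": 1.0}, 1, acq, seed=9, render=False)
        assert len(scenes) == 1
        assert scenes[0].seed == derive_cell_seed(9, 0)

    def test_zero_cells_rejected(self, acq):
        with pytest.raises(ValueError):
            simulate_cohort({"reversed": 1.0}, 0, acq)

    def test_bad_mix_rejected(self, acq):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_cohort({"reversed": 0.5}, 3, acq)
        with pytest.raises(ValueError, match="invalid class"):
            simulate_cohort({"sideways": 1.0}, 3, acq)

    def test_realized_fractions_near_study_mix(self, acq):
        """With the observed class mix, realized fractions stay within
        binomial sampling error of the proportions."""
        mix = {"no_response": 0.56, "medium": 0.21, "strong": 0.07, "reversed": 0.16}
        n = 400
        scenes = simulate_cohort(mix, n, acq, seed=3, render=False)
        labels = [s.kinetics.class_label for s in scenes]
        for cls, p in mix.items():
            frac = labels.count(cls) / n
            assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_per_cell_seeds_stable_under_cohort_size(self):
        assert derive_cell_seed(5, 3) == derive_cell_seed(5, 3)
        assert derive_cell_seed(5, 3) != derive_cell_seed(5, 4)
        assert derive_cell_seed(5, 3) != derive_cell_seed(6, 3)
        assert 0 <= derive_cell_seed(5, 3) < 2**31


def test_center_stim_cohort_shapes_and_flat_nonresponders():
    t, traces, is_resp = pf.simulate_center_stim_cohort(
        30, 0.5, seed=2, noise_sd=0.0
    )
    assert traces.shape == (30, t.size)
    flat = traces[~is_resp]
    assert np.allclose(flat, 1.0)
    bumps = traces[is_resp]
    assert (bumps.max(axis=1) > 1.01).all()
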