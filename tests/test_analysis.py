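"""Ground-truth recovery by the iTUG and gait detectors."""

import numpy as np
import pytest

import dndmotion as dm
from dndmotion.errors import InsufficientDataError, SegmentationError


def test_clean_itug_boundaries_recovered(clean_itug):
    session, truth = clean_itug
    seg = dm.segment_itug(session)
    assert np.abs(seg.boundaries - truth.boundaries).max() <= 0.05


def test_noisy_itug_boundaries_recovered(noisy_itug):
    session, truth = noisy_itug
    seg = dm.segment_itug(session)
    assert np.abs(seg.boundaries - truth.boundaries).max() <= 0.15


def test_static_session_fails_segmentation():
    with pytest.raises(SegmentationError):
        dm.segment_itug(dm.generate_static(10.0))


def test_itug_indexes_recover_profile(noisy_itug):
    session, truth = noisy_itug
    profile = truth.profile
    res = dm.analyze_itug(session)
    assert res.steps_during_walking == 2 * profile.steps_per_bout
    assert res.standing_max_inclination_deg == pytest.approx(
        profile.stand_inclination_deg, abs=1.0
    )
    assert res.sitting_max_inclination_deg == pytest.approx(
        profile.sit_inclination_deg, abs=1.0
    )
    assert res.turn_angular_velocity_dps == pytest.approx(
        profile.turn_peak_dps, rel=0.1
    )
    assert res.test_duration_s == pytest.approx(profile.total_s, abs=0.3)


def test_itug_phase_durations_sum_to_test_duration(noisy_itug):
    session, _ = noisy_itug
    res = dm.analyze_itug(session)
    assert sum(res.phase_durations_s.values()) == pytest.approx(
        res.test_duration_s, abs=0.05
    )


def test_risk_category_follows_duration_cutoffs():
    fast = dm.ITUGProfile(go_walk_s=1.6, back_walk_s=1.6, turn_s=1.2, presit_turn_s=1.2,
                          stand_s=1.0, sit_s=1.0)  # ~7.6 s
    slow = dm.ITUGProfile(go_walk_s=4.0, back_walk_s=4.0, turn_s=2.5, presit_turn_s=2.5,
                          stand_s=2.0, sit_s=2.0)  # ~17 s
    for profile, expected in ((fast, "Normal"), (slow, "High Risk")):
        ses, _ = dm.generate_itug(profile, dm.NoiseModel.table_defaults(), seed=2)
        assert dm.analyze_itug(ses).risk_category == expected


def test_clean_walk_event_recovery(clean_walk):
    session, truth = clean_walk
    ev = dm.detect_gait_events(session)
    ic = ev.all_ic()
    assert len(ic) == truth.n_steps == 20
    assert np.abs(np.sort(ic) - np.sort(truth.ic_times)).max() <= 0.05


def test_event_invariants_alternating_feet_ic_before_fc(noisy_walk):
    session, _ = noisy_walk
    ev = dm.detect_gait_events(session)
    # feet alternate in the chronological merge
    merged = sorted(
        [(t, "L") for t in ev.ic["L"]] + [(t, "R") for t in ev.ic["R"]]
    )
    labels = [f for _, f in merged]
    assert all(a != b for a, b in zip(labels, labels[1:]))
    for foot in ("L", "R"):
        assert ev.fc[foot][0] > ev.ic[foot][0]


def test_too_short_walk_raises(clean_walk):
    session, _ = clean_walk
    short = dm.SensorSession(
        session.t[:300],
        session.accel[:300],
        session.gyro[:300],
        session.quat[:300],
        session.rate_hz,
    )
    with pytest.raises(InsufficientDataError):
        dm.detect_gait_events(short)


def test_gait_parameters_recover_truth(noisy_walk):
    session, truth = noisy_walk
    res = dm.analyze_t10m(session)
    assert res.cadence_spm == pytest.approx(truth.cadence_spm, abs=2.0)
    assert res.walking_speed_mps == pytest.approx(truth.speed_mps, rel=0.05)
    assert res.step_length_m == pytest.approx(
        truth.distance_m / truth.n_steps, rel=1e-6
    )
    assert res.stride_time_s == pytest.approx(truth.stride_time_s, abs=0.03)
    assert res.stance_pct == pytest.approx(100 * truth.stance_fraction, abs=2.0)
    assert res.gait_symmetry == pytest.approx(0.0, abs=0.02)


def test_gait_internal_consistency_identities(noisy_walk):
    session, _ = noisy_walk
    res = dm.analyze_t10m(session)
    assert res.swing_pct + res.stance_pct == pytest.approx(100.0, abs=0.5)
    assert res.stride_time_s == pytest.approx(2 * res.step_time_s, rel=0.05)
    assert res.cadence_spm == pytest.approx(60.0 / res.step_time_s, rel=1e-9)
    assert res.stride_length_m == pytest.approx(2 * res.step_length_m, rel=1e-9)


def test_asymmetric_gait_detected():
    ses, truth = dm.generate_t10m(
        dm.GaitProfile(asymmetry=1.15), dm.NoiseModel.table_defaults(), seed=4
    )
    res = dm.analyze_t10m(ses)
    expected = abs(truth.step_time_left_s - truth.step_time_right_s) / (
        0.5 * (truth.step_time_left_s + truth.step_time_right_s)
    )
    assert res.gait_symmetry == pytest.approx(expected, abs=0.03)


def test_analysis_is_deterministic(noisy_walk):
    session, _ = noisy_walk
    a = dm.analyze_t10m(session)
    b = dm.analyze_t10m(session)
    assert a == b
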