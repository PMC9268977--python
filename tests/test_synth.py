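"""Synthetic session generation: determinism, morphology, noise model."""

import numpy as np
import pytest
from scipy import signal as sps

import dndmotion as dm
from dndmotion.errors import ParameterError
from dndmotion.synth import G_MS2


def test_static_session_is_gravity_only():
    ses = dm.generate_static(3.0)
    assert len(ses) == 300
    assert np.allclose(ses.accel, [0.0, 0.0, G_MS2])
    assert np.allclose(ses.gyro, 0.0)
    assert np.allclose(np.linalg.norm(ses.quat, axis=1), 1.0)


def test_itug_session_length_matches_rate():
    profile = dm.ITUGProfile()
    ses, truth = dm.generate_itug(profile, dm.NoiseModel.none())
    total = profile.lead_in_s + profile.total_s + profile.lead_out_s
    assert len(ses) == round(100 * total)
    assert truth.total_duration_s == pytest.approx(profile.total_s)
    assert np.diff(ses.t) == pytest.approx(0.01)


def test_itug_truth_phases_are_contiguous_and_ordered():
    _, truth = dm.generate_itug(noise=dm.NoiseModel.none())
    b = truth.boundaries
    assert np.all(np.diff(b) > 0)
    names = dm.ITUGProfile.PHASE_NAMES
    for i, name in enumerate(names):
        assert truth.phase_bounds[name] == (pytest.approx(b[i]), pytest.approx(b[i + 1]))


@pytest.mark.parametrize("steps", [4, 6, 8])
def test_step_impact_count_per_walking_bout(steps):
    profile = dm.ITUGProfile(steps_per_bout=steps)
    ses, truth = dm.generate_itug(profile, dm.NoiseModel.none())
    az = ses.accel[:, 2] - G_MS2
    for bout in ("go_walk", "back_walk"):
        s, e = truth.phase_bounds[bout]
        w = az[int(s * 100) : int(e * 100)]
        peaks, _ = sps.find_peaks(w, height=0.5 * profile.step_impact_accel)
        assert len(peaks) == steps


def test_itug_inclination_encoded_in_pitch():
    profile = dm.ITUGProfile(stand_inclination_deg=15.0)
    ses, truth = dm.generate_itug(profile, dm.NoiseModel.none())
    pitch = ses.pitch_deg()
    s, e = truth.phase_bounds["standing"]
    assert np.max(pitch[int(s * 100) : int(e * 100)]) == pytest.approx(15.0, abs=0.05)
    # quiet outside posture transients
    assert np.max(np.abs(pitch[: int(s * 100)])) < 0.01


def test_itug_rejects_non_positive_durations():
    with pytest.raises(ParameterError):
        dm.generate_itug(dm.ITUGProfile(turn_s=0.0), dm.NoiseModel.none())


def test_t10m_step_count_and_duration():
    profile = dm.GaitProfile(cadence_spm=120.0, speed_mps=1.0, distance_m=10.0)
    _, truth = dm.generate_t10m(profile, dm.NoiseModel.none())
    assert truth.n_steps == 20
    assert truth.duration_s == pytest.approx(10.0)
    assert truth.cadence_spm == pytest.approx(120.0)


def test_t10m_symmetric_profile_has_equal_step_times():
    _, truth = dm.generate_t10m(
        dm.GaitProfile(asymmetry=1.0), dm.NoiseModel.none()
    )
    assert truth.step_time_left_s == pytest.approx(truth.step_time_right_s)
    asym = dm.generate_t10m(dm.GaitProfile(asymmetry=1.1), dm.NoiseModel.none())[1]
    assert asym.step_time_left_s > asym.step_time_right_s
    assert asym.step_time_left_s / asym.step_time_right_s == pytest.approx(1.1)


def test_t10m_fc_follows_ic_by_stance_fraction():
    _, truth = dm.generate_t10m(dm.GaitProfile(stance_fraction=0.6), dm.NoiseModel.none())
    lag = truth.fc_times - truth.ic_times
    assert lag == pytest.approx(0.6 * truth.stride_time_s)


def test_zero_noise_model_is_identity(clean_itug):
    ses, _ = clean_itug
    out = dm.add_noise(ses, dm.NoiseModel.none(), seed=3)
    assert np.array_equal(out.accel, ses.accel)
    assert np.array_equal(out.gyro, ses.gyro)
    assert np.array_equal(out.quat, ses.quat)


def test_noise_injection_deterministic_per_seed(clean_itug):
    ses, _ = clean_itug
    a = dm.add_noise(ses, dm.NoiseModel.table_defaults(), seed=9)
    b = dm.add_noise(ses, dm.NoiseModel.table_defaults(), seed=9)
    c = dm.add_noise(ses, dm.NoiseModel.table_defaults(), seed=10)
    assert np.array_equal(a.accel, b.accel) and np.array_equal(a.gyro, b.gyro)
    assert not np.array_equal(a.accel, c.accel)


def test_noise_rms_and_offset_match_model():
    st = dm.generate_static(1000.0)  # 1e5 samples
    noisy = dm.add_noise(st, dm.NoiseModel.table_defaults(), seed=5)
    added = (noisy.accel - st.accel) / G_MS2
    model = dm.NoiseModel.table_defaults()
    for ax in range(3):
        assert np.std(added[:, ax]) == pytest.approx(model.accel_rms_g[ax], rel=0.05)
        assert np.mean(added[:, ax]) == pytest.approx(model.accel_offset_g[ax], abs=1e-4)
    for ax in range(3):
        assert np.std(noisy.gyro[:, ax] - st.gyro[:, ax]) == pytest.approx(
            model.gyro_rms_dps[ax], rel=0.05
        )


def test_quaternions_stay_unit_after_noise(noisy_itug):
    ses, _ = noisy_itug
    assert np.linalg.norm(ses.quat, axis=1) == pytest.approx(1.0, abs=1e-9)


def test_negative_rms_rejected():
    with pytest.raises(ParameterError):
        dm.NoiseModel(accel_rms_g=(-0.001, 0.0, 0.0))
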