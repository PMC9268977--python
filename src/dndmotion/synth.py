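"""Synthetic 100 Hz lumbar-IMU sessions with exact ground truth.

Generates the two instrumented clinical tests analysed by this package:

* an instrumented Timed Up & Go (iTUG): stand up from a chair, walk 3 m,
  turn, walk back, turn again, sit down — six ordered phases;
* an instrumented 10 m walk: a straight walk at a configurable cadence
  and speed.

The sensor is modelled on the lower back (L3–L5).  Axis convention:
X anterior–posterior, Y medio-lateral, Z vertical; accelerations in
m/s², angular velocities in °/s, orientation as unit quaternions
(w, x, y, z).  Trunk inclination (forward lean) is pitch about Y; turns
are yaw about Z.

Waveform morphology is a deliberate simplification: posture transients
and turns are raised-cosine profiles spanning their phase, and foot
impacts are Gaussian acceleration bumps.  Real signals are messier; the
generator's contract is that its ground truth (phase boundaries, event
times, cadence, inclination peaks) is exactly consistent with the
emitted trace, so detector accuracy can be measured without recordings.

The additive noise model follows a 140 min static characterisation of a
BNO055-class MIMU: per-axis accelerometer RMS noise and constant
offsets (in G), per-axis gyroscope RMS noise (°/s), and a slow linear
Euler drift folded into the quaternions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError

__all__ = [
    "G_MS2",
    "IMUSample",
    "SensorSession",
    "NoiseModel",
    "ITUGProfile",
    "ITUGTruth",
    "GaitProfile",
    "GaitTruth",
    "generate_itug",
    "generate_t10m",
    "generate_static",
    "add_noise",
]

#: standard gravity, m/s² — converts Table-style G units to m/s²
G_MS2 = 9.80665

RATE_HZ = 100.0


@dataclass(frozen=True)
class IMUSample:
    """One timestamped reading: accel m/s², gyro °/s, unit quaternion."""

    t: float
    accel: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray


@dataclass
class SensorSession:
    """A uniformly sampled IMU stream (default 100 Hz)."""

    t: np.ndarray
    accel: np.ndarray  # (n, 3) m/s²
    gyro: np.ndarray  # (n, 3) °/s
    quat: np.ndarray  # (n, 4) w, x, y, z
    rate_hz: float = RATE_HZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ParameterError("accel/gyro must be (n, 3) arrays")
        if self.quat.shape != (n, 4):
            raise ParameterError("quat must be an (n, 4) array")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.rate_hz, atol=1e-6):
                raise ParameterError(
                    f"sample spacing must be 1/{self.rate_hz} s throughout"
                )
        norms = np.linalg.norm(self.quat, axis=1)
        if n and not np.allclose(norms, 1.0, atol=1e-6):
            raise ParameterError("quaternions must be unit norm within 1e-6")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    def samples(self) -> Iterator[IMUSample]:
        """Yield one sample at a time (the streaming/disposable path)."""
        for i in range(len(self)):
            yield IMUSample(
                float(self.t[i]), self.accel[i], self.gyro[i], self.quat[i]
            )

    def copy(self) -> "SensorSession":
        return SensorSession(
            self.t.copy(),
            self.accel.copy(),
            self.gyro.copy(),
            self.quat.copy(),
            self.rate_hz,
            dict(self.meta),
        )

    def pitch_deg(self) -> np.ndarray:
        """Trunk pitch (rotation about Y), degrees, from the quaternions."""
        r = Rotation.from_quat(self.quat[:, [1, 2, 3, 0]])  # to x,y,z,w
        return r.as_euler("ZYX", degrees=True)[:, 1]


@dataclass(frozen=True)
class NoiseModel:
    """Additive sensor-noise parameters (static characterisation).

    Accelerometer values are in G (converted with g = 9.80665 m/s²);
    gyroscope values in °/s; Euler drift rates in °/s for (yaw, pitch,
    roll).  The defaults are the measured static figures of the target
    MIMU; pass :meth:`none` for noiseless output.
    """

    accel_rms_g: tuple = (0.0011, 0.0011, 0.0014)
    accel_offset_g: tuple = (0.013, 0.033, 0.150)
    gyro_rms_dps: tuple = (1.12, 1.42, 1.41)
    euler_drift_dps: tuple = (0.0, 2.88e-6, 1.60e-5)  # yaw, pitch, roll

    def __post_init__(self):
        for name in ("accel_rms_g", "gyro_rms_dps"):
            if any(v < 0 for v in getattr(self, name)):
                raise ParameterError(f"{name}: RMS values must be >= 0")

    @classmethod
    def table_defaults(cls) -> "NoiseModel":
        return cls()

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls((0.0,) * 3, (0.0,) * 3, (0.0,) * 3, (0.0,) * 3)

    @property
    def is_zero(self) -> bool:
        return all(
            all(v == 0 for v in getattr(self, f))
            for f in ("accel_rms_g", "accel_offset_g", "gyro_rms_dps", "euler_drift_dps")
        )


# ---------------------------------------------------------------------------
# iTUG


@dataclass(frozen=True)
class ITUGProfile:
    """Ground-truth parameters of a synthetic Timed Up & Go.

    Durations in seconds; the six phases run in the fixed order
    stand → go-walk → turn → back-walk → pre-sit turn → sit.  Defaults
    describe a mildly slow performer (total 11.5 s).
    """

    stand_s: float = 1.4
    go_walk_s: float = 2.6
    turn_s: float = 1.6
    back_walk_s: float = 2.6
    presit_turn_s: float = 1.8
    sit_s: float = 1.5
    stand_inclination_deg: float = 15.0
    sit_inclination_deg: float = 12.0
    stand_peak_accel: float = 2.0  # m/s², vertical transient
    sit_peak_accel: float = 1.8
    turn_peak_dps: float = 150.0
    presit_turn_peak_dps: float = 120.0
    steps_per_bout: int = 6
    step_impact_accel: float = 2.5  # m/s²
    lead_in_s: float = 1.5
    lead_out_s: float = 1.5

    PHASE_NAMES = (
        "standing",
        "go_walk",
        "turn",
        "back_walk",
        "presit_turn",
        "sitting",
    )

    def durations(self) -> tuple:
        d = (
            self.stand_s,
            self.go_walk_s,
            self.turn_s,
            self.back_walk_s,
            self.presit_turn_s,
            self.sit_s,
        )
        if any(x <= 0 for x in d):
            raise ParameterError("all iTUG phase durations must be positive")
        return d

    @property
    def total_s(self) -> float:
        return float(sum(self.durations()))


@dataclass
class ITUGTruth:
    """Realised ground truth returned alongside the generated session."""

    profile: ITUGProfile
    phase_bounds: dict  # name -> (start_s, end_s), absolute session time
    boundaries: np.ndarray  # the seven phase-edge times
    steps_per_bout: int
    total_duration_s: float

    def as_dict(self) -> dict:
        return {
            "profile": asdict(self.profile),
            "phase_bounds": {k: list(v) for k, v in self.phase_bounds.items()},
            "boundaries": self.boundaries.tolist(),
            "steps_per_bout": self.steps_per_bout,
            "total_duration_s": self.total_duration_s,
        }


def _raised_cosine(tau: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """0 → amplitude → 0 bump over [0, duration] (zero outside)."""
    out = np.zeros_like(tau)
    m = (tau >= 0) & (tau <= duration)
    out[m] = 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * tau[m] / duration))
    return out


def _raised_cosine_rate(tau: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """Analytic time-derivative of :func:`_raised_cosine` (per second)."""
    out = np.zeros_like(tau)
    m = (tau >= 0) & (tau <= duration)
    out[m] = (
        amplitude * np.pi / duration * np.sin(2.0 * np.pi * tau[m] / duration)
    )
    return out


def _gaussian_bumps(t: np.ndarray, centers, amplitude: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        out += amplitude * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return out


def _euler_to_quat_wxyz(yaw, pitch, roll) -> np.ndarray:
    ang = np.column_stack([yaw, pitch, roll])
    q = Rotation.from_euler("ZYX", ang, degrees=True).as_quat()  # x,y,z,w
    return q[:, [3, 0, 1, 2]]


def _gravity_in_sensor(quat_wxyz: np.ndarray) -> np.ndarray:
    """Gravity reaction measured by an accelerometer with orientation q."""
    r = Rotation.from_quat(quat_wxyz[:, [1, 2, 3, 0]])
    g_world = np.array([0.0, 0.0, G_MS2])
    return r.inv().apply(np.tile(g_world, (len(quat_wxyz), 1)))


IMPACT_SIGMA_S = 0.025  # width of a synthetic foot-impact bump


def generate_itug(
    profile: ITUGProfile = ITUGProfile(),
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
) -> tuple[SensorSession, ITUGTruth]:
    """Synthesize one iTUG session plus its exact ground truth.

    The trace shows a forward-lean pitch transient while rising, step
    impacts on the vertical axis during both walking bouts, elevated yaw
    rate during the two turns, and a second pitch transient while
    sitting down.  Quiet lead-in/lead-out padding surrounds the test so
    onset detection has a baseline.  Deterministic for a fixed seed.
    """
    durs = profile.durations()
    edges = np.concatenate([[0.0], np.cumsum(durs)]) + profile.lead_in_s
    total = profile.lead_in_s + profile.total_s + profile.lead_out_s
    n = int(round(RATE_HZ * total))
    t = np.arange(n) / RATE_HZ

    names = ITUGProfile.PHASE_NAMES
    bounds = {nm: (float(edges[i]), float(edges[i + 1])) for i, nm in enumerate(names)}

    # pitch: forward lean while standing up and while sitting down
    pitch = _raised_cosine(t - edges[0], durs[0], profile.stand_inclination_deg)
    pitch += _raised_cosine(t - edges[5], durs[5], profile.sit_inclination_deg)
    pitch_rate = _raised_cosine_rate(t - edges[0], durs[0], profile.stand_inclination_deg)
    pitch_rate += _raised_cosine_rate(t - edges[5], durs[5], profile.sit_inclination_deg)

    # yaw rate: the two turns (opposite senses, as when returning)
    yaw_rate = _raised_cosine(t - edges[2], durs[2], profile.turn_peak_dps)
    yaw_rate -= _raised_cosine(t - edges[4], durs[4], profile.presit_turn_peak_dps)
    yaw = np.cumsum(yaw_rate) / RATE_HZ

    roll = np.zeros(n)
    quat = _euler_to_quat_wxyz(yaw, pitch, roll)

    accel = _gravity_in_sensor(quat)
    # vertical transients for the chair transfers
    accel[:, 2] += _raised_cosine(t - edges[0], durs[0], profile.stand_peak_accel)
    accel[:, 2] += _raised_cosine(t - edges[5], durs[5], profile.sit_peak_accel)
    # step impacts, evenly placed within each walking bout
    for b0, b1 in (bounds["go_walk"], bounds["back_walk"]):
        m = profile.steps_per_bout
        centers = b0 + (np.arange(m) + 0.5) * (b1 - b0) / m
        accel[:, 2] += _gaussian_bumps(
            t, centers, profile.step_impact_accel, IMPACT_SIGMA_S
        )

    gyro = np.column_stack([np.zeros(n), pitch_rate, yaw_rate])

    session = SensorSession(
        t, accel, gyro, quat, RATE_HZ, {"test": "itug", "subject": "synthetic"}
    )
    if noise is not None and not noise.is_zero:
        session = add_noise(session, noise, seed)
    truth = ITUGTruth(
        profile=profile,
        phase_bounds=bounds,
        boundaries=edges.copy(),
        steps_per_bout=profile.steps_per_bout,
        total_duration_s=profile.total_s,
    )
    return session, truth


def generate_static(duration_s: float = 5.0) -> SensorSession:
    """Upright, motionless session: accel (0, 0, g), gyro 0, identity quat."""
    n = int(round(RATE_HZ * duration_s))
    t = np.arange(n) / RATE_HZ
    accel = np.tile([0.0, 0.0, G_MS2], (n, 1))
    gyro = np.zeros((n, 3))
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return SensorSession(t, accel, gyro, quat, RATE_HZ, {"test": "static"})


# ---------------------------------------------------------------------------
# 10 m walk


@dataclass(frozen=True)
class GaitProfile:
    """Requested parameters of a synthetic straight 10 m walk.

    ``asymmetry`` is the left/right step-time ratio (1.0 = perfectly
    symmetric).  ``stance_fraction`` is the fraction of a stride each
    foot spends on the ground (0.6 is typical of comfortable gait).
    """

    cadence_spm: float = 110.0
    speed_mps: float = 1.0
    distance_m: float = 10.0
    asymmetry: float = 1.0
    stance_fraction: float = 0.6
    ic_impact_accel: float = 2.5  # m/s² vertical, initial contact
    fc_impact_accel: float = 1.5  # m/s² antero-posterior, final contact
    lead_in_s: float = 2.0
    lead_out_s: float = 2.0

    def validate(self):
        if self.cadence_spm <= 0 or self.speed_mps <= 0 or self.distance_m <= 0:
            raise ParameterError("cadence, speed and distance must be positive")
        if not 0.5 < self.stance_fraction < 0.85:
            raise ParameterError("stance_fraction outside the plausible (0.5, 0.85)")
        if self.asymmetry <= 0:
            raise ParameterError("asymmetry (L/R step-time ratio) must be positive")


@dataclass
class GaitTruth:
    """Realised ground truth of a generated walk."""

    profile: GaitProfile
    ic_times: np.ndarray  # all initial contacts, chronological
    fc_times: np.ndarray  # matching final contacts (same order/foot)
    feet: list  # 'L'/'R' per contact; identity is conventional
    n_steps: int
    cadence_spm: float  # realised
    speed_mps: float
    duration_s: float  # realised walk duration
    step_time_left_s: float
    step_time_right_s: float
    stride_time_s: float
    stance_fraction: float
    distance_m: float

    def as_dict(self) -> dict:
        d = {
            "profile": asdict(self.profile),
            "ic_times": self.ic_times.tolist(),
            "fc_times": self.fc_times.tolist(),
            "feet": self.feet,
        }
        for k in (
            "n_steps",
            "cadence_spm",
            "speed_mps",
            "duration_s",
            "step_time_left_s",
            "step_time_right_s",
            "stride_time_s",
            "stance_fraction",
            "distance_m",
        ):
            d[k] = getattr(self, k)
        return d


def generate_t10m(
    profile: GaitProfile = GaitProfile(),
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
) -> tuple[SensorSession, GaitTruth]:
    """Synthesize one 10 m walk plus its exact event-level ground truth.

    Step count is ``round(duration × cadence / 60)`` with the walk
    duration fixed at ``distance / speed``; the realised cadence (which
    the truth reports) therefore matches the request except for the
    rounding to a whole number of steps.  Initial contacts are vertical
    impact bumps, final contacts antero-posterior bumps at
    ``stance_fraction`` of a stride after the same foot's contact.
    """
    profile.validate()
    duration = profile.distance_m / profile.speed_mps
    n_steps = int(round(duration * profile.cadence_spm / 60.0))
    if n_steps < 2:
        raise ParameterError("profile yields fewer than 2 steps")
    base = duration / n_steps  # realised mean step time
    r = profile.asymmetry
    step_left = 2.0 * base * r / (1.0 + r)
    step_right = 2.0 * base / (1.0 + r)

    # chronological contacts, feet alternating L, R, L, ...
    feet = ["L" if k % 2 == 0 else "R" for k in range(n_steps)]
    intervals = [step_left if f == "L" else step_right for f in feet[1:]]
    ic = profile.lead_in_s + 0.5 * base + np.concatenate([[0.0], np.cumsum(intervals)])
    stride = 2.0 * base
    fc = ic + profile.stance_fraction * stride

    total = profile.lead_in_s + duration + profile.lead_out_s
    n = int(round(RATE_HZ * total))
    t = np.arange(n) / RATE_HZ

    accel = np.tile([0.0, 0.0, G_MS2], (n, 1))
    accel[:, 2] += _gaussian_bumps(t, ic, profile.ic_impact_accel, IMPACT_SIGMA_S)
    accel[:, 0] += _gaussian_bumps(t, fc, profile.fc_impact_accel, IMPACT_SIGMA_S)
    gyro = np.zeros((n, 3))
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))

    session = SensorSession(
        t, accel, gyro, quat, RATE_HZ, {"test": "t10m", "subject": "synthetic"}
    )
    if noise is not None and not noise.is_zero:
        session = add_noise(session, noise, seed)
    truth = GaitTruth(
        profile=profile,
        ic_times=ic,
        fc_times=fc,
        feet=feet,
        n_steps=n_steps,
        cadence_spm=60.0 / base,
        speed_mps=profile.distance_m / duration,
        duration_s=duration,
        step_time_left_s=step_left,
        step_time_right_s=step_right,
        stride_time_s=stride,
        stance_fraction=profile.stance_fraction,
        distance_m=profile.distance_m,
    )
    return session, truth


# ---------------------------------------------------------------------------
# noise injection


def add_noise(session: SensorSession, noise: NoiseModel, seed: int = 0) -> SensorSession:
    """Overlay the additive noise model; deterministic per seed.

    White Gaussian noise at the per-axis RMS plus constant offsets on
    the accelerometer (converted G → m/s²), white Gaussian noise on the
    gyroscope, and a linear Euler drift composed into the quaternions
    (renormalised).  A zero model returns the input unchanged.
    """
    if noise.is_zero:
        return session.copy()
    rng = np.random.default_rng(seed)
    out = session.copy()
    n = len(out)
    for ax in range(3):
        rms = noise.accel_rms_g[ax] * G_MS2
        if rms > 0:
            out.accel[:, ax] += rng.normal(0.0, rms, n)
        off = noise.accel_offset_g[ax] * G_MS2
        if off != 0.0:
            out.accel[:, ax] += off
    for ax in range(3):
        if noise.gyro_rms_dps[ax] > 0:
            out.gyro[:, ax] += rng.normal(0.0, noise.gyro_rms_dps[ax], n)
    if any(d != 0.0 for d in noise.euler_drift_dps):
        drift = np.outer(out.t, noise.euler_drift_dps)  # yaw, pitch, roll (deg)
        r = Rotation.from_quat(out.quat[:, [1, 2, 3, 0]])
        r_drift = Rotation.from_euler("ZYX", drift, degrees=True)
        q = (r_drift * r).as_quat()
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        out.quat = q[:, [3, 0, 1, 2]]
    return out
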