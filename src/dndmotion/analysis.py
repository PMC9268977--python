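"""Instrumented-test analytics: iTUG segmentation and 10 m gait events.

These are transparent baseline detectors built from classical signal
plumbing — zero-phase band-pass filtering, envelope extraction, and
adaptive-threshold peak picking — whose accuracy contract is recovery
of the synthetic generator's ground truth, not replication of any
clinically validated pipeline.

iTUG segmentation strategy: the trunk-pitch channel (from the
quaternions) is active only while rising from and lowering onto the
chair, and the yaw-rate channel only during the two turns.  The six
phases are cut at the onsets/offsets of those two activity channels;
walking bouts are the quiet stretches in between.  Onset thresholds are
adaptive (a fraction of the interval peak, floored at a few times the
estimated noise level), and each detected edge is refined outward until
the signal falls to baseline, which keeps boundary bias small both on
clean and on realistically noisy traces.

Gait events: initial contacts are impact bumps on the vertical
acceleration, final contacts on the antero-posterior axis.  Feet are
labelled alternately from the first contact — a single lumbar sensor
cannot resolve absolute left/right identity, so the labels are
conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, SegmentationError
from .synth import SensorSession

__all__ = [
    "AnalysisConfig",
    "PhaseSegmentation",
    "ITUGResult",
    "GaitEvents",
    "T10MResult",
    "segment_itug",
    "itug_indexes",
    "detect_gait_events",
    "t10m_parameters",
    "analyze_itug",
    "analyze_t10m",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Detector tunables (units in names).

    The fall-risk cut-offs on total test duration are artifact defaults
    — configurable, and deliberately conservative round numbers.
    """

    smooth_s: float = 0.05  # gyro smoothing window
    yaw_floor_dps: float = 0.1  # minimum edge threshold, clean signals
    pitch_floor_deg: float = 0.05
    onset_frac: float = 0.25  # onset = this fraction of interval peak
    edge_frac: float = 0.002  # refine edge down to this fraction of peak
    noise_k: float = 4.0  # edge threshold >= noise_k * estimated noise SD
    band_hz: tuple = (3.0, 16.0)  # step-impact band
    impact_env_s: float = 0.05
    peak_height_frac: float = 0.35
    min_step_gap_s: float = 0.25
    risk_normal_max_s: float = 10.0
    risk_elevated_max_s: float = 13.5
    min_steps: int = 4


DEFAULT_CONFIG = AnalysisConfig()


# ---------------------------------------------------------------------------
# shared signal plumbing


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x.copy()
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise-level estimate: scaled MAD about the median.

    Activity is sparse in these traces, so the median absolute
    deviation reflects the quiet baseline rather than the transients.
    """
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _active_intervals(
    x: np.ndarray, rate: float, onset: float, edge: float, merge_gap_s: float = 0.3
):
    """Contiguous |x| > onset runs, merged, then edge-refined outward."""
    mask = np.abs(x) > onset
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > int(merge_gap_s * rate)) + 1
    runs = [(g[0], g[-1]) for g in np.split(idx, splits)]
    out = []
    n = len(x)
    for a, b in runs:
        while a > 0 and abs(x[a - 1]) > edge:
            a -= 1
        while b < n - 1 and abs(x[b + 1]) > edge:
            b += 1
        out.append((a, b))
    return out


def _impact_envelope(a: np.ndarray, rate: float, cfg: AnalysisConfig) -> np.ndarray:
    """Band-passed rectified-and-smoothed impact envelope of one axis."""
    nyq = rate / 2.0
    lo, hi = cfg.band_hz
    b, a_ = sps.butter(2, [lo / nyq, hi / nyq], btype="band")
    bp = sps.filtfilt(b, a_, a)
    return _moving_average(np.abs(bp), max(1, int(cfg.impact_env_s * rate)))


def _impact_peaks(
    env: np.ndarray, rate: float, cfg: AnalysisConfig, lo: int = 0, hi: Optional[int] = None
) -> np.ndarray:
    """Peak indices of an impact envelope within [lo, hi)."""
    hi = len(env) if hi is None else hi
    window = env[lo:hi]
    if window.size == 0:
        return np.array([], dtype=int)
    height = cfg.peak_height_frac * float(window.max())
    if height <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(
        window, height=height, distance=max(1, int(cfg.min_step_gap_s * rate))
    )
    return peaks + lo


# ---------------------------------------------------------------------------
# iTUG


@dataclass
class PhaseSegmentation:
    """Six ordered, contiguous labelled intervals (seconds)."""

    phases: dict  # name -> (start_s, end_s)

    PHASE_NAMES = (
        "standing",
        "go_walk",
        "turn",
        "back_walk",
        "presit_turn",
        "sitting",
    )

    def __post_init__(self):
        prev_end = None
        for name in self.PHASE_NAMES:
            s, e = self.phases[name]
            if e <= s:
                raise SegmentationError(f"phase {name} has non-positive length")
            if prev_end is not None and abs(s - prev_end) > 1e-9:
                raise SegmentationError("phases must be contiguous and ordered")
            prev_end = e

    @property
    def boundaries(self) -> np.ndarray:
        """The seven edge times, first phase start to last phase end."""
        starts = [self.phases[n][0] for n in self.PHASE_NAMES]
        return np.array(starts + [self.phases["sitting"][1]])

    def duration(self, name: str) -> float:
        s, e = self.phases[name]
        return e - s

    @property
    def total_duration_s(self) -> float:
        return float(self.boundaries[-1] - self.boundaries[0])


@dataclass
class ITUGResult:
    """The fall-risk index set of one instrumented Timed Up & Go."""

    risk_category: str  # Normal | Risk | High Risk
    test_duration_s: float
    phase_durations_s: dict
    standing_max_accel_ms2: float
    sitting_max_accel_ms2: float
    standing_max_inclination_deg: float
    sitting_max_inclination_deg: float
    steps_during_walking: int
    turn_angular_velocity_dps: float
    presit_turn_angular_velocity_dps: float

    def as_dict(self) -> dict:
        return asdict(self)


def segment_itug(
    session: SensorSession, config: AnalysisConfig = DEFAULT_CONFIG
) -> PhaseSegmentation:
    """Cut one iTUG recording into its six phases.

    Raises :class:`SegmentationError` when the expected structure (two
    pitch transients bracketing two turns) cannot be found.
    """
    rate = session.rate_hz
    pitch = session.pitch_deg()
    pitch_rel = pitch - float(np.median(pitch[: max(2, int(0.2 * rate))]))
    yaw_rate = _moving_average(
        session.gyro[:, 2], max(1, int(config.smooth_s * rate))
    )

    sd_yaw = _noise_sd(yaw_rate)
    sd_pitch = _noise_sd(pitch_rel)

    peak_yaw = float(np.max(np.abs(yaw_rate)))
    onset_yaw = max(config.onset_frac * peak_yaw, 6.0 * sd_yaw, 2.0 * config.yaw_floor_dps)
    edge_yaw = max(config.edge_frac * peak_yaw, config.noise_k * sd_yaw, config.yaw_floor_dps)
    turns = _active_intervals(yaw_rate, rate, onset_yaw, edge_yaw)
    turns = sorted(sorted(turns, key=lambda ab: ab[0] - ab[1])[:2])  # two longest

    peak_pitch = float(np.max(np.abs(pitch_rel)))
    onset_pitch = max(
        config.onset_frac * peak_pitch, 6.0 * sd_pitch, 2.0 * config.pitch_floor_deg
    )
    edge_pitch = max(
        config.edge_frac * peak_pitch, config.noise_k * sd_pitch, config.pitch_floor_deg
    )
    postures = _active_intervals(pitch_rel, rate, onset_pitch, edge_pitch)

    if len(turns) < 2 or len(postures) < 2 or peak_yaw < 5.0 or peak_pitch < 1.0:
        raise SegmentationError(
            "no recognisable iTUG structure (need two posture transients "
            "and two turns); got "
            f"{len(postures)} posture interval(s), {len(turns)} turn(s)"
        )

    s0, s1 = postures[0]
    w0, w1 = postures[-1]
    (u0, u1), (v0, v1) = turns

    edges_idx = [s0, s1, u0, u1, v0, v1, w1]
    edges = np.array(edges_idx, dtype=float) / rate
    if not np.all(np.diff(edges) > 0):
        raise SegmentationError("detected phase edges are out of order")

    names = PhaseSegmentation.PHASE_NAMES
    phases = {
        names[i]: (float(edges[i]), float(edges[i + 1])) for i in range(6)
    }
    return PhaseSegmentation(phases)


def itug_indexes(
    session: SensorSession,
    seg: PhaseSegmentation,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ITUGResult:
    """Compute the iTUG index set from a session and its segmentation.

    Maximum inclination is measured as pitch deviation from the
    session's initial posture; accelerations as deviation of the
    acceleration magnitude from its session baseline (robust to
    constant sensor offsets); the fall-risk category from total test
    duration via the configured cut-offs.
    """
    rate = session.rate_hz

    def idx(tsec: float) -> int:
        return int(round(tsec * rate))

    amag = np.linalg.norm(session.accel, axis=1)
    baseline = float(np.median(amag))
    pitch = session.pitch_deg()
    pitch_rel = pitch - float(np.median(pitch[: max(2, int(0.2 * rate))]))

    def win(name):
        s, e = seg.phases[name]
        return slice(idx(s), max(idx(s) + 1, idx(e)))

    env = _impact_envelope(session.accel[:, 2], rate, config)
    steps = 0
    for bout in ("go_walk", "back_walk"):
        w = win(bout)
        steps += len(_impact_peaks(env, rate, config, w.start, w.stop))

    total = seg.total_duration_s
    if total <= config.risk_normal_max_s:
        category = "Normal"
    elif total <= config.risk_elevated_max_s:
        category = "Risk"
    else:
        category = "High Risk"

    return ITUGResult(
        risk_category=category,
        test_duration_s=total,
        phase_durations_s={n: seg.duration(n) for n in seg.PHASE_NAMES},
        standing_max_accel_ms2=float(np.max(np.abs(amag[win("standing")] - baseline))),
        sitting_max_accel_ms2=float(np.max(np.abs(amag[win("sitting")] - baseline))),
        standing_max_inclination_deg=float(np.max(np.abs(pitch_rel[win("standing")]))),
        sitting_max_inclination_deg=float(np.max(np.abs(pitch_rel[win("sitting")]))),
        steps_during_walking=int(steps),
        turn_angular_velocity_dps=float(np.max(np.abs(session.gyro[win("turn"), 2]))),
        presit_turn_angular_velocity_dps=float(
            np.max(np.abs(session.gyro[win("presit_turn"), 2]))
        ),
    )


def analyze_itug(
    session: SensorSession, config: AnalysisConfig = DEFAULT_CONFIG
) -> ITUGResult:
    """Segment and index one iTUG session in a single call."""
    return itug_indexes(session, segment_itug(session, config), config)


# ---------------------------------------------------------------------------
# 10 m walk


@dataclass
class GaitEvents:
    """Per-foot ordered initial-contact and final-contact times (s).

    Foot identity is conventional (alternating from the first contact).
    """

    ic: dict = field(default_factory=lambda: {"L": [], "R": []})
    fc: dict = field(default_factory=lambda: {"L": [], "R": []})

    def all_ic(self) -> np.ndarray:
        return np.sort(np.concatenate([self.ic["L"], self.ic["R"]]))

    @property
    def n_steps(self) -> int:
        return len(self.ic["L"]) + len(self.ic["R"])


@dataclass
class T10MResult:
    """Spatio-temporal gait parameters of one 10 m walk."""

    functional_mobility: str
    walking_speed_mps: float
    cadence_spm: float
    step_time_s: float
    stride_time_s: float
    double_support_time_s: float
    single_support_time_s: float
    swing_pct: float
    stance_pct: float
    step_length_m: float
    stride_length_m: float
    gait_symmetry: float  # |L-R| / mean step time; 0 = perfect

    def as_dict(self) -> dict:
        return asdict(self)


def detect_gait_events(
    session: SensorSession, config: AnalysisConfig = DEFAULT_CONFIG
) -> GaitEvents:
    """Detect initial and final contacts of a steady straight walk.

    Initial contacts from vertical-axis impact peaks, final contacts
    from antero-posterior peaks; each final contact is attributed to the
    foot whose initial contact best matches one stance period earlier.
    """
    rate = session.rate_hz
    env_ic = _impact_envelope(session.accel[:, 2], rate, config)
    ic_idx = _impact_peaks(env_ic, rate, config)
    if len(ic_idx) < config.min_steps:
        raise InsufficientDataError(
            f"only {len(ic_idx)} initial contacts detected; need at least "
            f"{config.min_steps} steps for gait analysis"
        )
    ic_t = ic_idx / rate

    env_fc = _impact_envelope(session.accel[:, 0], rate, config)
    fc_idx = _impact_peaks(env_fc, rate, config)
    fc_t = fc_idx / rate

    mean_step = float(np.median(np.diff(ic_t)))
    feet = ["L" if k % 2 == 0 else "R" for k in range(len(ic_t))]
    events = GaitEvents()
    for tval, foot in zip(ic_t, feet):
        events.ic[foot].append(float(tval))

    # attribute each FC to the latest IC at least ~3/4 step earlier
    for fv in fc_t:
        cand = np.flatnonzero(ic_t <= fv - 0.75 * mean_step)
        if cand.size == 0:
            continue
        k = int(cand[-1])
        events.fc[feet[k]].append(float(fv))

    for foot in ("L", "R"):
        events.ic[foot] = list(np.sort(events.ic[foot]))
        events.fc[foot] = list(np.sort(events.fc[foot]))
    return events


def _functional_mobility_label(speed: float) -> str:
    # community-ambulation banding on walking speed; artifact default
    if speed < 0.4:
        return "household ambulation"
    if speed < 0.8:
        return "limited community ambulation"
    return "community ambulation"


def t10m_parameters(
    session: SensorSession,
    events: GaitEvents,
    distance_m: float = 10.0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> T10MResult:
    """Spatio-temporal parameters from detected events over a known distance.

    Walk duration is taken as steps × mean step time; stance/swing come
    from paired IC→FC intervals per foot; double support is the per-
    stride overlap 2·stance − stride and single support its complement
    stride − stance.  Symmetry is |L − R| / mean of the per-foot mean
    step times (0 = perfect symmetry).
    """
    all_ic = events.all_ic()
    n_steps = len(all_ic)
    if n_steps < config.min_steps:
        raise InsufficientDataError(
            f"{n_steps} steps insufficient for parameter extraction"
        )
    step_intervals = np.diff(all_ic)
    mean_step = float(np.mean(step_intervals))

    # per-foot mean step time: intervals ending on that foot's contact
    foot_step = {}
    for foot in ("L", "R"):
        ends = np.asarray(events.ic[foot])
        vals = [
            all_ic[k] - all_ic[k - 1]
            for k in range(1, n_steps)
            if np.any(np.isclose(ends, all_ic[k]))
        ]
        foot_step[foot] = float(np.mean(vals)) if vals else mean_step

    strides, stances = [], []
    for foot in ("L", "R"):
        ics = np.asarray(events.ic[foot])
        fcs = np.asarray(events.fc[foot])
        if len(ics) >= 2:
            strides.extend(np.diff(ics))
        for icv in ics:
            later = fcs[fcs > icv]
            if later.size:
                nxt = float(later[0])
                if nxt - icv < 2.5 * mean_step:
                    stances.append(nxt - icv)
    stride = float(np.mean(strides)) if strides else 2.0 * mean_step
    stance = float(np.mean(stances)) if stances else 0.6 * stride

    stance_pct = 100.0 * stance / stride
    swing_pct = 100.0 - stance_pct
    duration = n_steps * mean_step
    speed = distance_m / duration
    lr = (foot_step["L"], foot_step["R"])
    symmetry = abs(lr[0] - lr[1]) / (0.5 * (lr[0] + lr[1]))

    return T10MResult(
        functional_mobility=_functional_mobility_label(speed),
        walking_speed_mps=speed,
        cadence_spm=60.0 / mean_step,
        step_time_s=mean_step,
        stride_time_s=stride,
        double_support_time_s=max(0.0, 2.0 * stance - stride),
        single_support_time_s=stride - stance,
        swing_pct=swing_pct,
        stance_pct=stance_pct,
        step_length_m=distance_m / n_steps,
        stride_length_m=2.0 * distance_m / n_steps,
        gait_symmetry=symmetry,
    )


def analyze_t10m(
    session: SensorSession,
    distance_m: float = 10.0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> T10MResult:
    """Detect events and extract gait parameters in a single call."""
    return t10m_parameters(session, detect_gait_events(session, config), distance_m, config)
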