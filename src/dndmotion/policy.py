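"""The storage/transmission policy engine ("distributed and disposable").

A user policy is a pair (storage level, transmission level).  Three
storage levels — keep nothing, keep the analytic result, keep raw data —
cross four transmission levels — send nothing, send periodic handshakes,
send the analytic result, send raw data — to give ten named scenarios
(A)–(J) plus two impractical corners (keeping raw data while sending
nothing or only handshakes).  Scenarios A–F never need the raw series
after analysis: samples are fed one-by-one through disposable running
accumulators and immediately discarded ("forgetting while analysing").
Scenarios G–J require the raw stream, so data are accumulated and an
offline batch pass produces the identical report schema.

Each level carries a fixed disclosure percentage (nothing 0%,
handshake 10%, analytic result 30%, raw data 100%), which plugs the
scenario straight into the privacy quantification of
:mod:`dndmotion.privacy`.

"Transmission" here is delivery of a payload object to the caller (or a
sink directory downstream); the privacy contract concerns what crosses
the local boundary, not the transport stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np

from . import running
from .errors import ConfigError, ParameterError
from .privacy import dnd_privacy
from .synth import G_MS2, SensorSession

__all__ = [
    "StorageLevel",
    "TransmissionLevel",
    "ScenarioSpec",
    "PolicyOutcome",
    "SCENARIO_LETTERS",
    "classify_scenario",
    "scenario_for_letter",
    "scenario_privacy",
    "process_session",
    "offline_analytics",
    "CHANNELS",
    "DEFAULT_ALERT_BOUNDS",
]


class StorageLevel(Enum):
    """What is retained locally; value = disclosure percent."""

    NOTHING = 0
    ANALYTIC_RESULT = 30
    RAW_DATA = 100

    @property
    def disclosure_pct(self) -> float:
        return float(self.value)


class TransmissionLevel(Enum):
    """What leaves the local boundary; value = disclosure percent.

    Handshakes carry no movement data, but minimal identifying
    information (liveness, patient pseudo-ID, predefined alert codes);
    their disclosure is pessimistically rated at 10%.
    """

    NOTHING = 0
    HANDSHAKE = 10
    ANALYTIC_RESULT = 30
    RAW_DATA = 100

    @property
    def disclosure_pct(self) -> float:
        return float(self.value)


_LETTER_GRID = {
    ("NOTHING", "NOTHING"): "A",
    ("NOTHING", "HANDSHAKE"): "B",
    ("NOTHING", "ANALYTIC_RESULT"): "C",
    ("ANALYTIC_RESULT", "NOTHING"): "D",
    ("ANALYTIC_RESULT", "HANDSHAKE"): "E",
    ("ANALYTIC_RESULT", "ANALYTIC_RESULT"): "F",
    ("RAW_DATA", "ANALYTIC_RESULT"): "G",
    ("ANALYTIC_RESULT", "RAW_DATA"): "H",
    ("RAW_DATA", "RAW_DATA"): "I",
    ("NOTHING", "RAW_DATA"): "J",
    ("RAW_DATA", "NOTHING"): "IMPRACTICAL",
    ("RAW_DATA", "HANDSHAKE"): "IMPRACTICAL",
}

SCENARIO_LETTERS = tuple("ABCDEFGHIJ")

#: letters whose analysis can run disposably (raw never retained)
_DND_LETTERS = frozenset("ABCDEF")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the storage × transmission scenario grid."""

    letter: str  # A–J or "IMPRACTICAL"
    storage: StorageLevel
    transmission: TransmissionLevel
    dnd_applicable: bool


def classify_scenario(
    storage: StorageLevel, transmission: TransmissionLevel
) -> ScenarioSpec:
    """Name the scenario for a (storage, transmission) pair.

    Keeping raw data while sending nothing (or only handshakes) is
    labelled IMPRACTICAL: it makes little sense to hoard data without
    using them, so those corners exist for theoretical discussion only.
    """
    letter = _LETTER_GRID[(storage.name, transmission.name)]
    return ScenarioSpec(
        letter=letter,
        storage=storage,
        transmission=transmission,
        dnd_applicable=letter in _DND_LETTERS,
    )


def scenario_for_letter(letter: str) -> ScenarioSpec:
    """Inverse mapping: scenario letter → full spec."""
    letter = letter.upper()
    for (s_name, t_name), lt in _LETTER_GRID.items():
        if lt == letter:
            return classify_scenario(StorageLevel[s_name], TransmissionLevel[t_name])
    raise ConfigError(f"unknown scenario letter {letter!r}; expected A–J")


def scenario_privacy(spec: ScenarioSpec) -> float:
    """Combined privacy score of a scenario (0 for the impractical corners)."""
    if spec.letter == "IMPRACTICAL":
        return 0.0
    return dnd_privacy(spec.storage.disclosure_pct, spec.transmission.disclosure_pct)


# ---------------------------------------------------------------------------
# session processing


#: channels summarised by the analytic report (accel m/s², gyro °/s,
#: plus the acceleration magnitude)
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "amag")

#: default alert rules for handshake scenarios: channel-summary field → bound.
#: A fall-like impact shows as acceleration magnitude far above 1 g.
DEFAULT_ALERT_BOUNDS = {("amag", "max"): 3.0 * G_MS2}


@dataclass
class PolicyOutcome:
    """What one processed session produced, stored, and transmitted."""

    scenario: ScenarioSpec
    report: dict  # channel -> RunningSummary (always computed)
    stored_payload: object = None  # None | report dict | SensorSession
    transmitted_payload: object = None  # None | handshake codes | report | SensorSession
    audit_log: list = field(default_factory=list)
    error: Optional[str] = None

    def report_dict(self) -> dict:
        return {
            ch: (s.as_dict() if hasattr(s, "as_dict") else s)
            for ch, s in self.report.items()
        }


def _channel_values(sample) -> dict:
    ax, ay, az = (float(v) for v in sample.accel)
    gx, gy, gz = (float(v) for v in sample.gyro)
    return {
        "ax": ax,
        "ay": ay,
        "az": az,
        "gx": gx,
        "gy": gy,
        "gz": gz,
        "amag": float(np.sqrt(ax * ax + ay * ay + az * az)),
    }


def _streaming_analytics(session: SensorSession) -> dict:
    """One pass, one sample at a time, nothing retained but accumulators."""
    acc = {ch: running.RunningState() for ch in CHANNELS}
    for sample in session.samples():
        for ch, v in _channel_values(sample).items():
            acc[ch].push(v)
    return {ch: st.summary() for ch, st in acc.items()}


def offline_analytics(session: SensorSession) -> dict:
    """Batch analytics over accumulated raw data; same report schema.

    Produces, via the non-recursive batch oracle, the identical summary
    set the streaming path computes — the dual-path consistency the
    policy engine's tests rely on.
    """
    if len(session) == 0:
        raise ParameterError("offline analytics requires a non-empty session")
    amag = np.linalg.norm(session.accel, axis=1)
    cols = {
        "ax": session.accel[:, 0],
        "ay": session.accel[:, 1],
        "az": session.accel[:, 2],
        "gx": session.gyro[:, 0],
        "gy": session.gyro[:, 1],
        "gz": session.gyro[:, 2],
        "amag": amag,
    }
    return {ch: running.batch_oracle(v) for ch, v in cols.items()}


def _alerts(report: dict, bounds: dict) -> list:
    fired = []
    for (ch, stat), bound in bounds.items():
        summ = report.get(ch)
        if summ is None:
            continue
        value = {"max": summ.max_v, "min": summ.min_v, "mean": summ.mean}.get(stat)
        if value is not None and value > bound:
            fired.append(f"ALERT:{ch.upper()}_{stat.upper()}")
    return fired


def _handshake_payload(
    session: SensorSession, report: dict, bounds: dict, period_s: float
) -> list:
    """Heartbeat codes plus any predefined alert shortcut codes.

    Carries liveness and the patient pseudo-ID only — never raw samples
    or summary values.
    """
    subject = session.meta.get("subject", "unknown")
    beats = max(1, int(session.duration_s // period_s))
    payload = [{"code": "HB", "seq": i, "subject": subject} for i in range(beats)]
    payload += [{"code": code, "subject": subject} for code in _alerts(report, bounds)]
    return payload


def process_session(
    session: SensorSession,
    spec: ScenarioSpec,
    analyzers: Optional[Callable[[SensorSession], dict]] = None,
    alert_bounds: Optional[dict] = None,
    handshake_period_s: float = 10.0,
) -> PolicyOutcome:
    """Run one session through analysis and the scenario's data-flow rules.

    For DnD-applicable scenarios (A–F) the raw stream is consumed one
    sample at a time by running accumulators and never buffered; for
    G–J the raw data are accumulated and the offline batch path runs.
    The outcome's stored/transmitted payloads honour the scenario
    contract, and every store/send/erase action lands in the audit log
    (metadata only).  ``analyzers`` may supply an extra report callable
    (e.g. a movement analysis) used when raw data are available; its
    failure is recorded, never fatal to the policy contract.
    """
    if len(session) == 0:
        raise ParameterError("cannot process an empty session")
    if spec.letter == "IMPRACTICAL":
        raise ConfigError(
            "impractical scenario (raw storage without meaningful "
            "transmission) is for theoretical discussion only"
        )
    bounds = DEFAULT_ALERT_BOUNDS if alert_bounds is None else alert_bounds
    audit: list = []
    error = None
    raw: Optional[SensorSession] = None

    if spec.dnd_applicable:
        report = _streaming_analytics(session)
        audit.append(
            {"action": "analyse_streaming", "n_samples": len(session), "raw_buffered": False}
        )
    else:
        raw = session.copy()
        audit.append(
            {"action": "accumulate_raw", "n_samples": len(session), "raw_buffered": True}
        )
        report = offline_analytics(raw)
        audit.append({"action": "analyse_offline", "n_samples": len(raw)})

    extra = None
    if analyzers is not None and not spec.dnd_applicable:
        try:
            extra = analyzers(raw)
        except Exception as exc:  # contract survives analyzer failure
            error = f"analyzer failed: {exc}"
            audit.append({"action": "analyzer_error", "detail": str(exc)})
    full_report = dict(report)
    if extra is not None:
        full_report["movement"] = extra

    stored = None
    if spec.storage is StorageLevel.ANALYTIC_RESULT:
        stored = full_report
        audit.append({"action": "store_report", "channels": sorted(report)})
    elif spec.storage is StorageLevel.RAW_DATA:
        stored = raw
        audit.append({"action": "store_raw", "n_samples": len(raw)})

    transmitted = None
    if spec.transmission is TransmissionLevel.HANDSHAKE:
        transmitted = _handshake_payload(session, report, bounds, handshake_period_s)
        audit.append({"action": "transmit_handshake", "n_codes": len(transmitted)})
    elif spec.transmission is TransmissionLevel.ANALYTIC_RESULT:
        transmitted = full_report
        audit.append({"action": "transmit_report", "channels": sorted(report)})
    elif spec.transmission is TransmissionLevel.RAW_DATA:
        transmitted = session.copy() if raw is None else raw
        audit.append({"action": "transmit_raw", "n_samples": len(transmitted)})

    keep_raw = stored is raw and raw is not None
    if raw is not None and not keep_raw:
        raw = None
        audit.append({"action": "erase_raw"})
    elif spec.dnd_applicable:
        # nothing was ever buffered; record the disposal guarantee
        audit.append({"action": "erase_raw", "note": "streamed, never buffered"})

    return PolicyOutcome(
        scenario=spec,
        report=full_report,
        stored_payload=stored,
        transmitted_payload=transmitted,
        audit_log=audit,
        error=error,
    )
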