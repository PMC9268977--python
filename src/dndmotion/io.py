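"""Session serialisation, run configuration, and the full pipeline.

Session CSV layout: a comment header carrying the format version,
units, sample rate and session metadata, then columns
``t, ax, ay, az, gx, gy, gz, qw, qx, qy, qz`` (t in s, accel in m/s²,
gyro in °/s, quaternion w-first).  Numeric fields round-trip at full
double precision.  Ground truth travels as a sidecar JSON next to the
CSV, never inside it.

``run_pipeline`` ties everything together: simulate or load a session,
analyse it, and hand it to the policy engine; stored payloads land in a
local store directory, transmitted payloads in the sink directory, and
a metadata-only audit trail is always written as line-delimited JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import analysis, policy, synth
from .errors import ConfigError, ParseError
from .synth import SensorSession

__all__ = [
    "SESSION_COLUMNS",
    "read_session",
    "write_session",
    "write_truth",
    "RunConfig",
    "run_pipeline",
]

SESSION_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "qw", "qx", "qy", "qz"]

_HEADER_PREFIX = "# dndmotion-session v1 "


def write_session(session: SensorSession, path) -> None:
    """Write a session CSV (units: t s, accel m/s², gyro °/s, quat unit)."""
    path = Path(path)
    frame = pd.DataFrame(
        np.column_stack([session.t, session.accel, session.gyro, session.quat]),
        columns=SESSION_COLUMNS,
    )
    header = _HEADER_PREFIX + json.dumps(
        {"rate_hz": session.rate_hz, "meta": session.meta,
         "units": {"t": "s", "accel": "m/s^2", "gyro": "deg/s", "quat": "unit"}}
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_session(path) -> SensorSession:
    """Read a session CSV; raises :class:`ParseError` on malformed input."""
    path = Path(path)
    rate_hz, meta = synth.RATE_HZ, {}
    try:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith(_HEADER_PREFIX):
            info = json.loads(first[len(_HEADER_PREFIX):])
            rate_hz = float(info.get("rate_hz", rate_hz))
            meta = dict(info.get("meta", {}))
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse session file {path}: {exc}") from exc
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(
            f"session file {path} is missing column(s): {', '.join(missing)}"
        )
    if frame[SESSION_COLUMNS].isna().any().any():
        bad = int(frame[SESSION_COLUMNS].isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"session file {path}: malformed value near line {bad}")
    vals = frame[SESSION_COLUMNS].to_numpy(dtype=float)
    return SensorSession(
        t=vals[:, 0],
        accel=vals[:, 1:4],
        gyro=vals[:, 4:7],
        quat=vals[:, 7:11],
        rate_hz=rate_hz,
        meta=meta,
    )


def write_truth(truth, path) -> None:
    """Write generator ground truth as sidecar JSON."""
    with open(path, "w") as fh:
        json.dump(truth.as_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """One pipeline run: where data come from and how they may flow.

    Exactly one scenario must resolve: either a letter A–J or an
    explicit (storage, transmission) pair.  Paths are optional — with
    no store/sink directories the payloads stay in-process only.
    """

    scenario: Optional[str] = "A"
    storage: Optional[str] = None
    transmission: Optional[str] = None
    test: str = "itug"  # itug | t10m | none (skip movement analysis)
    input_path: Optional[str] = None  # load instead of simulate
    seed: int = 0
    noise: str = "table1"  # table1 | none
    store_dir: Optional[str] = None
    sink_dir: Optional[str] = None
    audit_path: Optional[str] = None
    alert_bounds: Optional[dict] = None
    contexts: dict = field(default_factory=dict)  # name -> {"s":..., "p":...}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def resolve_scenario(self) -> policy.ScenarioSpec:
        if self.storage is not None and self.transmission is not None:
            try:
                return policy.classify_scenario(
                    policy.StorageLevel[self.storage.upper()],
                    policy.TransmissionLevel[self.transmission.upper()],
                )
            except KeyError as exc:
                raise ConfigError(f"unknown storage/transmission level: {exc}") from exc
        if self.scenario is None:
            raise ConfigError("config must set a scenario letter or a level pair")
        return policy.scenario_for_letter(self.scenario)

    def noise_model(self) -> synth.NoiseModel:
        if self.noise == "none":
            return synth.NoiseModel.none()
        if self.noise == "table1":
            return synth.NoiseModel.table_defaults()
        raise ConfigError(f"unknown noise setting {self.noise!r} (table1|none)")


def _movement_analyzer(test: str):
    if test == "itug":
        return lambda s: analysis.analyze_itug(s).as_dict()
    if test == "t10m":
        return lambda s: analysis.analyze_t10m(s).as_dict()
    if test == "none":
        return None
    raise ConfigError(f"unknown test type {test!r} (itug|t10m|none)")


def _summaries_jsonable(payload) -> dict:
    out = {}
    for ch, summ in payload.items():
        out[ch] = summ.as_dict() if hasattr(summ, "as_dict") else summ
    return out


def run_pipeline(config: RunConfig) -> policy.PolicyOutcome:
    """Simulate-or-load, analyse, and dispatch one session per policy.

    Writes whatever the scenario permits: the stored payload under
    ``store_dir``, the transmitted payload under ``sink_dir``, and a
    metadata-only audit log (line JSON) at ``audit_path``.  Under a
    store-nothing scenario no session or report file is persisted
    locally — the report exists only in the returned outcome.
    """
    spec = config.resolve_scenario()
    analyzer = _movement_analyzer(config.test)

    if config.input_path:
        session = read_session(config.input_path)
    elif config.test == "t10m":
        session, _ = synth.generate_t10m(
            synth.GaitProfile(), config.noise_model(), config.seed
        )
    else:
        session, _ = synth.generate_itug(
            synth.ITUGProfile(), config.noise_model(), config.seed
        )

    outcome = policy.process_session(
        session, spec, analyzers=analyzer, alert_bounds=config.alert_bounds
    )

    if config.store_dir and outcome.stored_payload is not None:
        store = Path(config.store_dir)
        store.mkdir(parents=True, exist_ok=True)
        if isinstance(outcome.stored_payload, SensorSession):
            write_session(outcome.stored_payload, store / "raw_session.csv")
        else:
            (store / "report.json").write_text(
                json.dumps(_summaries_jsonable(outcome.stored_payload), indent=1)
            )
    if config.sink_dir and outcome.transmitted_payload is not None:
        sink = Path(config.sink_dir)
        sink.mkdir(parents=True, exist_ok=True)
        if isinstance(outcome.transmitted_payload, SensorSession):
            write_session(outcome.transmitted_payload, sink / "raw_session.csv")
        elif isinstance(outcome.transmitted_payload, list):
            (sink / "handshakes.jsonl").write_text(
                "\n".join(json.dumps(c) for c in outcome.transmitted_payload) + "\n"
            )
        else:
            (sink / "report.json").write_text(
                json.dumps(_summaries_jsonable(outcome.transmitted_payload), indent=1)
            )
    if config.audit_path:
        Path(config.audit_path).parent.mkdir(parents=True, exist_ok=True)
        with open(config.audit_path, "a") as fh:
            for entry in outcome.audit_log:
                fh.write(json.dumps({"scenario": spec.letter, **entry}) + "\n")
    return outcome
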