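"""Scenario taxonomy, data-flow contracts, and leak freedom."""

import json

import numpy as np
import pytest

import dndmotion as dm
from dndmotion import policy
from dndmotion.errors import ConfigError, ParameterError

S, T = dm.StorageLevel, dm.TransmissionLevel

EXPECTED_LETTERS = {
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


def test_scenario_grid_is_complete_and_correct():
    for (s_name, t_name), letter in EXPECTED_LETTERS.items():
        spec = dm.classify_scenario(S[s_name], T[t_name])
        assert spec.letter == letter
        assert spec.dnd_applicable == (letter in set("ABCDEF"))


def test_letter_round_trip_identity():
    for letter in policy.SCENARIO_LETTERS:
        spec = dm.scenario_for_letter(letter)
        again = dm.classify_scenario(spec.storage, spec.transmission)
        assert again == spec
    with pytest.raises(ConfigError):
        dm.scenario_for_letter("Z")


def test_scenario_privacy_matches_quantification_grid():
    grid = dm.scenario_matrix([0, 30, 100], [0, 10, 30, 100])
    store_ix = {"NOTHING": 0, "ANALYTIC_RESULT": 1, "RAW_DATA": 2}
    trans_ix = {"NOTHING": 0, "HANDSHAKE": 1, "ANALYTIC_RESULT": 2, "RAW_DATA": 3}
    for letter in policy.SCENARIO_LETTERS:
        spec = dm.scenario_for_letter(letter)
        cell = grid[store_ix[spec.storage.name], trans_ix[spec.transmission.name]]
        assert dm.scenario_privacy(spec) == pytest.approx(cell, rel=1e-12)
    impractical = dm.classify_scenario(S.RAW_DATA, T.NOTHING)
    assert dm.scenario_privacy(impractical) == 0.0


def test_streaming_and_offline_reports_agree(noisy_itug, summary_compare):
    session, _ = noisy_itug
    streaming = dm.process_session(session, dm.scenario_for_letter("A")).report
    offline = dm.offline_analytics(session)
    for ch in policy.CHANNELS:
        summary_compare(streaming[ch], offline[ch], rtol=1e-9)


def _payload_text(payload):
    """Serialise any outcome payload for a content scan."""
    if payload is None:
        return ""
    if isinstance(payload, dm.SensorSession):
        return np.array2string(payload.accel, precision=17)
    if isinstance(payload, list):
        return json.dumps(payload)
    return json.dumps(
        {k: (v.as_dict() if hasattr(v, "as_dict") else v) for k, v in payload.items()}
    )


@pytest.mark.parametrize("letter", list("ABCDEF"))
def test_dnd_scenarios_leak_no_raw_samples(marked_session, letter):
    """Store-nothing / no-raw-transmission outcomes must not contain raw values."""
    session, needle = marked_session
    out = dm.process_session(session, dm.scenario_for_letter(letter))
    assert not isinstance(out.stored_payload, dm.SensorSession)
    assert not isinstance(out.transmitted_payload, dm.SensorSession)
    for payload in (out.stored_payload, out.transmitted_payload):
        assert needle not in _payload_text(payload)
    assert needle not in json.dumps(out.audit_log)


def test_handshake_payload_is_codes_only(marked_session):
    out = dm.process_session(marked_session[0], dm.scenario_for_letter("B"))
    assert isinstance(out.transmitted_payload, list)
    for code in out.transmitted_payload:
        assert set(code) <= {"code", "seq", "subject"}
    assert out.stored_payload is None


def test_handshake_alert_fires_on_threshold_crossing(marked_session):
    quiet = dm.process_session(
        marked_session[0],
        dm.scenario_for_letter("B"),
        alert_bounds={("amag", "max"): 1e6},
    )
    loud = dm.process_session(
        marked_session[0],
        dm.scenario_for_letter("B"),
        alert_bounds={("amag", "max"): 1.0},
    )
    codes_quiet = {c["code"] for c in quiet.transmitted_payload}
    codes_loud = {c["code"] for c in loud.transmitted_payload}
    assert "ALERT:AMAG_MAX" not in codes_quiet
    assert "ALERT:AMAG_MAX" in codes_loud


def test_scenario_a_keeps_report_local_only(noisy_itug):
    session, _ = noisy_itug
    out = dm.process_session(session, dm.scenario_for_letter("A"))
    assert out.stored_payload is None and out.transmitted_payload is None
    assert set(policy.CHANNELS) <= set(out.report)
    actions = [e["action"] for e in out.audit_log]
    assert "erase_raw" in actions and "analyse_streaming" in actions


def test_scenario_c_transmits_report_and_erases(noisy_itug):
    session, _ = noisy_itug
    out = dm.process_session(session, dm.scenario_for_letter("C"))
    assert out.stored_payload is None
    assert set(policy.CHANNELS) <= set(out.transmitted_payload)
    assert out.audit_log[-1]["action"] == "erase_raw"


def test_scenario_j_transmits_raw_bit_identical(noisy_itug):
    session, _ = noisy_itug
    out = dm.process_session(session, dm.scenario_for_letter("J"))
    assert out.stored_payload is None
    sent = out.transmitted_payload
    assert isinstance(sent, dm.SensorSession)
    assert np.array_equal(sent.accel, session.accel)
    assert np.array_equal(sent.gyro, session.gyro)
    assert np.array_equal(sent.quat, session.quat)


def test_offline_analytics_rejects_empty():
    empty = dm.SensorSession(
        np.empty(0), np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 4))
    )
    with pytest.raises(ParameterError):
        dm.offline_analytics(empty)
    with pytest.raises(ParameterError):
        dm.process_session(empty, dm.scenario_for_letter("A"))


def test_impractical_scenario_refused(noisy_itug):
    session, _ = noisy_itug
    spec = dm.classify_scenario(S.RAW_DATA, T.NOTHING)
    with pytest.raises(ConfigError):
        dm.process_session(session, spec)


def test_analyzer_failure_keeps_policy_contract(marked_session):
    def broken(_):
        raise RuntimeError("boom")

    session, needle = marked_session
    out = dm.process_session(session, dm.scenario_for_letter("G"), analyzers=broken)
    assert out.error is not None and "boom" in out.error
    # contract: G still stores raw locally, transmits only the report
    assert isinstance(out.stored_payload, dm.SensorSession)
    assert needle not in _payload_text(out.transmitted_payload)
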