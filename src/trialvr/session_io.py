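"""Single-file JSON serialization of an entire experimental session.

The schema (kept stable; version tag ``trialvr-session/1``)::

    {
      "schema": "trialvr-session/1",
      "metadata": {...}, "config": {...},
      "start_time": float|null, "end_time": float|null,
      "validations": [{"timestamp": ..., "targets": [...]}, ...],
      "trials": [
        {"index": int, "number": int|null, "block": int, "status": str,
         "params": {...}, "results": {...},
         "events": [{"time", "frame", "label", "payload"}],
         "samples": [{"time", "frame",
                      "nodes": {id: {"pos": [x,y,z], "quat": [x,y,z,w]}|null},
                      "gaze": {...}|null, "state": {...}}]}
      ]
    }

Loading the saved file reproduces an equal session on all persisted
fields (floats survive exactly via repr-based JSON encoding).
"""

from __future__ import annotations

import json

from .design import ExperimentSession, ParamSet, SerializationError, TrialRecord
from .recorder import EventRecord, Sample
from .validation import ValidationResult

__all__ = [
    "session_to_dict",
    "session_from_dict",
    "save_session_json",
    "load_session_json",
]

SCHEMA = "trialvr-session/1"

_JSONABLE = (bool, int, float, str, type(None))


def _check_jsonable(value, path: str):
    if isinstance(value, _JSONABLE):
        return value
    if isinstance(value, dict):
        return {k: _check_jsonable(v, f"{path}.{k}") for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_check_jsonable(v, f"{path}[{i}]") for i, v in enumerate(value)]
    raise SerializationError(
        f"unserializable value of type {type(value).__name__} at {path!r}"
    )


def _trial_to_dict(trial: TrialRecord) -> dict:
    return {
        "index": trial.index,
        "number": trial.number,
        "block": trial.block,
        "status": trial.status,
        "params": trial.params.to_dict(),
        "results": trial.results.to_dict(),
        "events": [e.to_dict() for e in trial.events],
        "samples": [s.to_dict() for s in trial.samples],
    }


def _trial_from_dict(d: dict) -> TrialRecord:
    trial = TrialRecord(
        index=d["index"],
        number=d.get("number"),
        block=d.get("block", 0),
        status=d.get("status", "pending"),
        params=ParamSet(d.get("params", {})),
    )
    results = ParamSet(d.get("results", {}))
    results._set_frozen(trial.status == "pending")
    trial.results = results
    trial.events = [EventRecord.from_dict(e) for e in d.get("events", [])]
    trial.samples = [Sample.from_dict(s) for s in d.get("samples", [])]
    return trial


def session_to_dict(session: ExperimentSession) -> dict:
    doc = {
        "schema": SCHEMA,
        "metadata": session.metadata.to_dict(),
        "config": session.config.to_dict(),
        "start_time": session.start_time,
        "end_time": session.end_time,
        "validations": [v.to_dict() for v in session.validations],
        "trials": [_trial_to_dict(t) for t in session.trials],
    }
    return _check_jsonable(doc, "session")


def session_from_dict(doc: dict) -> ExperimentSession:
    session = ExperimentSession(
        metadata=ParamSet(doc.get("metadata", {})),
        config=ParamSet(doc.get("config", {})),
        start_time=doc.get("start_time"),
        end_time=doc.get("end_time"),
    )
    session.validations = [
        ValidationResult.from_dict(v) for v in doc.get("validations", [])
    ]
    session.trials = [_trial_from_dict(t) for t in doc.get("trials", [])]
    return session


def save_session_json(session: ExperimentSession, path) -> None:
    """Write the session as a compact single-file JSON document."""
    doc = session_to_dict(session)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, separators=(",", ":"))
        fh.write("\n")


def load_session_json(path) -> ExperimentSession:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return session_from_dict(doc)
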