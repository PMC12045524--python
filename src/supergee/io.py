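"""Serialization of session logs and analysis artifacts.

A session is written as two plain-text files: a JSON-lines samples file
(one 100 Hz sample per line: trial, t, x, v, kL, kR) and a JSON sidecar
(``<path>.events.json``) carrying the schema version, task configuration,
per-trial events and success flags, planet sequence, hour played and
timestamp.  The round trip is lossless; the wide-CSV export flattens
events away and is documented as lossy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .metrics import MalformedLogError
from .task import SessionLog, TaskConfig, TrialLog

__all__ = [
    "SCHEMA_VERSION",
    "SchemaVersionError",
    "write_session",
    "read_session",
    "session_to_csv",
    "RunManifest",
    "config_hash",
]

SCHEMA_VERSION = 1


class SchemaVersionError(ValueError):
    """The file was written by an incompatible schema version."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".events.json")


def write_session(path: str | Path, session: SessionLog) -> Path:
    """Write the JSONL samples file and its event sidecar; returns the
    samples path."""
    path = Path(path)
    with path.open("w") as fh:
        for log in session.trial_logs:
            for t, x, v, kl, kr in zip(
                log.times, log.positions, log.velocities, log.key_left, log.key_right
            ):
                fh.write(
                    json.dumps(
                        {
                            "trial": log.trial_index,
                            "t": float(t),
                            "x": float(x),
                            "v": float(v),
                            "kL": int(kl),
                            "kR": int(kr),
                        }
                    )
                    + "\n"
                )
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(session.config),
        "hour_played": session.hour_played,
        "timestamp": session.timestamp,
        "planet_sequence": [list(p) for p in session.planet_sequence],
        "trials": [
            {
                "trial_index": log.trial_index,
                "n_samples": len(log),
                "success": bool(log.success),
                "events": [[float(t), ev] for t, ev in log.events],
            }
            for log in session.trial_logs
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path: str | Path) -> SessionLog:
    """Read a session written by :func:`write_session`.

    Truncated or malformed files raise :class:`MalformedLogError`; a
    sidecar from a different schema version raises
    :class:`SchemaVersionError`.
    """
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise MalformedLogError(f"missing event sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"schema version {meta.get('schema_version')} != {SCHEMA_VERSION}"
        )
    config = TaskConfig(**meta["config"])

    per_trial: dict[int, list[dict[str, Any]]] = {}
    with path.open() as fh:
        for line_no, line in enumerate(fh, 1):
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise MalformedLogError(f"bad JSONL at line {line_no}") from exc
            per_trial.setdefault(rec["trial"], []).append(rec)

    logs = []
    for tr in meta["trials"]:
        i = tr["trial_index"]
        recs = per_trial.get(i, [])
        if len(recs) != tr["n_samples"]:
            raise MalformedLogError(
                f"trial {i}: expected {tr['n_samples']} samples, found {len(recs)}"
            )
        logs.append(
            TrialLog(
                trial_index=i,
                times=np.array([r["t"] for r in recs]),
                positions=np.array([r["x"] for r in recs]),
                velocities=np.array([r["v"] for r in recs]),
                key_left=np.array([bool(r["kL"]) for r in recs]),
                key_right=np.array([bool(r["kR"]) for r in recs]),
                events=[(float(t), ev) for t, ev in tr["events"]],
                success=bool(tr["success"]),
            )
        )
    return SessionLog(
        trial_logs=logs,
        planet_sequence=[tuple(p) for p in meta["planet_sequence"]],
        hour_played=int(meta["hour_played"]),
        timestamp=meta["timestamp"],
        config=config,
    )


def session_to_csv(path: str | Path, session: SessionLog) -> Path:
    """Wide CSV export of the raw samples (events are flattened away)."""
    frames = [
        pd.DataFrame(
            {
                "trial_index": log.trial_index,
                "t": log.times,
                "x": log.positions,
                "v": log.velocities,
                "kL": log.key_left.astype(int),
                "kR": log.key_right.astype(int),
            }
        )
        for log in session.trial_logs
    ]
    out = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return out


def config_hash(obj: Any) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record tying every output of a run to its inputs."""

    seed: int
    config_hashes: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)
    stage_versions: dict[str, int] = field(default_factory=lambda: {"schema": SCHEMA_VERSION})
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        p = Path(path)
        p.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return p
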