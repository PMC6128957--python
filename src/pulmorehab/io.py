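"""Readers and writers for session logs, rosters, outcomes, and config.

Session logs come in two renderings of the same schema:

* **JSONL** — one object per line with the vitals stream embedded:
  ``{"patient_id", "session_date", "distance", "duration", "borg",
  "samples": [[t, spo2, hr], ...]}``.
* **CSV** — one row per session (UTF-8, comma, header required, ISO-8601
  dates) with a ``session_id`` column; vitals streams live in a companion
  ``<stem>.samples.jsonl`` file keyed by that id.

Malformed rows are collected with their line numbers rather than aborting
the read; the read fails only if every row is invalid.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field

from .regimen import FixedLevelTable, InteractiveLevelTable, WalkSession

_FORMATS = ("csv", "jsonl")


@dataclass
class ReadReport:
    """Validated sessions plus per-line errors from one file."""

    sessions: list[WalkSession]
    errors: list[tuple[int, str]] = field(default_factory=list)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _session_to_obj(s: WalkSession) -> dict:
    return {
        "patient_id": s.patient_id,
        "session_date": s.session_date.isoformat(),
        "distance": s.distance,
        "duration": s.duration,
        "borg": s.borg,
        "samples": [list(t) for t in s.samples],
    }


def write_sessions(sessions: Sequence[WalkSession], path: str | Path,
                   fmt: Optional[str] = None) -> Path:
    """Write a session log as JSONL (embedded samples) or CSV + companion."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for s in sessions:
                fh.write(json.dumps(_session_to_obj(s)) + "\n")
        return path
    companion = path.with_suffix(".samples.jsonl")
    with path.open("w", encoding="utf-8", newline="") as fh, \
            companion.open("w", encoding="utf-8") as sfh:
        writer = csv.writer(fh)
        writer.writerow(["session_id", "patient_id", "session_date",
                         "distance", "duration", "borg"])
        for i, s in enumerate(sessions):
            sid = f"S{i:06d}"
            writer.writerow([sid, s.patient_id, s.session_date.isoformat(),
                             repr(s.distance), repr(s.duration),
                             "" if s.borg is None else repr(s.borg)])
            if s.samples:
                sfh.write(json.dumps(
                    {"session_id": sid, "samples": [list(t) for t in s.samples]}
                ) + "\n")
    return path


def read_sessions(path: str | Path, fmt: Optional[str] = None) -> ReadReport:
    """Read and validate a session log.

    Returns every record that passes :class:`WalkSession` validation plus
    a list of ``(line_number, message)`` for records that do not.  Raises
    only if the file has records and none of them validate.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    sessions: list[WalkSession] = []
    errors: list[tuple[int, str]] = []
    n_rows = 0

    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                n_rows += 1
                try:
                    obj = json.loads(line)
                    obj["samples"] = [tuple(t) for t in obj.get("samples") or []]
                    sessions.append(WalkSession.model_validate(obj))
                except Exception as exc:
                    errors.append((lineno, str(exc)))
    else:
        samples_by_id: dict[str, list] = {}
        companion = path.with_suffix(".samples.jsonl")
        if companion.exists():
            with companion.open(encoding="utf-8") as sfh:
                for line in sfh:
                    if line.strip():
                        obj = json.loads(line)
                        samples_by_id[obj["session_id"]] = [
                            tuple(t) for t in obj["samples"]]
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):  # 1 = header
                n_rows += 1
                try:
                    borg = row.get("borg") or None
                    sessions.append(WalkSession(
                        patient_id=row["patient_id"],
                        session_date=_dt.date.fromisoformat(row["session_date"]),
                        distance=float(row["distance"]),
                        duration=float(row["duration"]),
                        borg=None if borg is None else float(borg),
                        samples=tuple(samples_by_id.get(row.get("session_id", ""), [])),
                    ))
                except Exception as exc:
                    errors.append((lineno, str(exc)))

    if n_rows and not sessions:
        summary = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:5])
        raise ValueError(f"no valid session records in {path} ({summary})")
    return ReadReport(sessions=sessions, errors=errors)


class MonitorSettings(BaseModel):
    model_config = {"frozen": True, "extra": "forbid"}

    spo2_threshold: float = 90.0
    debounce_s: float = 30.0


class RunConfig(BaseModel):
    """Top-level run configuration loadable from YAML or JSON.

    Unknown keys are rejected so typos in config files fail loudly.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    fixed_table: FixedLevelTable = Field(default_factory=FixedLevelTable)
    interactive_table: InteractiveLevelTable = Field(
        default_factory=InteractiveLevelTable)
    monitor: MonitorSettings = Field(default_factory=MonitorSettings)
    stride_length_m: float = 0.70
    sixmwt_max_speed: Optional[float] = None
    seed: int = 0
    site: Optional[str] = None


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML/JSON; defaults when path is None."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
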