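"""Longitudinal patient-record store backing the automatic baseline comparison.

Storage is flat JSONL, one file per patient, so a records directory is
plain text and diffable.  The in-memory store keeps each patient's session
summaries strictly time-ordered.
"""
from __future__ import annotations

import bisect
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "HistoryIntegrityError",
    "RecordStore",
    "SessionSummary",
    "append_session",
    "latest_before",
]

_SAFE_ID = re.compile(r"^[A-Za-z0-9._-]+$")


class HistoryIntegrityError(ValueError):
    """Raised when a persisted history fails to parse or violates ordering."""


@dataclass(frozen=True)
class SessionSummary:
    """Terminal-session digest sufficient for the record-comparison item."""

    patient_id: str
    timestamp: datetime
    combo: tuple[bool, bool, bool, bool]  # present flags for F1..F4
    delirium: bool
    item_values: dict[int, str] = field(default_factory=dict)  # cognitive items 1..7
    modality: str = "dst"
    mode: str = "fast"

    def to_json_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timestamp": self.timestamp.isoformat(),
            "combo": list(self.combo),
            "delirium": self.delirium,
            "item_values": {str(k): v for k, v in self.item_values.items()},
            "modality": self.modality,
            "mode": self.mode,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "SessionSummary":
        try:
            combo = tuple(bool(x) for x in data["combo"])
            if len(combo) != 4:
                raise ValueError("combo must have 4 entries")
            return cls(
                patient_id=str(data["patient_id"]),
                timestamp=datetime.fromisoformat(data["timestamp"]),
                combo=combo,  # type: ignore[arg-type]
                delirium=bool(data["delirium"]),
                item_values={int(k): str(v) for k, v in data.get("item_values", {}).items()},
                modality=data.get("modality", "dst"),
                mode=data.get("mode", "fast"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise HistoryIntegrityError(f"corrupted session record: {exc}") from exc


def _coerce_summary(obj) -> SessionSummary:
    if isinstance(obj, SessionSummary):
        return obj
    # duck-typed terminal AssessmentSession
    summary = getattr(obj, "summary", None)
    if callable(summary):
        if getattr(obj, "outcome", None) is None:
            raise ValueError("cannot append a non-terminal session")
        return summary()
    raise TypeError(f"cannot append object of type {type(obj).__name__}")


class RecordStore:
    """In-memory store of per-patient session summaries with JSONL persistence."""

    def __init__(self) -> None:
        self._by_patient: dict[str, list[SessionSummary]] = {}

    # -- mutation --------------------------------------------------------

    def append(self, session) -> "RecordStore":
        """Add a terminal session; idempotent on (patient_id, timestamp)."""
        s = _coerce_summary(session)
        rows = self._by_patient.setdefault(s.patient_id, [])
        keys = [r.timestamp for r in rows]
        i = bisect.bisect_left(keys, s.timestamp)
        if i < len(rows) and rows[i].timestamp == s.timestamp:
            return self  # idempotent
        rows.insert(i, s)
        return self

    # -- queries ---------------------------------------------------------

    def patients(self) -> list[str]:
        return sorted(self._by_patient)

    def sessions(self, patient_id: str) -> tuple[SessionSummary, ...]:
        return tuple(self._by_patient.get(patient_id, ()))

    def latest_before(self, patient_id: str, t: datetime) -> Optional[SessionSummary]:
        """Most recent session strictly earlier than ``t``; None if none exists."""
        rows = self._by_patient.get(patient_id)
        if not rows:
            return None
        keys = [r.timestamp for r in rows]
        i = bisect.bisect_left(keys, t)
        return rows[i - 1] if i > 0 else None

    def baseline(self, patient_id: str) -> Optional[SessionSummary]:
        """Earliest stored session (the admission assessment)."""
        rows = self._by_patient.get(patient_id)
        return rows[0] if rows else None

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_patient.values())

    # -- persistence -----------------------------------------------------

    def save(self, directory: Union[str, Path]) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for pid, rows in self._by_patient.items():
            if not _SAFE_ID.match(pid):
                raise ValueError(f"patient id not filename-safe: {pid!r}")
            with open(d / f"{pid}.jsonl", "w") as fh:
                for r in rows:
                    fh.write(json.dumps(r.to_json_dict(), sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "RecordStore":
        d = Path(directory)
        if not d.exists():
            raise FileNotFoundError(f"records directory not found: {d}")
        store = cls()
        for path in sorted(d.glob("*.jsonl")):
            pid = path.stem
            for ln, line in enumerate(path.read_text().splitlines(), 1):
                if not line.strip():
                    continue
                try:
                    data = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise HistoryIntegrityError(
                        f"{path}:{ln}: invalid JSON: {exc}"
                    ) from exc
                s = SessionSummary.from_json_dict(data)
                if s.patient_id != pid:
                    raise HistoryIntegrityError(
                        f"{path}:{ln}: patient id {s.patient_id!r} does not match file"
                    )
                store.append(s)
        return store


def append_session(store: RecordStore, session) -> RecordStore:
    return store.append(session)


def latest_before(store: RecordStore, patient_id: str, t: datetime):
    return store.latest_before(patient_id, t)
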