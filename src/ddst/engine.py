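"""Adaptive assessment engine.

Sequencing walks the bank's page order, jumping over every item whose
feature already has positive evidence.  In ``fast`` mode the session ends
as soon as the diagnosis is decidable: the classifier applied to the
features currently present agrees with the classifier applied to every
feature that is present or still reachable.  The record-comparison item is
never displayed; its value is re-derived from the stored baseline after
every response.

The diagnostic rule is the CAM algorithm: feature 1 AND feature 2 AND
(feature 3 OR feature 4).
"""
from __future__ import annotations

import itertools
from collections.abc import Mapping
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Optional, Union

from .item_bank import AUTO_ITEM, FEATURES, Feature, ItemBank, feature_evidence_map
from .records import RecordStore, SessionSummary

__all__ = [
    "ABSENT",
    "AssessmentSession",
    "EngineError",
    "FeatureStatus",
    "ItemResponse",
    "NORMAL",
    "OutcomeCategory",
    "POSITIVE",
    "PRESENT",
    "SequencingError",
    "SessionStateError",
    "TERMINAL",
    "UNDETERMINED",
    "classify",
    "derive_item22",
    "enumerate_outcomes",
    "next_item",
    "session_metrics",
    "start_session",
    "submit_response",
]

NORMAL = "normal"
POSITIVE = "positive"

PRESENT = "present"
ABSENT = "absent"
UNDETERMINED = "undetermined"

MODALITIES = ("paper", "dst")
MODES = ("full", "fast")

#: objectively scored cognitive test items, compared item-by-item against baseline
COGNITIVE_ITEMS = tuple(range(1, 8))


class _Terminal:
    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "TERMINAL"


#: sentinel returned by :func:`next_item` when the session has just ended
TERMINAL = _Terminal()


class EngineError(RuntimeError):
    pass


class SequencingError(EngineError):
    """An item was submitted out of order or twice."""


class SessionStateError(EngineError):
    """An operation was called in the wrong session state."""


@dataclass(frozen=True)
class ItemResponse:
    item_id: int
    value: Optional[str]  # NORMAL | POSITIVE; None iff skipped
    source: str  # entered | skipped | auto
    timestamp: datetime


@dataclass(frozen=True)
class FeatureStatus:
    feature: Feature
    state: str  # PRESENT | ABSENT | UNDETERMINED
    evidence: tuple[int, ...]


@dataclass(frozen=True)
class OutcomeCategory:
    combo: tuple[bool, bool, bool, bool]  # present flags F1..F4
    delirium: bool
    label: str


def _as_flags(combo) -> tuple[bool, bool, bool, bool]:
    if isinstance(combo, Mapping):
        vals = [combo[f] for f in FEATURES]
    else:
        vals = list(combo)
    if len(vals) != 4:
        raise ValueError("feature combo must have 4 entries")
    flags = []
    for v in vals:
        if isinstance(v, str):
            if v == PRESENT:
                flags.append(True)
            elif v == ABSENT:
                flags.append(False)
            else:
                raise ValueError(f"feature state must be present/absent, got {v!r}")
        else:
            flags.append(bool(v))
    return tuple(flags)  # type: ignore[return-value]


def classify(combo) -> OutcomeCategory:
    """Classify a complete present/absent assignment of the four features."""
    flags = _as_flags(combo)
    f1, f2, f3, f4 = flags
    delirium = f1 and f2 and (f3 or f4)
    marks = "".join(f.value + ("+" if p else "-") for f, p in zip(FEATURES, flags))
    verdict = "delirium-positive" if delirium else "delirium-negative"
    return OutcomeCategory(combo=flags, delirium=delirium, label=f"{marks} {verdict}")


def enumerate_outcomes() -> list[OutcomeCategory]:
    """All 16 feature-combination outcome categories, in a stable order."""
    return [classify(c) for c in itertools.product((False, True), repeat=4)]


def _derive_change_value(
    baseline: Optional[SessionSummary],
    values: Mapping[int, str],
    feat_items: Mapping[Feature, list[int]],
) -> str:
    """Record-comparison rule: positive iff the current pattern shows a NEW deficit.

    A new deficit is positive evidence for a feature that was absent at
    baseline, or a positive response on a cognitive test item that was
    answered normal at baseline.
    """
    if baseline is None:
        return NORMAL
    for idx, f in enumerate(FEATURES):
        if baseline.combo[idx]:
            continue
        for i in feat_items[f]:
            if i != AUTO_ITEM and values.get(i) == POSITIVE:
                return POSITIVE
    for i in COGNITIVE_ITEMS:
        if baseline.item_values.get(i) == NORMAL and values.get(i) == POSITIVE:
            return POSITIVE
    return NORMAL


def _utcnow() -> datetime:
    return datetime.now(timezone.utc)


class AssessmentSession:
    """One administration of the instrument to one patient by one nurse."""

    def __init__(
        self,
        bank: ItemBank,
        patient_id: str,
        nurse_id: str,
        modality: str = "dst",
        mode: str = "fast",
        baseline: Optional[SessionSummary] = None,
        start_time: Optional[datetime] = None,
    ) -> None:
        if modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.bank = bank
        self.patient_id = patient_id
        self.nurse_id = nurse_id
        self.modality = modality
        self.mode = mode
        self.baseline = baseline
        self.no_baseline = baseline is None
        self.outcome: Optional[OutcomeCategory] = None
        self.started_at = start_time or _utcnow()
        self.ended_at: Optional[datetime] = None

        self._feat_items = feature_evidence_map(bank)
        self._item_feature = {it.id: it.feature for it in bank.items}
        self._order = bank.display_order()
        self._cursor = 0
        self._values: dict[int, str] = {}
        self._skipped: set[int] = set()
        self.responses: list[ItemResponse] = []

        # the hidden record-comparison item resolves immediately and is
        # re-derived after every entered response
        self._values[AUTO_ITEM] = _derive_change_value(
            self.baseline, self._values, self._feat_items
        )
        self.responses.append(
            ItemResponse(AUTO_ITEM, self._values[AUTO_ITEM], "auto", self.started_at)
        )

    # -- state inspection ------------------------------------------------

    @property
    def is_terminal(self) -> bool:
        return self.outcome is not None

    @property
    def duration_minutes(self) -> Optional[float]:
        if self.ended_at is None:
            return None
        return (self.ended_at - self.started_at).total_seconds() / 60.0

    def feature_status(self, feature: Feature) -> FeatureStatus:
        items = self._feat_items[feature]
        evidence = tuple(i for i in items if self._values.get(i) == POSITIVE)
        if evidence:
            state = PRESENT
        elif all(self._values.get(i) == NORMAL for i in items):
            state = ABSENT
        else:
            state = UNDETERMINED
        return FeatureStatus(feature=feature, state=state, evidence=evidence)

    def features(self) -> tuple[FeatureStatus, ...]:
        return tuple(self.feature_status(f) for f in FEATURES)

    # -- stepping --------------------------------------------------------

    def _pending_items(self, feature: Feature) -> list[int]:
        """Display items of a feature that could still be administered."""
        return [
            i
            for i in self._feat_items[feature]
            if i != AUTO_ITEM and i not in self._values and i not in self._skipped
        ]

    def _auto_item_mutable(self) -> bool:
        """Could the record-comparison item still flip to positive?"""
        if self.baseline is None or self._values[AUTO_ITEM] == POSITIVE:
            return False
        for f in FEATURES:
            for i in self._pending_items(f):
                idx = FEATURES.index(self._item_feature[i])
                if not self.baseline.combo[idx]:
                    return True
                if i in COGNITIVE_ITEMS and self.baseline.item_values.get(i) == NORMAL:
                    return True
        return False

    def _decidable(self) -> bool:
        lower: dict[Feature, bool] = {}
        upper: dict[Feature, bool] = {}
        auto_feature = self._item_feature[AUTO_ITEM]
        for f in FEATURES:
            present = self.feature_status(f).state == PRESENT
            lower[f] = present
            reachable = present or bool(self._pending_items(f))
            if f == auto_feature and self._auto_item_mutable():
                reachable = True
            upper[f] = reachable
        return classify(lower).delirium == classify(upper).delirium

    def next_item(self):
        """Next administrable item id, or TERMINAL (finalizing the session).

        Raises on a session that has already been finalized.
        """
        if self.is_terminal:
            raise SessionStateError("session is terminal")
        if self.mode == "fast" and self._decidable():
            self._finalize()
            return TERMINAL
        while self._cursor < len(self._order):
            iid = self._order[self._cursor]
            if iid in self._values or iid in self._skipped:
                self._cursor += 1
                continue
            if self.feature_status(self._item_feature[iid]).state == PRESENT:
                self._record_skip(iid)
                self._cursor += 1
                continue
            return iid
        self._finalize()
        return TERMINAL

    def submit(self, item_id: int, value: str) -> "AssessmentSession":
        if self.is_terminal:
            raise SessionStateError("cannot submit to a terminal session")
        if value not in (NORMAL, POSITIVE):
            raise ValueError(f"value must be {NORMAL!r} or {POSITIVE!r}")
        if item_id in self._values or item_id in self._skipped:
            raise SequencingError(f"item {item_id} was already administered")
        expected = self.next_item()
        if expected is TERMINAL:
            raise SequencingError("session reached its outcome; no item expected")
        if item_id != expected:
            raise SequencingError(
                f"out-of-order submission: expected item {expected}, got {item_id}"
            )
        self._values[item_id] = value
        self.responses.append(ItemResponse(item_id, value, "entered", _utcnow()))
        self._refresh_auto_item()
        return self

    def _refresh_auto_item(self) -> None:
        new = _derive_change_value(self.baseline, self._values, self._feat_items)
        if new != self._values[AUTO_ITEM]:
            self._values[AUTO_ITEM] = new
            for i, r in enumerate(self.responses):
                if r.source == "auto":
                    self.responses[i] = ItemResponse(AUTO_ITEM, new, "auto", _utcnow())
                    break

    def _record_skip(self, item_id: int) -> None:
        self._skipped.add(item_id)
        self.responses.append(ItemResponse(item_id, None, "skipped", _utcnow()))

    def _finalize(self) -> None:
        for iid in self._order:
            if iid not in self._values and iid not in self._skipped:
                self._record_skip(iid)
        # undetermined features (fast-mode early exit) label as absent;
        # decidability guarantees the delirium verdict is unaffected
        combo = tuple(self.feature_status(f).state == PRESENT for f in FEATURES)
        self.outcome = classify(combo)
        self.ended_at = _utcnow()

    # -- terminal-session products ---------------------------------------

    def metrics(self) -> dict:
        if not self.is_terminal:
            raise SessionStateError("metrics require a terminal session")
        administered = sum(1 for r in self.responses if r.source == "entered")
        skipped = len(self._skipped)
        auto = sum(1 for r in self.responses if r.source == "auto")
        assert administered + skipped + auto == len(self.bank.items)
        return {
            "items_administered": administered,
            "items_skipped": skipped,
            "duration": self.duration_minutes,
        }

    def summary(self) -> SessionSummary:
        if not self.is_terminal:
            raise SessionStateError("summary requires a terminal session")
        item_values = {
            i: self._values[i] for i in COGNITIVE_ITEMS if i in self._values
        }
        return SessionSummary(
            patient_id=self.patient_id,
            timestamp=self.ended_at or _utcnow(),
            combo=self.outcome.combo,
            delirium=self.outcome.delirium,
            item_values=item_values,
            modality=self.modality,
            mode=self.mode,
        )

    def value_of(self, item_id: int) -> Optional[str]:
        return self._values.get(item_id)


# -- module-level operation surface -------------------------------------


def start_session(
    bank: ItemBank,
    patient_id: str,
    nurse_id: str,
    modality: str = "dst",
    mode: str = "fast",
    history: Optional[RecordStore] = None,
    start_time: Optional[datetime] = None,
) -> AssessmentSession:
    """Initialize a session; the record-comparison item is pre-derived from history."""
    start_time = start_time or _utcnow()
    baseline = (
        history.latest_before(patient_id, start_time) if history is not None else None
    )
    return AssessmentSession(
        bank,
        patient_id,
        nurse_id,
        modality=modality,
        mode=mode,
        baseline=baseline,
        start_time=start_time,
    )


def next_item(session: AssessmentSession):
    return session.next_item()


def submit_response(session: AssessmentSession, item_id: int, value: str):
    return session.submit(item_id, value)


def derive_item22(
    history: Optional[RecordStore], session: AssessmentSession
) -> ItemResponse:
    """Stand-alone record-comparison derivation against a history store."""
    baseline = (
        history.latest_before(session.patient_id, session.started_at)
        if history is not None
        else None
    )
    value = _derive_change_value(baseline, session._values, session._feat_items)
    return ItemResponse(AUTO_ITEM, value, "auto", _utcnow())


def session_metrics(session: AssessmentSession) -> dict:
    return session.metrics()


def run_scripted(
    session: AssessmentSession, answers: Mapping[int, str]
) -> AssessmentSession:
    """Drive a session to its terminal state from a full answer table."""
    while (iid := session.next_item()) is not TERMINAL:
        session.submit(iid, answers[iid])
    return session
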