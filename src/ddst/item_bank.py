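"""Instrument definition: the 22-item bank, feature mapping, and page layout.

The bank ships with a default reconstruction: generic item wording organised
into an inquiry block (cognitive tests and symptom probes), an observation
block, and a single auto-derived record-comparison item that is never shown
on a page.  Any licensed wording can be dropped in through a YAML/JSON
config with the same schema.
"""
from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "AUTO_ITEM",
    "BankValidationError",
    "Block",
    "CUE_ITEMS",
    "Feature",
    "FEATURES",
    "Item",
    "ItemBank",
    "PageDef",
    "REMINDER_ITEMS",
    "bank_from_dict",
    "bank_to_dict",
    "default_item_bank",
    "feature_evidence_map",
    "load_item_bank",
    "save_item_bank",
]


class Feature(str, enum.Enum):
    """The four diagnostic features scored by the instrument."""

    F1 = "F1"  #: acute onset / fluctuating course
    F2 = "F2"  #: inattention
    F3 = "F3"  #: disorganized thinking
    F4 = "F4"  #: altered level of consciousness


FEATURES: tuple[Feature, ...] = tuple(Feature)


class Block(str, enum.Enum):
    INQUIRY = "inquiry"
    OBSERVATION = "observation"
    SELECTIVE = "selective"


N_ITEMS = 22
N_PAGES = 8
#: items whose expected correct response is surfaced as a reminder
REMINDER_ITEMS = frozenset({1, 2, 5})
#: items carrying an interpretation cue
CUE_ITEMS = frozenset(range(11, 21))
#: the record-comparison item, auto-derived and never displayed
AUTO_ITEM = 22


class BankValidationError(ValueError):
    """Raised when an item-bank config violates a structural invariant."""


class Item(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    id: int = Field(ge=1, le=N_ITEMS)
    text: str
    block: Block
    feature: Feature
    page: Optional[int] = Field(default=None, ge=1, le=N_PAGES)
    reminder: Optional[str] = None
    cue: Optional[str] = None
    auto_derived: bool = False


class PageDef(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    id: int = Field(ge=1, le=N_PAGES)
    items: tuple[int, ...]


class ItemBank(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    version: str = "default-reconstruction-1.0"
    items: tuple[Item, ...]
    pages: tuple[PageDef, ...]

    @model_validator(mode="after")
    def _check_invariants(self) -> "ItemBank":
        ids = [it.id for it in self.items]
        seen = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        if dupes:
            raise ValueError(f"duplicate item ids: {dupes}")
        missing = sorted(set(range(1, N_ITEMS + 1)) - set(ids))
        if missing:
            raise ValueError(f"missing item ids: {missing}")

        by_id = {it.id: it for it in self.items}
        for i in sorted(REMINDER_ITEMS):
            if not by_id[i].reminder:
                raise ValueError(f"item {i} must define a non-empty reminder")
        for i in sorted(CUE_ITEMS):
            if not by_id[i].cue:
                raise ValueError(f"item {i} must define a non-empty cue")

        auto = by_id[AUTO_ITEM]
        if not auto.auto_derived or auto.page is not None:
            raise ValueError(
                f"item {AUTO_ITEM} must be auto-derived and hidden (no page)"
            )
        for it in self.items:
            if it.id != AUTO_ITEM and it.auto_derived:
                raise ValueError(f"item {it.id} may not be auto-derived")
            if it.id != AUTO_ITEM and it.page is None:
                raise ValueError(f"item {it.id} must be assigned to a page")

        if len(self.pages) != N_PAGES:
            raise ValueError(
                f"bank must define exactly {N_PAGES} pages, got {len(self.pages)}"
            )
        page_ids = [p.id for p in self.pages]
        if sorted(page_ids) != list(range(1, N_PAGES + 1)):
            raise ValueError(f"page ids must be a permutation of 1..{N_PAGES}")

        placed: list[int] = []
        for p in self.pages:
            placed.extend(p.items)
        if len(placed) != len(set(placed)):
            raise ValueError("an item appears on more than one page")
        if set(placed) != set(range(1, N_ITEMS)):
            raise ValueError(
                f"pages must display exactly items 1..{N_ITEMS - 1}, got {sorted(set(placed))}"
            )
        for p in self.pages:
            for iid in p.items:
                if by_id[iid].page != p.id:
                    raise ValueError(
                        f"item {iid} page field disagrees with page {p.id} layout"
                    )

        covered = {it.feature for it in self.items}
        if covered != set(Feature):
            missing_f = sorted(f.value for f in set(Feature) - covered)
            raise ValueError(f"features without evidence items: {missing_f}")
        return self

    # -- convenience accessors -------------------------------------------

    def item(self, item_id: int) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def display_order(self) -> tuple[int, ...]:
        """Item ids in administration order: pages ascending, items in page order."""
        out: list[int] = []
        for p in sorted(self.pages, key=lambda p: p.id):
            out.extend(p.items)
        return tuple(out)

    def feature_items(self, feature: Feature) -> tuple[int, ...]:
        return tuple(it.id for it in self.items if it.feature == feature)


def feature_evidence_map(bank: ItemBank) -> dict[Feature, list[int]]:
    """Partition item ids by the feature they give evidence for."""
    out: dict[Feature, list[int]] = {f: [] for f in FEATURES}
    for it in bank.items:
        out[it.feature].append(it.id)
    for f in out:
        out[f].sort()
    return out


def _default_bank_dict() -> dict:
    items: list[dict] = []

    def add(id, text, block, feature, page, reminder=None, cue=None, auto=False):
        items.append(
            dict(
                id=id,
                text=text,
                block=block,
                feature=feature,
                page=page,
                reminder=reminder,
                cue=cue,
                auto_derived=auto,
            )
        )

    # inquiry block: orientation tests (disorganized thinking evidence)
    add(1, "Orientation test: state the current year", "inquiry", "F3", 1,
        reminder="Correct response: the current calendar year")
    add(2, "Orientation test: state the day of the week", "inquiry", "F3", 1,
        reminder="Correct response: today's day of the week")
    add(3, "Orientation test: state the type of place we are in", "inquiry", "F3", 1)
    # inquiry block: attention tests
    add(4, "Attention test: say the days of the week backward", "inquiry", "F2", 2)
    add(5, "Attention test: say the months of the year backward", "inquiry", "F2", 2,
        reminder="Correct response: months recited in reverse order without omission")
    add(6, "Attention test: repeat 3 digits backward", "inquiry", "F2", 3)
    add(7, "Attention test: repeat 4 digits backward", "inquiry", "F2", 3)
    # inquiry block: patient-reported symptom probes (acute change evidence)
    add(8, "Symptom probe: felt confused during the past day", "inquiry", "F1", 4)
    add(9, "Symptom probe: saw things that were not really there", "inquiry", "F1", 4)
    add(10, "Symptom probe: thoughts felt jumbled during the past day", "inquiry", "F1", 4)
    # observation block: altered level of consciousness
    add(11, "Observed: abnormally sleepy or difficult to rouse", "observation", "F4", 5,
        cue="Score positive if the patient dozes off or needs repeated stimulation")
    add(12, "Observed: hypervigilant or abnormally agitated", "observation", "F4", 5,
        cue="Score positive for restlessness or startle responses out of proportion")
    add(13, "Observed: stuporous or unresponsive to voice", "observation", "F4", 5,
        cue="Score positive if voice alone does not obtain a response")
    # observation block: disorganized thinking
    add(14, "Observed: rambling or irrelevant conversation", "observation", "F3", 6,
        cue="Score positive for speech that drifts off topic")
    add(15, "Observed: unclear or illogical flow of ideas", "observation", "F3", 6,
        cue="Score positive when reasoning cannot be followed")
    add(16, "Observed: unpredictable switching between subjects", "observation", "F3", 6,
        cue="Score positive for abrupt topic changes without transition")
    add(17, "Observed: answers unrelated to the questions asked", "observation", "F3", 6,
        cue="Score positive for non sequitur answers")
    # observation block: inattention
    add(18, "Observed: difficulty keeping track of the conversation", "observation", "F2", 7,
        cue="Score positive if questions must be repeated to regain attention")
    add(19, "Observed: easily distracted by surroundings", "observation", "F2", 7,
        cue="Score positive if ambient events interrupt the patient's responses")
    add(20, "Observed: inappropriate staring or reduced eye contact", "observation", "F2", 7,
        cue="Score positive for vacant gaze or failure to engage")
    # observation block: fluctuation observed during the session
    add(21, "Observed: level of attention or consciousness fluctuated during assessment",
        "observation", "F1", 8)
    # selective block: record comparison, derived from stored history
    add(22, "Acute change from the patient's baseline record", "selective", "F1", None,
        auto=True)

    pages = [
        dict(id=1, items=[1, 2, 3]),
        dict(id=2, items=[4, 5]),
        dict(id=3, items=[6, 7]),
        dict(id=4, items=[8, 9, 10]),
        dict(id=5, items=[11, 12, 13]),
        dict(id=6, items=[14, 15, 16, 17]),
        dict(id=7, items=[18, 19, 20]),
        dict(id=8, items=[21]),
    ]
    return dict(version="default-reconstruction-1.0", items=items, pages=pages)


def bank_from_dict(data: dict) -> ItemBank:
    """Validate a plain-dict config into an :class:`ItemBank`.

    Raises
    ------
    BankValidationError
        naming the first violated invariant.
    """
    try:
        return ItemBank.model_validate(data)
    except ValidationError as exc:
        raise BankValidationError(str(exc)) from exc


def bank_to_dict(bank: ItemBank) -> dict:
    return bank.model_dump(mode="json")


def default_item_bank() -> ItemBank:
    return bank_from_dict(_default_bank_dict())


def load_item_bank(path: Union[str, Path, None] = None) -> ItemBank:
    """Load and validate an instrument config (YAML or JSON).

    With ``path=None`` the built-in default reconstruction is returned.
    """
    if path is None:
        return default_item_bank()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"item bank config not found: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise BankValidationError(f"item bank config must be a mapping: {p}")
    return bank_from_dict(data)


def save_item_bank(bank: ItemBank, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(bank_to_dict(bank), fh, sort_keys=False)
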