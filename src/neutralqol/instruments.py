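"""Instrument definitions, item crosswalks, and confusion counting.

An *instrument* is a patient-reported HRQoL questionnaire described by its
item inventory.  Instruments are either *specific* (built for one disease,
condition, or symptom cluster) or *generic* (applicable across diseases,
e.g. SF-36, EQ-5D).  A *crosswalk* records reviewer-asserted correspondences
between a specific instrument's items and a generic instrument's items; the
package consumes these assertions, it never attempts semantic matching.

Confusion counting treats the specific instrument as the surrogate for the
ideal ("Neutral") construct: a specific item with a match is a true positive
of the generic instrument, one without a match a false negative, and a
generic item matched to nothing a false positive.  Because the specific
instrument itself cannot be known to be exhaustive, true negatives are not
countable; a fixed true-negative mass (default 0.9 item-equivalents) is
carried instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from ._util import ValidationError

Category = Literal["specific", "generic"]
Stratum = Literal["rare", "non_rare", "symptom_specific", "not_applicable"]

#: Disease-prevalence cut-off defining the "rare" stratum: fewer than
#: 1 in 2000 of the population.  Metadata only — strata are user-asserted.
RARE_DISEASE_PREVALENCE_CUTOFF = 1 / 2000


class Item(BaseModel):
    """One questionnaire item."""

    item_id: str
    label: str
    domain: Optional[str] = None

    @field_validator("item_id", "label")
    @classmethod
    def _strip_nonempty(cls, v: str) -> str:
        v = v.strip()
        if not v:
            raise ValueError("item_id and label must be non-empty")
        return v

    @field_validator("domain", mode="before")
    @classmethod
    def _strip_domain(cls, v):
        if v is None:
            return None
        v = str(v).strip()
        return v or None


class InstrumentDefinition(BaseModel):
    """An instrument's identity, stratum, and item inventory."""

    instrument_id: str
    name: str
    category: Category
    stratum: Stratum
    items: list[Item]

    @field_validator("instrument_id", "name")
    @classmethod
    def _strip(cls, v: str) -> str:
        v = v.strip()
        if not v:
            raise ValueError("identifier must be non-empty")
        return v

    @model_validator(mode="after")
    def _check(self) -> "InstrumentDefinition":
        if not self.items:
            raise ValueError(f"instrument {self.instrument_id!r} has no items")
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(
                f"instrument {self.instrument_id!r} has duplicate item_id(s): "
                f"{sorted(dupes)}"
            )
        if (self.stratum == "not_applicable") != (self.category == "generic"):
            raise ValueError(
                "stratum must be 'not_applicable' exactly for generic instruments "
                f"(got category={self.category!r}, stratum={self.stratum!r})"
            )
        return self

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def domains(self) -> list[str]:
        """Distinct item domains, in first-appearance order."""
        seen: dict[str, None] = {}
        for it in self.items:
            if it.domain is not None:
                seen.setdefault(it.domain, None)
        return list(seen)


class CrossWalk(BaseModel):
    """Reviewer-asserted item matches between a specific and a generic instrument.

    A specific item may appear in at most one match pair; a generic item may
    cover several specific items (one-to-many, as permitted for the EQ-5D's
    five questions and adopted for both generic instruments).
    """

    specific_id: str
    generic_id: str
    matches: list[tuple[str, str]]

    @field_validator("specific_id", "generic_id")
    @classmethod
    def _strip(cls, v: str) -> str:
        return v.strip()

    @field_validator("matches")
    @classmethod
    def _norm_matches(cls, v):
        out = [(s.strip(), g.strip()) for s, g in v]
        specifics = [s for s, _ in out]
        dupes = {s for s in specifics if specifics.count(s) > 1}
        if dupes:
            raise ValueError(
                f"specific item(s) matched more than once: {sorted(dupes)}"
            )
        return out

    def validate_against(
        self, specific: InstrumentDefinition, generic: InstrumentDefinition
    ) -> None:
        """Raise :class:`ValidationError` unless every referenced item exists."""
        if self.specific_id != specific.instrument_id:
            raise ValidationError(
                f"crosswalk specific_id {self.specific_id!r} does not name "
                f"instrument {specific.instrument_id!r}"
            )
        if self.generic_id != generic.instrument_id:
            raise ValidationError(
                f"crosswalk generic_id {self.generic_id!r} does not name "
                f"instrument {generic.instrument_id!r}"
            )
        spec_ids = set(specific.item_ids)
        gen_ids = set(generic.item_ids)
        for s, g in self.matches:
            if s not in spec_ids:
                raise ValidationError(
                    f"crosswalk references unknown specific item {s!r}"
                )
            if g not in gen_ids:
                raise ValidationError(
                    f"crosswalk references unknown generic item {g!r}"
                )


@dataclass(frozen=True)
class ConfusionSummary:
    """Item-level confusion counts for one specific-vs-generic comparison.

    ``tp``: specific items with a match; ``fn``: specific items without one;
    ``fp``: generic items matched to no specific item; ``tn_mass``: the
    assumed true-negative mass (not a count).  ``tp + fn`` always equals the
    specific instrument's item count.
    """

    tp: int
    fn: int
    fp: int
    tn_mass: float = 0.9
    n_specific_items: int = 0
    n_generic_items: int = 0
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tn_mass < 0:
            raise ValidationError("tn_mass must be non-negative")
        if self.n_specific_items and self.tp + self.fn != self.n_specific_items:
            raise ValidationError("tp + fn must equal the specific item count")
        if self.n_generic_items and self.fp > self.n_generic_items:
            raise ValidationError("fp cannot exceed the generic item count")


def confusion_counts(
    specific: InstrumentDefinition,
    generic: InstrumentDefinition,
    walk: CrossWalk,
    tn_mass: float = 0.9,
) -> ConfusionSummary:
    """Count item-level TP/FN/FP for a generic instrument against a specific one.

    TP counts distinct matched specific items, FN the unmatched specific
    items, FP the distinct generic items appearing in no match pair.  The
    true-negative mass is copied through unchanged.
    """
    if specific.category != "specific":
        raise ValidationError(
            f"{specific.instrument_id!r} is not a specific instrument"
        )
    if generic.category != "generic":
        raise ValidationError(
            f"{generic.instrument_id!r} is not a generic instrument"
        )
    walk.validate_against(specific, generic)
    matched_specific = {s for s, _ in walk.matches}
    matched_generic = {g for _, g in walk.matches}
    tp = len(matched_specific)
    fn = specific.n_items - tp
    fp = generic.n_items - len(matched_generic)
    return ConfusionSummary(
        tp=tp,
        fn=fn,
        fp=fp,
        tn_mass=tn_mass,
        n_specific_items=specific.n_items,
        n_generic_items=generic.n_items,
    )


def flag_complete_overlap(summary: ConfusionSummary) -> ConfusionSummary:
    """Mark a comparison as excluded when it is degenerate (fn=0 and fp=0).

    A generic instrument that completely overlaps a specific one carries no
    information about mismatch in either direction, mirroring the exclusion
    of the UCLA Prostate Cancer Index against the SF-36.
    """
    if summary.fn == 0 and summary.fp == 0:
        return replace(summary, excluded=True, exclusion_reason="complete overlap")
    return summary


# ---------------------------------------------------------------------------
# I/O.  Instrument CSV: one row per item with columns
#   instrument_id,name,category,stratum,item_id,item_label,item_domain
# Instrument JSON: a single object with an "items" array.
# CrossWalk CSV: columns specific_id,generic_id,specific_item_id,generic_item_id.
# ---------------------------------------------------------------------------

_INSTRUMENT_COLUMNS = [
    "instrument_id",
    "name",
    "category",
    "stratum",
    "item_id",
    "item_label",
    "item_domain",
]


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValidationError(f"cannot infer format from {path.name!r}; pass format=")


def load_instrument(
    path: str | Path, format: Optional[Literal["csv", "json"]] = None
) -> InstrumentDefinition:
    """Read an instrument definition from CSV (one row per item) or JSON."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path.name}: invalid JSON ({exc})") from exc
        try:
            return InstrumentDefinition.model_validate(payload)
        except Exception as exc:
            raise ValidationError(f"{path.name}: {exc}") from exc
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _INSTRUMENT_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    if df.empty:
        raise ValidationError(f"{path.name}: no item rows")
    head = df.iloc[0]
    items = [
        Item(
            item_id=row["item_id"],
            label=row["item_label"],
            domain=row.get("item_domain") or None,
        )
        for _, row in df.iterrows()
    ]
    try:
        return InstrumentDefinition(
            instrument_id=head["instrument_id"],
            name=head["name"],
            category=head["category"],
            stratum=head["stratum"],
            items=items,
        )
    except Exception as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc


def save_instrument(
    instrument: InstrumentDefinition,
    path: str | Path,
    format: Optional[Literal["csv", "json"]] = None,
) -> Path:
    """Write an instrument definition; the written file round-trips exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(
            json.dumps(instrument.model_dump(), indent=2, sort_keys=True) + "\n"
        )
        return path
    rows = [
        {
            "instrument_id": instrument.instrument_id,
            "name": instrument.name,
            "category": instrument.category,
            "stratum": instrument.stratum,
            "item_id": it.item_id,
            "item_label": it.label,
            "item_domain": it.domain or "",
        }
        for it in instrument.items
    ]
    pd.DataFrame(rows, columns=_INSTRUMENT_COLUMNS).to_csv(path, index=False)
    return path


def load_crosswalks(path: str | Path) -> list[CrossWalk]:
    """Read crosswalks from CSV; rows are grouped by (specific_id, generic_id)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ["specific_id", "generic_id", "specific_item_id", "generic_item_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    walks = []
    for (sid, gid), grp in df.groupby(["specific_id", "generic_id"], sort=False):
        matches = [
            (row["specific_item_id"], row["generic_item_id"])
            for _, row in grp.iterrows()
            if row["specific_item_id"]  # a blank row records an empty crosswalk
        ]
        try:
            walks.append(CrossWalk(specific_id=sid, generic_id=gid, matches=matches))
        except Exception as exc:
            raise ValidationError(f"{path.name}: {exc}") from exc
    return walks


def save_crosswalks(walks: Sequence[CrossWalk], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for w in walks:
        if not w.matches:
            rows.append(
                {
                    "specific_id": w.specific_id,
                    "generic_id": w.generic_id,
                    "specific_item_id": "",
                    "generic_item_id": "",
                }
            )
        for s, g in w.matches:
            rows.append(
                {
                    "specific_id": w.specific_id,
                    "generic_id": w.generic_id,
                    "specific_item_id": s,
                    "generic_item_id": g,
                }
            )
    pd.DataFrame(
        rows,
        columns=["specific_id", "generic_id", "specific_item_id", "generic_item_id"],
    ).to_csv(path, index=False)
    return path
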