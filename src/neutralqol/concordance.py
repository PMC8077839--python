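"""Three-level concordance between paired specific- and generic-instrument results.

Each study reports, per instrument and time point, a direction of HRQoL
effect (improved / worsened / no change) and whether it was statistically
significant.  A pair of results is classified:

* **strong** — fully aligned: both significant in the same direction, or
  both non-significant (a non-significant result is read as "no change"
  for alignment, whatever direction was recorded);
* **moderate** — same direction, but significant with only one instrument;
* **none** — one instrument shows a significant effect while the other shows
  no change or a significant effect in the opposite direction.

The classification is symmetric in its two arguments and total over every
direction × significance combination.  Studies reporting several time points
get one level per time point; the study's headline level is the first
(earliest) time point's, and the study is flagged *reclassified* when the
level differs across time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from ._util import EmptyInputError, ValidationError, round_half_up_ratio

Direction = Literal["improved", "worsened", "no_change"]
Level = Literal["none", "moderate", "strong"]
ResultStratum = Literal["rare", "non_rare", "symptom_specific"]

LEVELS: tuple[Level, ...] = ("none", "moderate", "strong")


class StudyResult(BaseModel):
    """Direction and significance of one instrument's result at one time point."""

    direction: Direction
    significant: bool

    @model_validator(mode="after")
    def _no_change_not_significant(self) -> "StudyResult":
        if self.direction == "no_change" and self.significant:
            raise ValueError("a 'no_change' result cannot be significant")
        return self


class TimepointPair(BaseModel):
    """Specific- and generic-instrument results at one labelled time point."""

    timepoint: str
    specific: StudyResult
    generic: StudyResult

    @field_validator("timepoint")
    @classmethod
    def _strip(cls, v: str) -> str:
        v = v.strip()
        if not v:
            raise ValueError("timepoint label must be non-empty")
        return v


class ComparisonRecord(BaseModel):
    """One study's paired results over one or more time points."""

    study_id: str
    stratum: ResultStratum
    generic_id: str
    is_clinical_trial: bool = False
    pairs: list[TimepointPair]

    @model_validator(mode="after")
    def _check(self) -> "ComparisonRecord":
        if not self.pairs:
            raise ValueError(f"study {self.study_id!r} has no time points")
        tps = [p.timepoint for p in self.pairs]
        if len(set(tps)) != len(tps):
            raise ValueError(f"study {self.study_id!r} has duplicate time points")
        return self


def classify(specific: StudyResult, generic: StudyResult) -> Level:
    """Classify one pair of results as none / moderate / strong concordance."""
    a, b = specific, generic
    if a.significant and b.significant:
        return "strong" if a.direction == b.direction else "none"
    if not a.significant and not b.significant:
        # both effectively "no change": fully aligned
        return "strong"
    sig, other = (a, b) if a.significant else (b, a)
    return "moderate" if other.direction == sig.direction else "none"


@dataclass(frozen=True)
class RecordClassification:
    study_id: str
    levels: tuple[Level, ...]  # one per time point, in record order
    headline: Level  # level at the first (earliest) time point
    reclassified: bool  # levels differ across time points


def classify_record(record: ComparisonRecord) -> RecordClassification:
    """Classify every time point of a study; flag cross-time reclassification."""
    levels = tuple(classify(p.specific, p.generic) for p in record.pairs)
    return RecordClassification(
        study_id=record.study_id,
        levels=levels,
        headline=levels[0],
        reclassified=len(set(levels)) > 1,
    )


@dataclass(frozen=True)
class CellSummary:
    """Per-level study counts and integer percentages for one table cell."""

    stratum: ResultStratum
    generic_id: str
    n: int
    counts: dict[Level, int]
    percentages: dict[Level, int]
    empty: bool = False


def aggregate(
    records: Iterable[ComparisonRecord],
    stratum: ResultStratum,
    generic_id: str,
) -> CellSummary:
    """Count headline concordance levels in one stratum × generic-instrument cell.

    Percentages are rounded half-up to whole percent, the style used in the
    printed concordance tables.  An empty cell returns an explicit empty
    marker (rendered "–"), never zeros.
    """
    selected = [
        r for r in records if r.stratum == stratum and r.generic_id == generic_id
    ]
    if not selected:
        return CellSummary(
            stratum=stratum,
            generic_id=generic_id,
            n=0,
            counts={lv: 0 for lv in LEVELS},
            percentages={lv: 0 for lv in LEVELS},
            empty=True,
        )
    counts = {lv: 0 for lv in LEVELS}
    for r in selected:
        counts[classify_record(r).headline] += 1
    n = len(selected)
    percentages = {lv: round_half_up_ratio(counts[lv], n) for lv in LEVELS}
    return CellSummary(
        stratum=stratum, generic_id=generic_id, n=n, counts=counts,
        percentages=percentages,
    )


@dataclass(frozen=True)
class TimecourseSummary:
    """Multi-time-point studies: how often HRQoL changed and concordance flipped."""

    stratum: ResultStratum
    generic_id: str
    n_multi_timepoint: int
    n_qol_change: int
    n_reclassified: int
    pct_qol_change: int
    pct_reclassified: int
    empty: bool = False


def _qol_changed(record: ComparisonRecord) -> bool:
    """True when any instrument's direction or significance differs between
    consecutive time points."""
    for prev, cur in zip(record.pairs, record.pairs[1:]):
        for attr in ("specific", "generic"):
            a, b = getattr(prev, attr), getattr(cur, attr)
            if (a.direction, a.significant) != (b.direction, b.significant):
                return True
    return False


def aggregate_timecourse(
    records: Iterable[ComparisonRecord],
    stratum: ResultStratum,
    generic_id: str,
) -> TimecourseSummary:
    """Summarise studies with more than one time point in one cell."""
    multi = [
        r
        for r in records
        if r.stratum == stratum and r.generic_id == generic_id and len(r.pairs) > 1
    ]
    if not multi:
        return TimecourseSummary(
            stratum=stratum, generic_id=generic_id, n_multi_timepoint=0,
            n_qol_change=0, n_reclassified=0, pct_qol_change=0,
            pct_reclassified=0, empty=True,
        )
    n = len(multi)
    n_change = sum(_qol_changed(r) for r in multi)
    n_reclass = sum(classify_record(r).reclassified for r in multi)
    return TimecourseSummary(
        stratum=stratum,
        generic_id=generic_id,
        n_multi_timepoint=n,
        n_qol_change=n_change,
        n_reclassified=n_reclass,
        pct_qol_change=round_half_up_ratio(n_change, n),
        pct_reclassified=round_half_up_ratio(n_reclass, n),
    )


# ---------------------------------------------------------------------------
# Study-results CSV: two rows (instrument_role specific/generic) per study
# per time point, columns study_id,stratum,generic_id,is_clinical_trial,
# timepoint,instrument_role,direction,significant.
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "study_id",
    "stratum",
    "generic_id",
    "is_clinical_trial",
    "timepoint",
    "instrument_role",
    "direction",
    "significant",
]


def save_study_results(
    records: Sequence[ComparisonRecord], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for rec in records:
        for pair in rec.pairs:
            for role, res in (("specific", pair.specific), ("generic", pair.generic)):
                rows.append(
                    {
                        "study_id": rec.study_id,
                        "stratum": rec.stratum,
                        "generic_id": rec.generic_id,
                        "is_clinical_trial": rec.is_clinical_trial,
                        "timepoint": pair.timepoint,
                        "instrument_role": role,
                        "direction": res.direction,
                        "significant": res.significant,
                    }
                )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)
    return path


def load_study_results(path: str | Path) -> list[ComparisonRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"study_id": str, "timepoint": str})
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    records = []
    for (sid, stratum, gid, ict), grp in df.groupby(
        ["study_id", "stratum", "generic_id", "is_clinical_trial"], sort=False
    ):
        pairs = []
        # preserve file order of time points
        for tp in grp["timepoint"].drop_duplicates():
            sub = grp[grp["timepoint"] == tp]
            by_role = {}
            for _, row in sub.iterrows():
                by_role[row["instrument_role"]] = StudyResult(
                    direction=row["direction"], significant=bool(row["significant"])
                )
            if set(by_role) != {"specific", "generic"}:
                raise ValidationError(
                    f"{path.name}: study {sid!r} timepoint {tp!r} must have exactly "
                    "one specific and one generic row"
                )
            pairs.append(
                TimepointPair(
                    timepoint=tp, specific=by_role["specific"],
                    generic=by_role["generic"],
                )
            )
        try:
            records.append(
                ComparisonRecord(
                    study_id=sid, stratum=stratum, generic_id=gid,
                    is_clinical_trial=bool(ict), pairs=pairs,
                )
            )
        except Exception as exc:
            raise ValidationError(f"{path.name}: {exc}") from exc
    return records
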