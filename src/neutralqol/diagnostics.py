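"""Construct-level sensitivity and specificity of a generic HRQoL instrument.

With the specific instrument taken as the surrogate for the ideal construct,
sensitivity is the fraction of its items the generic instrument captures,
``tp / (tp + fn)``.  Specificity needs true negatives — relevant indicators
absent from both instruments — which cannot be counted, because the specific
instrument itself may miss indicators.  A true-negative *fraction* of 0.9
(an arbitrary 10% assumed missing) stands in for them.  Under the default
interpretation this enters as a constant mass of 0.9 item-equivalents:

    specificity = tn_mass / (tn_mass + fp)

which is 1 when the generic instrument adds no unmatched items and falls
quickly for item-rich generic instruments.  Two alternative readings scale
the mass by an instrument's item count; they are selectable, never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from ._util import ConfigError, EmptyInputError, NeutralQolError, ValidationError
from .instruments import ConfusionSummary, CrossWalk, InstrumentDefinition, Stratum
from .instruments import confusion_counts, flag_complete_overlap

TnInterpretation = Literal["constant_mass", "scaled_by_specific", "scaled_by_generic"]

_TN_INTERPRETATIONS = ("constant_mass", "scaled_by_specific", "scaled_by_generic")


class DegenerateInstrumentError(NeutralQolError):
    """Raised when a comparison has no specific items (tp + fn = 0)."""


class ExclusionError(NeutralQolError):
    """Raised in strict mode when a comparison is excluded by rule."""


@dataclass(frozen=True)
class DiagnosticResult:
    """Sensitivity/specificity of one generic instrument vs one specific one."""

    specific_id: str
    generic_id: str
    stratum: Stratum
    tp: int
    fp: int
    fn: int
    tn_mass: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ExcludedComparison:
    """Explicit marker for an excluded comparison; carries no numbers."""

    specific_id: str
    generic_id: str
    reason: str


@dataclass(frozen=True)
class RangeSummary:
    """Extrema of sensitivity/specificity over one stratum × generic instrument."""

    stratum: Stratum
    generic_id: str
    sensitivity_min: float
    sensitivity_max: float
    specificity_min: float
    specificity_max: float
    n_instruments: int


def sensitivity(summary: ConfusionSummary) -> float:
    """Fraction of the specific instrument's items the generic one captures."""
    total = summary.tp + summary.fn
    if total == 0:
        raise DegenerateInstrumentError(
            "sensitivity undefined: the specific instrument has no items"
        )
    return summary.tp / total


def _tn_value(summary: ConfusionSummary, interpretation: str) -> float:
    if interpretation == "constant_mass":
        return summary.tn_mass
    if interpretation == "scaled_by_specific":
        return summary.tn_mass * (summary.n_specific_items or summary.tp + summary.fn)
    if interpretation == "scaled_by_generic":
        if not summary.n_generic_items:
            raise ConfigError(
                "scaled_by_generic needs the generic item count on the summary"
            )
        return summary.tn_mass * summary.n_generic_items
    raise ConfigError(
        f"unknown tn_interpretation {interpretation!r}; "
        f"expected one of {_TN_INTERPRETATIONS}"
    )


def specificity(
    summary: ConfusionSummary,
    tn_interpretation: TnInterpretation = "constant_mass",
) -> float:
    """Specificity under an assumed true-negative mass: tn / (tn + fp)."""
    tn = _tn_value(summary, tn_interpretation)
    denom = tn + summary.fp
    if denom == 0:
        # only reachable with tn_mass = 0 and fp = 0
        return 1.0
    return tn / denom


def diagnose(
    specific: InstrumentDefinition,
    generic: InstrumentDefinition,
    walk: CrossWalk,
    *,
    tn_mass: float = 0.9,
    tn_interpretation: TnInterpretation = "constant_mass",
    exclude_complete_overlap: bool = True,
    strict: bool = False,
) -> DiagnosticResult | ExcludedComparison:
    """Count the crosswalk and assemble sensitivity/specificity for one pair.

    A completely overlapping pair (fn=0 and fp=0) is returned as an
    :class:`ExcludedComparison` marker — never as numbers — unless the
    exclusion rule is switched off; in strict mode it raises instead.
    """
    summary = confusion_counts(specific, generic, walk, tn_mass=tn_mass)
    if exclude_complete_overlap:
        summary = flag_complete_overlap(summary)
    if summary.excluded:
        if strict:
            raise ExclusionError(
                f"comparison {specific.instrument_id} vs {generic.instrument_id} "
                f"excluded: {summary.exclusion_reason}"
            )
        return ExcludedComparison(
            specific_id=specific.instrument_id,
            generic_id=generic.instrument_id,
            reason=summary.exclusion_reason or "excluded",
        )
    return DiagnosticResult(
        specific_id=specific.instrument_id,
        generic_id=generic.instrument_id,
        stratum=specific.stratum,
        tp=summary.tp,
        fp=summary.fp,
        fn=summary.fn,
        tn_mass=summary.tn_mass,
        sensitivity=sensitivity(summary),
        specificity=specificity(summary, tn_interpretation),
    )


def summarize_ranges(
    results: Iterable[DiagnosticResult],
    stratum: Stratum,
    generic_id: str,
) -> RangeSummary:
    """Min/max sensitivity and specificity over one stratum × generic instrument."""
    selected = [
        r for r in results if r.stratum == stratum and r.generic_id == generic_id
    ]
    if not selected:
        raise EmptyInputError(
            f"no diagnostic results for stratum={stratum!r}, generic={generic_id!r}"
        )
    se = [r.sensitivity for r in selected]
    sp = [r.specificity for r in selected]
    return RangeSummary(
        stratum=stratum,
        generic_id=generic_id,
        sensitivity_min=min(se),
        sensitivity_max=max(se),
        specificity_min=min(sp),
        specificity_max=max(sp),
        n_instruments=len(selected),
    )


# ---------------------------------------------------------------------------
# Diagnostic table I/O — also the ingest layout for a supplementary-style
# per-tool table: counts may be omitted when sensitivity/specificity are
# supplied directly.
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "specific_id",
    "generic_id",
    "stratum",
    "tp",
    "fp",
    "fn",
    "sensitivity",
    "specificity",
]


def save_diagnostic_table(
    results: Sequence[DiagnosticResult], path: str | Path, sep: str = ","
) -> Path:
    path = Path(path)
    rows = [
        {
            "specific_id": r.specific_id,
            "generic_id": r.generic_id,
            "stratum": r.stratum,
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False, sep=sep)
    return path


def load_diagnostic_table(
    path: str | Path, tn_mass: float = 0.9, sep: Optional[str] = None
) -> list[DiagnosticResult]:
    """Read a diagnostic table CSV/TSV.

    Rows with tp/fp/fn counts are recomputed from the counts (constant-mass
    specificity); rows without counts must carry sensitivity and specificity
    directly, as a supplementary-style table would.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("specific_id", "generic_id", "stratum"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")
    results = []
    for _, row in df.iterrows():
        has_counts = all(
            c in df.columns and pd.notna(row.get(c)) for c in ("tp", "fp", "fn")
        )
        if has_counts:
            summary = ConfusionSummary(
                tp=int(row["tp"]), fn=int(row["fn"]), fp=int(row["fp"]), tn_mass=tn_mass
            )
            se = sensitivity(summary)
            sp = specificity(summary)
            tp, fp, fn = int(row["tp"]), int(row["fp"]), int(row["fn"])
        else:
            if pd.isna(row.get("sensitivity")) or pd.isna(row.get("specificity")):
                raise ValidationError(
                    f"{path.name}: row for {row['specific_id']!r} has neither "
                    "counts nor direct sensitivity/specificity"
                )
            se = float(row["sensitivity"])
            sp = float(row["specificity"])
            if not (0 <= se <= 1 and 0 <= sp <= 1):
                raise ValidationError(
                    f"{path.name}: sensitivity/specificity out of [0,1] for "
                    f"{row['specific_id']!r}"
                )
            tp = fp = fn = 0
        results.append(
            DiagnosticResult(
                specific_id=str(row["specific_id"]),
                generic_id=str(row["generic_id"]),
                stratum=str(row["stratum"]),
                tp=tp,
                fp=fp,
                fn=fn,
                tn_mass=tn_mass,
                sensitivity=se,
                specificity=sp,
            )
        )
    return results
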