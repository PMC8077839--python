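"""Seeded generators for every input the pipeline consumes.

Nothing in this analysis requires real questionnaire text: the diagnostics
depend only on item counts and match structure, the misclassification model
only on (sensitivity, specificity, prevalence), and the concordance tables
only on direction/significance patterns.  The generators here produce
instrument pairs with a controlled item-overlap fraction, patient cohorts
classified by a (se, sp) instrument, and study-comparison sets drawn from a
specified none/moderate/strong concordance mix — all deterministic under a
seed, and all writing the same CSV dialects the readers consume.

The concordance pattern library is enumerated from the classifier's own
truth table, so a generated label can never drift from the classifier's
semantics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ._util import ConfigError, NeutralQolError, round_half_up
from .concordance import (
    LEVELS,
    ComparisonRecord,
    Level,
    ResultStratum,
    StudyResult,
    TimepointPair,
    classify,
    save_study_results,
)
from .diagnostics import diagnose, save_diagnostic_table
from .instruments import (
    CrossWalk,
    InstrumentDefinition,
    Item,
    save_crosswalks,
    save_instrument,
)
from .misclassification import simulate_study


class InfeasibleSpecError(NeutralQolError):
    """The requested overlap structure cannot be realised."""


class OverlapSpec(BaseModel):
    """Recipe for an instrument pair with a controlled item-overlap fraction."""

    n_specific_items: int = Field(ge=1)
    n_generic_items: int = Field(ge=1)
    match_fraction: float = Field(ge=0.0, le=1.0)
    one_to_many_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0


def gen_instrument_pair(
    spec: OverlapSpec,
    specific_id: str = "SPEC-1",
    generic_id: str = "GEN-1",
    stratum: str = "non_rare",
) -> tuple[InstrumentDefinition, InstrumentDefinition, CrossWalk]:
    """Generate a (specific, generic, crosswalk) triple.

    Exactly ``round(match_fraction * n_specific_items)`` specific items are
    matched.  Each match after the first reuses an already-used generic item
    with probability ``one_to_many_rate``, otherwise consumes a fresh one;
    with reuse disabled, more matches than generic items is infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    n_match = round_half_up(spec.match_fraction * spec.n_specific_items)
    if n_match > spec.n_generic_items and spec.one_to_many_rate == 0.0:
        raise InfeasibleSpecError(
            f"{n_match} matches cannot be covered by {spec.n_generic_items} "
            "generic items without one-to-many reuse"
        )

    specific = InstrumentDefinition(
        instrument_id=specific_id,
        name=f"Synthetic specific instrument {specific_id}",
        category="specific",
        stratum=stratum,
        items=[
            Item(item_id=f"{specific_id}-i{k + 1}", label=f"specific item {k + 1}")
            for k in range(spec.n_specific_items)
        ],
    )
    generic = InstrumentDefinition(
        instrument_id=generic_id,
        name=f"Synthetic generic instrument {generic_id}",
        category="generic",
        stratum="not_applicable",
        items=[
            Item(item_id=f"{generic_id}-i{k + 1}", label=f"generic item {k + 1}")
            for k in range(spec.n_generic_items)
        ],
    )

    matched_specific = rng.choice(
        spec.n_specific_items, size=n_match, replace=False
    )
    generic_pool = list(rng.permutation(spec.n_generic_items))
    used: list[int] = []
    matches: list[tuple[str, str]] = []
    for s_idx in matched_specific:
        reuse = bool(used) and (
            not generic_pool or rng.random() < spec.one_to_many_rate
        )
        g_idx = used[int(rng.integers(len(used)))] if reuse else generic_pool.pop(0)
        if g_idx not in used:
            used.append(g_idx)
        matches.append(
            (specific.item_ids[int(s_idx)], generic.item_ids[int(g_idx)])
        )
    walk = CrossWalk(
        specific_id=specific_id, generic_id=generic_id, matches=matches
    )
    walk.validate_against(specific, generic)
    return specific, generic, walk


def gen_patient_cohort(
    se: float, sp: float, prevalence: float, n_patients: int, seed: int
) -> pd.DataFrame:
    """Patient-level cohort classified by a (se, sp) instrument.

    Shares :func:`~neutralqol.misclassification.simulate_study`'s draw order
    (cohort size, true positives, false positives from a generator seeded the
    same way), so aggregating the returned table reproduces that study draw
    exactly.  Returns columns patient_id, true_poor, classified_poor.
    """
    rng = np.random.default_rng(seed)
    tp, fp, fn, tn = simulate_study(se, sp, prevalence, n_patients, rng)
    true_poor = np.concatenate(
        [np.ones(tp + fn, dtype=bool), np.zeros(fp + tn, dtype=bool)]
    )
    classified = np.concatenate(
        [
            np.ones(tp, dtype=bool),
            np.zeros(fn, dtype=bool),
            np.ones(fp, dtype=bool),
            np.zeros(tn, dtype=bool),
        ]
    )
    order = rng.permutation(n_patients)
    return pd.DataFrame(
        {
            "patient_id": [f"P{k + 1:05d}" for k in range(n_patients)],
            "true_poor": true_poor[order],
            "classified_poor": classified[order],
        }
    )


# ---------------------------------------------------------------------------
# Concordance-mix generator
# ---------------------------------------------------------------------------

_DIRECTIONS_SIG = [
    ("improved", True),
    ("improved", False),
    ("worsened", True),
    ("worsened", False),
    ("no_change", False),
]


def _pattern_library() -> dict[Level, list[tuple[StudyResult, StudyResult]]]:
    """Enumerate all valid result pairs, grouped by the level classify assigns."""
    lib: dict[Level, list[tuple[StudyResult, StudyResult]]] = {
        lv: [] for lv in LEVELS
    }
    for d1, s1 in _DIRECTIONS_SIG:
        for d2, s2 in _DIRECTIONS_SIG:
            a = StudyResult(direction=d1, significant=s1)
            b = StudyResult(direction=d2, significant=s2)
            lib[classify(a, b)].append((a, b))
    return lib


PATTERN_LIBRARY = _pattern_library()


class ConcordanceMix(BaseModel):
    """Recipe for a set of paired study results with a known concordance mix.

    ``allocation='exact'`` assigns per-level counts by largest remainder so a
    mix stated as exact study counts (e.g. 2/11, 6/11, 3/11 with n=11) is
    reproduced exactly; ``'multinomial'`` draws the counts instead.
    Multi-time-point studies are inserted at ``multi_timepoint_fraction``,
    and among those a ``reclassification_rate`` fraction change level at the
    second time point.
    """

    p_none: float = Field(ge=0.0, le=1.0)
    p_moderate: float = Field(ge=0.0, le=1.0)
    p_strong: float = Field(ge=0.0, le=1.0)
    n_studies: int = Field(ge=1)
    multi_timepoint_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    reclassification_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    clinical_trial_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    stratum: ResultStratum = "non_rare"
    generic_id: str = "SF-36"
    allocation: Literal["exact", "multinomial"] = "exact"
    seed: int = 0

    @model_validator(mode="after")
    def _simplex(self) -> "ConcordanceMix":
        total = self.p_none + self.p_moderate + self.p_strong
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"level probabilities must sum to 1 (got {total!r})"
            )
        return self


def _largest_remainder(proportions: list[float], n: int) -> list[int]:
    """Integer counts summing to n, proportional to the given weights."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def gen_study_comparisons(mix: ConcordanceMix) -> list[ComparisonRecord]:
    """Generate comparison records whose headline levels follow the mix."""
    rng = np.random.default_rng(mix.seed)
    if mix.allocation == "exact":
        counts = _largest_remainder(
            [mix.p_none, mix.p_moderate, mix.p_strong], mix.n_studies
        )
    else:
        counts = list(
            rng.multinomial(
                mix.n_studies, [mix.p_none, mix.p_moderate, mix.p_strong]
            )
        )
    labels: list[Level] = []
    for lv, c in zip(LEVELS, counts):
        labels.extend([lv] * c)
    rng.shuffle(labels)  # type: ignore[arg-type]

    n = mix.n_studies
    n_multi = round_half_up(mix.multi_timepoint_fraction * n)
    n_reclass = round_half_up(mix.reclassification_rate * n_multi)
    n_trial = round_half_up(mix.clinical_trial_fraction * n)
    multi_flags = np.zeros(n, dtype=bool)
    multi_flags[:n_multi] = True
    reclass_flags = np.zeros(n, dtype=bool)
    reclass_flags[:n_reclass] = True  # reclassified studies are multi-time-point
    trial_flags = np.zeros(n, dtype=bool)
    trial_flags[rng.choice(n, size=n_trial, replace=False)] = True

    records = []
    for k in range(n):
        level = labels[k]
        pats = PATTERN_LIBRARY[level]
        a, b = pats[int(rng.integers(len(pats)))]
        pairs = [TimepointPair(timepoint="t1", specific=a, generic=b)]
        if multi_flags[k]:
            if reclass_flags[k]:
                other_levels = [lv for lv in LEVELS if lv != level]
                level2: Level = other_levels[int(rng.integers(len(other_levels)))]
            else:
                level2 = level
            pats2 = PATTERN_LIBRARY[level2]
            a2, b2 = pats2[int(rng.integers(len(pats2)))]
            pairs.append(TimepointPair(timepoint="t2", specific=a2, generic=b2))
        records.append(
            ComparisonRecord(
                study_id=f"S{k + 1:04d}",
                stratum=mix.stratum,
                generic_id=mix.generic_id,
                is_clinical_trial=bool(trial_flags[k]),
                pairs=pairs,
            )
        )
    return records


def fixture_suite(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a self-consistent miniature study to disk.

    Two specific instruments (one rare-disease, one symptom-specific), one
    generic instrument, crosswalks, the derived diagnostic table, and a study
    -results file.  Re-running with the same seed is byte-identical; every
    file loads through the corresponding reader.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)

    spec_a, generic, walk_a = gen_instrument_pair(
        OverlapSpec(
            n_specific_items=10,
            n_generic_items=8,
            match_fraction=0.4,
            seed=int(rng_seeds[0]),
        ),
        specific_id="RARE-1",
        generic_id="GEN-36",
        stratum="rare",
    )
    spec_b, _, walk_b = gen_instrument_pair(
        OverlapSpec(
            n_specific_items=12,
            n_generic_items=8,
            match_fraction=0.25,
            seed=int(rng_seeds[1]),
        ),
        specific_id="SYMP-1",
        generic_id="GEN-36",
        stratum="symptom_specific",
    )

    results = [
        diagnose(spec_a, generic, walk_a),
        diagnose(spec_b, generic, walk_b),
    ]
    records = gen_study_comparisons(
        ConcordanceMix(
            p_none=0.3,
            p_moderate=0.4,
            p_strong=0.3,
            n_studies=20,
            multi_timepoint_fraction=0.5,
            reclassification_rate=0.2,
            clinical_trial_fraction=0.6,
            stratum="non_rare",
            generic_id="GEN-36",
            seed=int(rng_seeds[2]),
        )
    )

    paths = {
        "instrument_rare": save_instrument(spec_a, outdir / "instrument_rare.csv"),
        "instrument_symptom": save_instrument(
            spec_b, outdir / "instrument_symptom.csv"
        ),
        "instrument_generic": save_instrument(
            generic, outdir / "instrument_generic.json"
        ),
        "crosswalks": save_crosswalks(
            [walk_a, walk_b], outdir / "crosswalks.csv"
        ),
        "diagnostic_table": save_diagnostic_table(
            [r for r in results if not hasattr(r, "reason")],
            outdir / "diagnostic_table.csv",
        ),
        "study_results": save_study_results(
            records, outdir / "study_results.csv"
        ),
    }
    return paths
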