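"""End-to-end pipeline driver and report rendering.

One validated configuration drives the whole analysis: overlap diagnostics
for every specific-vs-generic crosswalk, misclassification simulation for
every diagnostic row at each prevalence, the threshold census, and the two
concordance tables.  All constants the analysis rests on — the assumed
true-negative fraction (0.9), the number of simulated studies (1000), the
prevalences of poor HRQoL (20, 50, 80%) — live here as configuration
defaults, never inside stage logic.

Reports are TSV; a JSON manifest records the configuration, seed and package
version so every number in every report is recomputable from the manifest
plus the inputs alone.  Logging goes to standard error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from ._util import round_half_up_ratio
from .concordance import (
    LEVELS,
    aggregate,
    aggregate_timecourse,
    load_study_results,
)
from .diagnostics import (
    DiagnosticResult,
    TnInterpretation,
    diagnose,
    load_diagnostic_table,
    save_diagnostic_table,
)
from .instruments import load_crosswalks, load_instrument
from .misclassification import (
    PercentileSet,
    SimulationConfig,
    derive_instrument_seed,
    export_panels,
    run_misclassification,
    threshold_census,
)

logger = logging.getLogger("neutralqol")

#: census rows reported by default: (metric, comparator, threshold)
DEFAULT_CENSUS = (
    ("fdr_median", "gt", 0.5),
    ("fdr_median", "gt", 0.75),
    ("fdr_median", "lt", 0.5),
    ("for_median", "gt", 0.5),
    ("for_median", "gt", 0.75),
    ("for_median", "lt", 0.5),
)


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    tn_interpretation: TnInterpretation = "constant_mass"
    tn_fraction: float = Field(default=0.9, ge=0.0)
    prevalences: list[float] = Field(default=[0.2, 0.5, 0.8])
    n_studies: int = Field(default=1000, ge=1)
    n_patients: int = Field(default=100, ge=1)
    percentile_set: PercentileSet = "p5_p95"
    seed: int = 0

    instrument_files: list[Path] = Field(default_factory=list)
    crosswalk_file: Optional[Path] = None
    diagnostic_table: Optional[Path] = None
    study_results: Optional[Path] = None
    output_dir: Path = Path("results")

    @field_validator("prevalences")
    @classmethod
    def _open_interval(cls, v: list[float]) -> list[float]:
        for p in v:
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"prevalence must lie strictly between 0 and 1, got {p}"
                )
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


@dataclass(frozen=True)
class RunResult:
    """Paths of the report files one pipeline run produced."""

    diagnostic_table: Path
    panels: Path
    census: Path
    concordance_levels: Path
    concordance_timecourse: Path
    manifest: Path


def format_cell(count: int, total: int) -> str:
    """Render one table cell: ``"3 (27%)"``, or ``"–"`` for an empty cell."""
    if total == 0:
        return "–"
    return f"{count} ({round_half_up_ratio(count, total)}%)"


def render_concordance_table(records, strata, generic_ids) -> pd.DataFrame:
    """Level-by-cell table of ``count (percent)`` strings, empty cells as "–"."""
    rows = []
    for level in LEVELS:
        row: dict[str, str] = {"level": level}
        for stratum in strata:
            for gid in generic_ids:
                cell = aggregate(records, stratum, gid)
                row[f"{stratum}:{gid}"] = (
                    "–" if cell.empty else format_cell(cell.counts[level], cell.n)
                )
        rows.append(row)
    return pd.DataFrame(rows)


def render_timecourse_table(records, strata, generic_ids) -> pd.DataFrame:
    rows = []
    for stratum in strata:
        for gid in generic_ids:
            tc = aggregate_timecourse(records, stratum, gid)
            rows.append(
                {
                    "stratum": stratum,
                    "generic_id": gid,
                    "n_multi_timepoint": tc.n_multi_timepoint,
                    "qol_change": "–"
                    if tc.empty
                    else format_cell(tc.n_qol_change, tc.n_multi_timepoint),
                    "concordance_change": "–"
                    if tc.empty
                    else (
                        f"{tc.n_reclassified}/{tc.n_multi_timepoint} "
                        f"({tc.pct_reclassified}%)"
                    ),
                }
            )
    return pd.DataFrame(rows)


def _load_diagnostics(config: RunConfig) -> list[DiagnosticResult]:
    if config.diagnostic_table is not None:
        logger.info("loading diagnostic table %s", config.diagnostic_table)
        return load_diagnostic_table(
            config.diagnostic_table, tn_mass=config.tn_fraction
        )
    instruments = {}
    for path in config.instrument_files:
        inst = load_instrument(path)
        instruments[inst.instrument_id] = inst
    logger.info("loaded %d instruments", len(instruments))
    if config.crosswalk_file is None:
        return []
    results = []
    for walk in load_crosswalks(config.crosswalk_file):
        res = diagnose(
            instruments[walk.specific_id],
            instruments[walk.generic_id],
            walk,
            tn_mass=config.tn_fraction,
            tn_interpretation=config.tn_interpretation,
        )
        if hasattr(res, "reason"):
            logger.info(
                "comparison %s vs %s excluded: %s",
                walk.specific_id, walk.generic_id, res.reason,
            )
        else:
            results.append(res)
    return results


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute diagnose → simulate → census → concord and write all reports."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    diagnostics = _load_diagnostics(config)
    logger.info("diagnostics: %d comparisons", len(diagnostics))
    diag_path = save_diagnostic_table(
        diagnostics, outdir / "diagnostic_table.tsv", sep="\t"
    )

    results_by_prevalence = {}
    for prevalence in config.prevalences:
        per_instrument = {}
        for idx, d in enumerate(diagnostics):
            sim = SimulationConfig(
                n_studies=config.n_studies,
                n_patients=config.n_patients,
                prevalence=prevalence,
                seed=derive_instrument_seed(config.seed, idx),
                percentile_set=config.percentile_set,
            )
            per_instrument[f"{d.specific_id}|{d.generic_id}"] = run_misclassification(
                d.sensitivity, d.specificity, sim
            )
        results_by_prevalence[prevalence] = per_instrument
        logger.info(
            "simulated %d instruments at prevalence %.2f", len(per_instrument),
            prevalence,
        )

    panels = export_panels(results_by_prevalence)
    panels_path = outdir / "misclassification_panels.tsv"
    panels.to_csv(panels_path, sep="\t", index=False)

    census_rows = []
    for prevalence, per_instrument in results_by_prevalence.items():
        if not per_instrument:
            continue
        for metric, comparator, threshold in DEFAULT_CENSUS:
            census_rows.append(
                {
                    "prevalence": prevalence,
                    "metric": metric,
                    "comparator": comparator,
                    "threshold": threshold,
                    "count": threshold_census(
                        per_instrument, metric, threshold, comparator
                    ),
                    "total": len(per_instrument),
                }
            )
    census_path = outdir / "census.tsv"
    pd.DataFrame(
        census_rows,
        columns=["prevalence", "metric", "comparator", "threshold", "count", "total"],
    ).to_csv(census_path, sep="\t", index=False)

    if config.study_results is not None:
        records = load_study_results(config.study_results)
        logger.info("concordance: %d study records", len(records))
        strata = sorted({r.stratum for r in records})
        gids = sorted({r.generic_id for r in records})
    else:
        records, strata, gids = [], [], []
    levels_path = outdir / "concordance_levels.tsv"
    render_concordance_table(records, strata, gids).to_csv(
        levels_path, sep="\t", index=False
    )
    timecourse_path = outdir / "concordance_timecourse.tsv"
    render_timecourse_table(records, strata, gids).to_csv(
        timecourse_path, sep="\t", index=False
    )

    manifest = {
        "package": "neutralqol",
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "n_diagnostics": len(diagnostics),
        "n_study_records": len(records),
        "reports": {
            "diagnostic_table": diag_path.name,
            "panels": panels_path.name,
            "census": census_path.name,
            "concordance_levels": levels_path.name,
            "concordance_timecourse": timecourse_path.name,
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote reports to %s", outdir)

    return RunResult(
        diagnostic_table=diag_path,
        panels=panels_path,
        census=census_path,
        concordance_levels=levels_path,
        concordance_timecourse=timecourse_path,
        manifest=manifest_path,
    )
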