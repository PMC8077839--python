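"""Monte-Carlo simulation of patient-level misclassification.

A generic instrument with construct-level sensitivity ``se`` and specificity
``sp`` is applied to cohorts in which a fraction ``p`` of patients truly have
poor HRQoL.  Each simulated study draws the number of truly-poor patients
``D ~ Binomial(n, p)``, then classifies: ``tp ~ Binomial(D, se)`` and
``fp ~ Binomial(n - D, 1 - sp)``, with ``fn = D - tp`` and ``tn = n - D - fp``.

Misclassification is summarised per study by the false-discovery proportion
``fp / (fp + tp)`` (among patients flagged poor, the fraction not truly poor)
and the false-omission proportion ``fn / (fn + tn)`` (among patients not
flagged, the fraction truly poor).  Both depend strongly on prevalence —
the discovery error falls and the omission error rises as ``p`` grows —
unlike ``1 - sp`` and ``1 - se`` themselves.  Across many studies the
median and a percentile prediction band are reported; their large-cohort
limits have the closed forms in :func:`analytic_fdr` / :func:`analytic_for`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from ._util import ConfigError, EmptyInputError, NeutralQolError

PercentileSet = Literal["p5_p95", "p2.5_p97.5"]

_PERCENTILES: dict[str, tuple[float, float]] = {
    "p5_p95": (5.0, 95.0),
    "p2.5_p97.5": (2.5, 97.5),
}


class DegenerateSimulationError(NeutralQolError):
    """Every simulated draw left the requested proportion undefined."""


class SimulationConfig(BaseModel):
    """Study-level simulation settings.

    1000 studies per condition and prevalences of poor HRQoL of 20, 50 and
    80% are the reference conditions; the per-study cohort size is not fixed
    by them and defaults to 100 patients.  ``percentile_set`` chooses between
    the 5th/95th percentile band used for reporting and a 2.5/97.5 band.
    """

    n_studies: int = Field(default=1000, ge=1)
    n_patients: int = Field(default=100, ge=1)
    prevalence: float
    seed: int = 0
    percentile_set: PercentileSet = "p5_p95"

    @field_validator("prevalence")
    @classmethod
    def _open_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        return v


@dataclass(frozen=True)
class MisclassificationResult:
    """Per-study misclassification draws and their percentile summary."""

    se: float
    sp: float
    config: SimulationConfig
    fdr_draws: np.ndarray
    for_draws: np.ndarray
    fdr_median: float
    fdr_lo: float
    fdr_hi: float
    for_median: float
    for_lo: float
    for_hi: float
    n_undefined_fdr: int
    n_undefined_for: int


def simulate_study(
    se: float,
    sp: float,
    prevalence: float,
    n_patients: int,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Draw one study's patient-level confusion counts (tp, fp, fn, tn)."""
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    d = int(rng.binomial(n_patients, prevalence))
    tp = int(rng.binomial(d, se))
    fp = int(rng.binomial(n_patients - d, 1.0 - sp))
    fn = d - tp
    tn = n_patients - d - fp
    return tp, fp, fn, tn


def false_discovery_proportion(tp: int, fp: int) -> Optional[float]:
    """fp / (fp + tp); None when the study flagged nobody as poor."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp
    if total == 0:
        return None
    return fp / total


def false_omission_proportion(fn: int, tn: int) -> Optional[float]:
    """fn / (fn + tn); None when the study flagged everybody as poor."""
    if fn < 0 or tn < 0:
        raise ValueError("counts must be non-negative")
    total = fn + tn
    if total == 0:
        return None
    return fn / total


def analytic_fdr(se: float, sp: float, prevalence: float) -> Optional[float]:
    """Large-cohort false-discovery proportion: (1-sp)(1-p) / ((1-sp)(1-p) + se·p)."""
    num = (1.0 - sp) * (1.0 - prevalence)
    denom = num + se * prevalence
    if denom == 0.0:
        return None
    return num / denom


def analytic_for(se: float, sp: float, prevalence: float) -> Optional[float]:
    """Large-cohort false-omission proportion: (1-se)p / ((1-se)p + sp(1-p))."""
    num = (1.0 - se) * prevalence
    denom = num + sp * (1.0 - prevalence)
    if denom == 0.0:
        return None
    return num / denom


def run_misclassification(
    se: float, sp: float, config: SimulationConfig
) -> MisclassificationResult:
    """Simulate ``config.n_studies`` studies and summarise both proportions.

    The three binomial stages are drawn vectorised over studies from a single
    generator seeded with ``config.seed`` (stage order: cohort sizes, then
    true-positive counts, then false-positive counts), so results are
    bit-reproducible for a given configuration.  Undefined draws — studies
    with no flagged patients (for the discovery proportion) or with everyone
    flagged (for the omission proportion) — are excluded from the percentiles
    and counted.
    """
    rng = np.random.default_rng(config.seed)
    n, ns = config.n_patients, config.n_studies
    d = rng.binomial(n, config.prevalence, size=ns)
    tp = rng.binomial(d, se)
    fp = rng.binomial(n - d, 1.0 - sp)
    fn = d - tp
    tn = n - d - fp

    lo_q, hi_q = _PERCENTILES[config.percentile_set]

    def _summary(num: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, float, float, float, int]:
        denom = num + other
        defined = denom > 0
        draws = num[defined] / denom[defined]
        n_undef = int(ns - defined.sum())
        if draws.size == 0:
            raise DegenerateSimulationError(
                "every simulated study left the proportion undefined"
            )
        lo, med, hi = np.percentile(draws, [lo_q, 50.0, hi_q])
        return draws, float(med), float(lo), float(hi), n_undef

    fdr_draws, fdr_med, fdr_lo, fdr_hi, n_undef_fdr = _summary(fp, tp)
    for_draws, for_med, for_lo, for_hi, n_undef_for = _summary(fn, tn)

    return MisclassificationResult(
        se=se,
        sp=sp,
        config=config,
        fdr_draws=fdr_draws,
        for_draws=for_draws,
        fdr_median=fdr_med,
        fdr_lo=fdr_lo,
        fdr_hi=fdr_hi,
        for_median=for_med,
        for_lo=for_lo,
        for_hi=for_hi,
        n_undefined_fdr=n_undef_fdr,
        n_undefined_for=n_undef_for,
    )


def derive_instrument_seed(root_seed: int, instrument_index: int) -> int:
    """Deterministic per-instrument child seed, independent of iteration order."""
    ss = np.random.SeedSequence([int(root_seed), int(instrument_index)])
    return int(ss.generate_state(1)[0] % (2**31))


Metric = Literal["fdr_median", "for_median"]
Comparator = Literal["gt", "lt"]


def threshold_census(
    results: Mapping[str, MisclassificationResult] | Sequence[MisclassificationResult],
    metric: Metric,
    threshold: float,
    comparator: Comparator,
) -> int:
    """Count instruments whose median proportion is above/below a threshold."""
    if metric not in ("fdr_median", "for_median"):
        raise ConfigError(f"unknown metric {metric!r}")
    if comparator not in ("gt", "lt"):
        raise ConfigError(f"unknown comparator {comparator!r}")
    values = (
        [getattr(r, metric) for r in results.values()]
        if isinstance(results, Mapping)
        else [getattr(r, metric) for r in results]
    )
    if not values:
        raise EmptyInputError("threshold census over an empty result collection")
    if comparator == "gt":
        return sum(v > threshold for v in values)
    return sum(v < threshold for v in values)


def export_panels(
    results_by_prevalence: Mapping[float, Mapping[str, MisclassificationResult]],
) -> pd.DataFrame:
    """Long-format table behind the nine-panel misclassification figures.

    One row per (prevalence, point, instrument) with the false-negative
    proportion (``fnr``, x-axis) and false-positive proportion (``fpr``,
    y-axis) at the lower percentile, the median, and the upper percentile.
    """
    rows = []
    for prevalence in sorted(results_by_prevalence):
        for instrument, r in results_by_prevalence[prevalence].items():
            for point, fnr, fpr in (
                ("lo", r.for_lo, r.fdr_lo),
                ("median", r.for_median, r.fdr_median),
                ("hi", r.for_hi, r.fdr_hi),
            ):
                rows.append(
                    {
                        "prevalence": prevalence,
                        "point": point,
                        "instrument": instrument,
                        "fnr": fnr,
                        "fpr": fpr,
                    }
                )
    return pd.DataFrame(rows, columns=["prevalence", "point", "instrument", "fnr", "fpr"])
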