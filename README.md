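# neutralqol

How much does a generic health-related quality-of-life (HRQoL) instrument —
the SF-36 or EQ-5D — miss when it is used in a disease where a
disease-specific instrument exists? `neutralqol` treats the specific
instrument as the closest available surrogate for an ideal, exhaustive item
list and quantifies the generic instrument against it in three steps:

1. **Item-overlap diagnostics.** From a reviewer-asserted item crosswalk,
   construct-level sensitivity and specificity:

   ```
   se = tp / (tp + fn)          tp: specific items matched,  fn: unmatched
   sp = 0.9 / (0.9 + fp)        fp: generic items matched to nothing
   ```

   where 0.9 is an assumed true-negative mass (the specific instrument
   itself is allowed to miss 10% of the construct). Comparisons that
   overlap completely are excluded as degenerate.

2. **Misclassification simulation.** Patients in simulated study cohorts
   (default: 1000 studies × 100 patients) are classified by an instrument
   with that (se, sp) at a given prevalence *p* of poor HRQoL
   (`D ~ Bin(n, p)`, `tp* ~ Bin(D, se)`, `fp* ~ Bin(n−D, 1−sp)`). Each
   study yields a false-discovery proportion `fp*/(fp*+tp*)` and a
   false-omission proportion `fn*/(fn*+tn*)`; medians with 5th–95th
   percentile prediction bands are reported at p = 0.2, 0.5, 0.8, plus a
   census of instruments beyond chosen thresholds.

3. **Concordance classification.** Paired study results (direction +
   significance per instrument per time point) are classified
   none / moderate / strong, aggregated into tables by disease stratum
   (rare, non-rare, symptom-specific), with reclassification across time
   points tracked separately.

A seeded synthetic-data module generates every input the pipeline consumes
(instrument pairs with a controlled overlap fraction, patient cohorts,
study sets with a known concordance mix), so the whole analysis is testable
without any external data. See `docs/methods.md` for the model details and
design decisions.

## Worked example

```python
from neutralqol import (OverlapSpec, SimulationConfig, gen_instrument_pair,
                        diagnose, run_misclassification, analytic_fdr)

spec, gen, walk = gen_instrument_pair(
    OverlapSpec(n_specific_items=10, n_generic_items=8,
                match_fraction=0.4, seed=1))
d = diagnose(spec, gen, walk)
print(f"sensitivity {d.sensitivity:.2f}, specificity {d.specificity:.3f}")

r = run_misclassification(
    d.sensitivity, d.specificity,
    SimulationConfig(prevalence=0.5, seed=1))
print(f"FDR median {r.fdr_median:.2f} "
      f"[{r.fdr_lo:.2f}, {r.fdr_hi:.2f}]  "
      f"analytic {analytic_fdr(d.sensitivity, d.specificity, 0.5):.2f}")
```

prints

```
sensitivity 0.40, specificity 0.184
FDR median 0.67 [0.58, 0.77]  analytic 0.67
```

A generic instrument that captures 4 of 10 specific items while leaving 4
of its own 8 items unmatched has construct-level sensitivity 40% and
specificity 18%; used at 50% prevalence of poor HRQoL, about two-thirds of
the patients it flags as having poor HRQoL are not truly poor, in agreement
with the closed-form large-cohort limit.

## The analysis

Numbered drivers under `analysis/` run the full pipeline on generated
inputs and write their tables under `results/`:

```
python analysis/01_generate_inputs.py --seed 1     # instruments, crosswalks, study results
python analysis/02_overlap_diagnostics.py          # diagnostic_table.tsv + range summaries
python analysis/03_misclassification.py --seed 1   # misclassification_panels.tsv, census.tsv
python analysis/04_concordance.py                  # concordance_levels.tsv, _timecourse.tsv
```

`neutralqol.pipeline.run_pipeline(RunConfig(...))` performs the same chain
in one call and writes a JSON manifest from which every reported number is
recomputable. A published-style per-tool sensitivity/specificity table can
be substituted for the generated diagnostics via
`load_diagnostic_table` (columns
`specific_id,generic_id,stratum[,tp,fp,fn][,sensitivity,specificity]`).

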