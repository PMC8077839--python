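# Methods

## The problem

Health-related quality of life (HRQoL) is measured through instruments —
questionnaires whose items operationalise the construct. Generic instruments
(SF-36, EQ-5D) are used across all diseases, which makes them convenient for
health-technology assessment but potentially blind to what matters in a
particular disease. Treating a disease- or condition-specific instrument as
the closest available surrogate for an ideal, exhaustive ("neutral") item
list, this package asks three questions:

1. **Coverage.** How much of the specific instrument's content does the
   generic instrument capture, expressed as a construct-level sensitivity
   and specificity?
2. **Consequence.** If a generic instrument with that sensitivity and
   specificity is used to label patients as having poor HRQoL, how badly are
   patients misclassified at realistic prevalences of poor HRQoL?
3. **Concordance.** When a study reports results from both instruments, do
   their directions and significance agree?

## Construct-level diagnostics

Given a reviewer-asserted item crosswalk between a specific instrument
(`n_s` items) and a generic one (`n_g` items):

- **tp** — distinct specific items with a match,
- **fn** — specific items without a match (`tp + fn = n_s` always),
- **fp** — distinct generic items matched to nothing (`fp ≤ n_g`).

One generic item may cover several specific items (explicitly allowed for
the EQ-5D's five questions and adopted symmetrically for both generic
instruments); matching is at item level, with domains carried as metadata
only. Identifiers are compared exactly after whitespace trimming — semantic
matching of item wordings is a human task and out of scope.

`sensitivity = tp / (tp + fn)`. True negatives — relevant indicators absent
from both instruments — cannot be counted, because the specific instrument
itself may be incomplete. A true-negative *fraction* of 0.9 (10% of the
construct arbitrarily assumed missing) stands in for them. The default
operationalisation is a constant mass of 0.9 item-equivalents:

`specificity = 0.9 / (0.9 + fp)`

This is the simplest reading that is computable from observed counts alone,
gives specificity 1 exactly when the generic instrument adds nothing
unmatched, and collapses toward 0 for item-rich generic instruments — the
qualitative pattern seen when a 36-item generic instrument is compared with
short specific questionnaires. Two alternatives are implemented behind
`tn_interpretation` and never silently mixed: `scaled_by_specific`
(`tn = 0.9 · n_s`) and `scaled_by_generic` (`tn = 0.9 · n_g`). No single
interpretation can reproduce every published per-tool value (specificities
of both 0% and 100% appear in that literature), so the choice is exposed
rather than guessed; the constant-mass default is this package's own design
decision.

A comparison in which the two instruments overlap completely (`fn = 0` and
`fp = 0`) is degenerate and is excluded with an explicit marker rather than
reported as sensitivity = specificity = 1; the rule is togglable. Stratum
labels (rare disease: affecting < 1 in 2000 of the population; non-rare;
symptom-specific) are user-asserted metadata, never computed. Reported
percentages are rounded half-up to whole percent at the reporting layer
only; internal values keep full precision.

## Misclassification model

A study cohort of `n` patients with prevalence `p` of truly poor HRQoL,
classified by an instrument with sensitivity `se` and specificity `sp`, is
drawn in two binomial stages:

```
D   ~ Binomial(n, p)          truly-poor patients
tp* ~ Binomial(D, se)         detected
fp* ~ Binomial(n − D, 1 − sp) falsely flagged
fn* = D − tp*,  tn* = n − D − fp*
```

Each study is summarised by the **false-discovery proportion**
`fp*/(fp*+tp*)` (among patients flagged poor, the fraction not truly poor)
and the **false-omission proportion** `fn*/(fn*+tn*)` (among patients not
flagged, the fraction truly poor). These, not `1−sp` and `1−se`, are the
quantities that depend on prevalence — the discovery error falls and the
omission error rises as `p` grows — which is exactly the prevalence
dependence the analysis is designed to expose. Draws in which a proportion
is undefined (no patients flagged, or none unflagged) are excluded from the
summary and counted rather than imputed, since imputing 0 or 1 would bias
medians at extreme prevalence.

Across `n_studies` independent studies the median and a percentile
prediction band are reported. Defaults: 1000 studies; prevalences 0.20,
0.50, 0.80; 5th/95th percentile band (a 2.5/97.5 band is selectable). The
per-study cohort size is a free parameter of the model with no canonical
value; the default is 100 patients, a typical HRQoL-study scale, and the
large-cohort limits have closed forms used as oracles:

```
FDR∞ = (1−sp)(1−p) / [(1−sp)(1−p) + se·p]
FOR∞ = (1−se)p / [(1−se)p + sp(1−p)]
```

The sampler is drawn vectorised over studies from one seeded NumPy
generator (stage order: cohort sizes, detected counts, falsely-flagged
counts), so a configuration is bit-reproducible. Per-instrument seeds are
derived from the root seed and the instrument's index via `SeedSequence`,
making census results independent of iteration order. The threshold census
counts instruments whose median proportion exceeds or falls below a cut-off
(e.g. median false-discovery proportion > 0.75 at p = 0.5); the panel
export is the long-format table behind the nine-panel (three prevalences ×
three percentile points) misclassification figures.

## Concordance classification

Each study contributes, per instrument and time point, a direction
(improved / worsened / no change) and a significance flag; a "no change"
result cannot be significant. A pair is classified:

- **strong** — both significant in the same direction, or both
  non-significant (a non-significant result is read as "no change"
  for alignment, regardless of recorded direction — the package's
  resolution of a case the three published rules do not pin down);
- **moderate** — same direction, significant with exactly one instrument;
- **none** — one significant result against no change, or two significant
  results in opposite directions.

The rule is total and symmetric over every direction × significance
combination. Multi-time-point studies are classified per time point; the
study's headline level is the first time point's (the published tables
report one level per study plus a separate reclassification flag without
saying which time point anchors the level — the choice is isolated in one
function), and the study is *reclassified* when levels differ over time.
"QoL change" is operationalised as any instrument's direction or
significance differing between consecutive time points. Cell percentages
are rounded half-up; empty cells render as "–". Inputs must already be
reduced to one direction/significance per instrument per time point —
collapsing multi-subscale reports is upstream, human work.

## Synthetic data

Every pipeline input can be generated, because no stage depends on item
wordings — only on counts, match structure, (se, sp, p), and
direction/significance patterns:

- `gen_instrument_pair` builds an instrument pair plus crosswalk with an
  exact match fraction (`round(match_fraction · n_s)` specific items
  matched) and a controllable one-to-many reuse rate; infeasible requests
  (more matches than generic items with reuse disabled) are rejected.
- `gen_patient_cohort` produces a patient-level table sharing the study
  sampler's draw order, so aggregating it reproduces the corresponding
  study draw exactly.
- `gen_study_comparisons` draws study records from a stated
  none/moderate/strong mix. Patterns come from a library enumerated from
  the classifier's own truth table, so generated labels cannot drift from
  the classifier's semantics. Per-level counts are allocated by largest
  remainder by default (`allocation="exact"`), so a mix stated as study
  counts (2/11, 6/11, 3/11) is reproduced exactly; multinomial draws are
  available when sampling variability is wanted. Multi-time-point records,
  their reclassification rate, and the clinical-trial fraction are exact in
  the same way.
- `fixture_suite` writes a self-consistent mini-study to disk,
  byte-identical under a fixed seed.

What the generators do **not** emulate: real item semantics and reviewers'
matching judgement, correlation between an instrument pair's overlap and the
concordance of its study results, within-patient longitudinal correlation,
and continuous HRQoL scores (the misclassification construct is binary).
Passing tests therefore demonstrate the arithmetic, the sampling model, and
the classification rules — not the validity of any particular published
crosswalk.

## Numerical and design choices

- Percentages: half-up rounding in exact rational arithmetic
  (`Fraction`), so 54.5% → 55% regardless of float representation.
- Percentiles: NumPy's default linear interpolation.
- Degenerate inputs: an instrument must have ≥ 1 item; a comparison with no
  specific items raises rather than returning NaN; a simulation whose draws
  are all undefined raises rather than returning an empty summary.
- Seeds: one root seed per run; all derived seeds stay below 2³¹.
- Problem sizes in tests and the acceptance script — 400–1000 simulated
  studies, cohorts of 100 (10 000 where the analytic limit is the oracle),
  10⁵ draws for the exact-enumeration check at cohort size ≤ 5 — were
  chosen so the closed-form comparisons resolve well inside Monte-Carlo
  noise while the whole suite runs in seconds.

## Known limitations

- The published per-tool sensitivity/specificity values cannot be
  regenerated from first principles here: they require the original 163
  instrument descriptions and the reviewers' matching judgement. The
  ingest layout (`load_diagnostic_table`) accepts such a table when one is
  available.
- The constant-mass specificity is one defensible reading of "true-negative
  fraction 0.9"; published per-tool specificities suggest the original
  arithmetic may have varied per comparison, and no attempt is made to
  reverse-engineer it.
- With the per-study cohort size unstated in the source analysis, per-tool
  percentile bounds are reproducible only up to that choice; medians are
  anchored by the analytic limit.
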