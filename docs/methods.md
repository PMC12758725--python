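# Methods

## Model

The package costs hospital labour for the acute phase of aneurysmal
subarachnoid haemorrhage (aSAH): roughly 14 days from admission to
discharge, with day 0 the admission-and-operation day.  Cost is assigned
by time-driven activity-based costing: each care activity consumes
`minutes × headcount` of one profession's time, priced at that
profession's hourly capacity cost rate.  No drug, equipment or
consumable costs are modelled — the comparison is labour only, and no
discounting or QALY weighting applies over a two-week horizon.

Eight strata are costed: surgical modality (endovascular coiling or
open clipping) × clazosentan arm × symptomatic-vasospasm (sVSP) status.
Clazosentan is modelled purely through its effect on care intensity
(shorter daily examinations, less observation and drug preparation) and
on the probability of vasospasm; the control arm receives conventional
management with intra-arterial fasudil rescue if vasospasm occurs.

### Care-process map

The packaged process map has three phases:

- **Day 0** — initial examination (physician 90 min), nursing
  assistance (120), imaging work-up (90), the operation (coiling
  180 min or clipping 360 min, 3 physicians + 2 assisting nurses),
  post-treatment examination, observation, X-ray/CT, and insertion of a
  spinal drain and central venous catheter with nursing assistance and
  preparation.
- **Smooth recovery** (days 1–14, or 1–6 if vasospasm intervenes) —
  daily physician examination (5 min with clazosentan / 15 without),
  daily nursing observation (15/30), drug preparation (30/90), drain
  checks (60), a 7-day blood-test series, scheduled imaging (MRI days
  1/7/14, X-ray/CT days 7/14, echo + trunk CT and cerebral angiography
  day 7) and, after coiling only, a day-7 DSA.
- **Vasospasm rescue** (days 7–14 when sVSP occurs) — daily physician
  examination (60), daily intra-arterial fasudil infusion (90 min × 2
  physicians, with 2 assisting and 2 preparing nurses), intrathecal
  administration, DSA on days 7 and 14 after coiling, intensive nursing
  (observation 60, drug preparations, drain checks, neurological care,
  puncture-site compression) and daily cerebral angiography plus
  scheduled MRI/CT/echo.

Activity times carry triangular distributions.  Where only a most-likely
value was elicited, the default rule sets `min = mode/2` and
`max = 2 × mode`; procedure rows with their own elicited bounds (e.g.
drain/catheter insertion 45 (15, 60), rescue-phase DSA and angiography
90 (45, 100)) keep them.  Day schedules are data, not code: every rule
(daily-over-window, explicit days, first-n-days, day 0) lives in the
packaged YAML and can be overridden by user configs.

Three no-clazosentan rows are encoded as *substitution pairs*: the
clazosentan variant is tagged `claz_plus_only` and its longer control
sibling `claz_minus_only`, so exactly one member of each pair appears
in any expansion.  The smooth-phase drug-preparation pair (30 vs
90 min) mirrors the rescue-phase pair; the 90-minute control value is
required to reconcile the published nurse cost differences (37,518.29
and 33,230.49 yen) and is the one schedule element not printed as its
own process-map row.

### Wages

Hourly rates come from the national Basic Survey on Wage Structure:
mean rates 5,924.9 (physician), 2,143.9 (nurse) and 2,143.6
(radiographer) yen/h, used exactly as printed to one decimal.  Each
profession also carries an age-band distribution (rate and workforce
share per band; physicians have no observed 20–24 band) used for wage
sampling, and physicians carry three seniority rates — resident
2,775.7, specialist 6,141.2, trainer 8,351.2 yen/h — used in the
scenario analysis.  Scenario repricing applies to *all* physician
occurrences (including the three-surgeon operation); only this reading
reproduces the published grade-stratified differences, which are
exactly the 140- and 60-minute physician time gaps priced at each grade
rate.

### Decision tree and cohort simulation

After the operation a patient develops sVSP with probability 13.6%
(coiling + clazosentan), 28.8% (coiling, control), 16.2% (clipping +
clazosentan) or 39.6% (clipping, control), taken from the pivotal
Japanese trial.  Expected per-arm cost is the probability-weighted mix
of the sVSP+ and sVSP− pathway totals.  The cohort simulation runs
1,000 outer iterations; each draws one sensitivity-analysis parameter
set (shared by all patients of that iteration — patient-level cost
heterogeneity within an iteration is deliberately not modelled, which
keeps the binomial structure exact) and binomial vasospasm counts among
10,000 patients per arm, then summarises the between-arm savings by
mean and 2.5/97.5 percentiles.

## Numerical and sampling choices

- Currency is computed in double precision and reported to 2 decimals.
  Comparisons against published values use ±2 yen for totals and ±1 yen
  for profession/grade differences: wage rates printed to 0.1 yen/h
  propagate about a yen into 14-day totals.
- Triangular sampling is by inverse CDF; degenerate triangles
  (min = mode = max) return the mode, so point-parameter configurations
  collapse the Monte Carlo onto the deterministic estimate.
- Wage sampling draws an age band with probability equal to its
  workforce share and returns that band's rate (a categorical, not a
  continuous, distribution).
- Sampling granularity default: one time draw per activity per
  iteration (shared across its occurrences and across pathways) and one
  wage draw per profession per iteration.  This maximises
  between-iteration variance transparency; the alternative reading —
  independent draws per occurrence — is available via
  `PSAConfig(time_granularity="occurrence", wage_granularity="occurrence")`
  and leaves the means unchanged (verified in the suite).
- Randomness: a single seed feeds a `SeedSequence` split into
  fixed-purpose streams (activity times, wages, one stream per pathway
  for per-occurrence draws, a separate stream for binomial cohort
  draws), so one pathway's results do not shift when another is added
  and all outputs are bit-reproducible per seed and platform.
- Run sizes: the PSA default is 10,000 iterations and the cohort
  default 1,000 × 10,000, both vectorised (seconds on one core); the
  repeated credible-interval coverage check uses 200 × 2,000 replicates.

## Reconciliation with the published tables, and the known residual

The published schedule column is ambiguous in places; the packaged
schedule was fixed by reconciling against the published totals.  With
the encoding above, all four no-vasospasm totals reproduce within
±0.8 yen of 229,228.38 / 177,885.40 / 290,971.93 / 239,628.95, every
between-arm difference (totals, professions, grades) reproduces within
±0.2 yen, and the modality-independence of the differences holds
exactly.  Two reconciliation-relevant choices: the day-7 cerebral
angiography is performed for both modalities (required by the clipping
totals), while both DSA rows — smooth day 7 and rescue days 7/14 — are
coiling-only follow-up.

The vasospasm-stratum *absolute* totals do not reproduce exactly: the
packaged schedule yields 614,646.63 / 575,491.28 / 645,284.73 /
606,129.38 yen against published 602,564.35 / 563,409.00 / 646,533.30 /
607,377.95 — within 2.15% everywhere.  The published rescue-phase
occurrence counts are not specified precisely enough to close this gap
while keeping the (exactly reproduced) differences intact, so the
residual is asserted as a ≤2.5% bound in the test-suite and documented
here rather than absorbed by tuning.  Relatedly, the published PSA
means for the clipping vasospasm stratum lie *below* the deterministic
totals: several rescue-phase triangles have `max < 2 × mode`
(e.g. 90 (45, 100)), placing their means below their modes, so the
mean-exceeds-mode property holds only for pathways whose triangles all
follow the default half/double rule — the suite asserts it exactly
there, plus for the packaged no-vasospasm pathways.

## Synthetic generator

`generate_random_study` emits random configurations with the packaged
structure — triangular times by the half/double rule, all three phases
and schedule kinds, guaranteed arm-substitution pair and scheduled
activity, random wage tables with positive band weights summing to
100 — for property testing against `oracle_cost`, a deliberately naive
day-by-day enumeration that re-reads the raw config records (so
schema-mapping bugs are caught) and shares no code with the pipeline.
The generator does not emulate realistic labour-economics structure in
its wage tables, and no synthetic config reproduces clinical realism;
passing the oracle sweep establishes the algebraic correctness of
expansion + costing, not the clinical validity of any schedule.

## Limitations

- Discharge always occurs on day 14; early discharge, re-bleeding,
  treatment discontinuation and mortality are not modelled.
- Vasospasm, if it occurs, always starts on day 7 and lasts through
  day 14.
- The process map reflects a single institution's protocol; other
  hospitals' workflows will differ.
- Only labour is costed; clazosentan's acquisition cost is outside the
  model's scope, so the savings reported here are not a full
  cost-effectiveness statement.
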