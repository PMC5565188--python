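# Methods

## The recruitment model

Seed fate is modelled as a chain of four stages.  Stage 1 places a seed
in a microhabitat: for dispersed seeds a deposition distribution `w`
over microhabitats, for undispersed seeds a point mass on the focal
shrub's own microhabitat (seeds fall beneath their mother).  Stages 2–4
are survival of post-dispersal seed predation (`s2`), seedling emergence
(`s3`) and first-season seedling survival (`s4`).  The probability that
a seed becomes a newly emerged seedling is `Σ_m w_m s2_m s3_m`, and of a
surviving seedling `Σ_m w_m s2_m s3_m s4_m`.

Assumptions: stages act multiplicatively and independently given the
microhabitat; transitions are stationary over the season measured; the
microhabitat (not seed density or distance) is the unit of environmental
variation; gut passage affects seeds only through the treatment-specific
emergence/survival tables.

## Estimation

* **Stage 1.**  Deposition is estimated by default from the dropping
  survey (counts of disperser droppings containing target seeds per
  microhabitat): this is the realized seed shadow.  An alternative mode
  uses direct disperser sightings (time allocation); both are
  proportional-count estimators.  Probabilities are renormalized over the
  three studied microhabitats; deposition to unstudied vegetation can
  instead be routed to zero recruitment by passing a deposition
  distribution that retains an explicit OTHER mass of zero recruitment
  (no stage tables exist for it, so it must be excluded or zeroed
  explicitly).
* **Stage 2.**  Each uncensored predation tray contributes one replicate
  proportion `n_surviving / n_exposed`, grouped by microhabitat.
  Censored trays (destroyed during monitoring) are stored in the data
  model but excluded at estimation time; a group left empty after
  exclusions is an error, never a silent zero.
* **Stage 3.**  Each sowing station × treatment contributes
  `n_emerged / n_sown`, grouped by microhabitat × treatment.
* **Stage 4.**  Survival is conditional on emergence:
  `n_surviving / n_emerged`, with zero-emergence stations contributing no
  replicate (the conditional proportion is undefined there).

Only end-of-monitoring states enter the model; per-visit census columns
in input tables are carried as metadata and ignored.

## The bootstrap simulation

Per iteration, stage transitions are drawn independently across stages
and microhabitats from the replicate lists, then chained and summed.
Two draw modes are provided because "resample the replicates with
replacement" admits two readings:

* `SINGLE_REPLICATE` (default): pick one replicate proportion uniformly
  at random per stage per iteration.  Iteration outputs then spread like
  single field replicates.
* `RESAMPLED_MEAN`: resample each replicate list with replacement to its
  own size and use its mean — the classic bootstrap of the plug-in
  estimator.  Iteration outputs then spread like the estimator, and
  their 2.5–97.5 percentiles form a conventional bootstrap CI (the
  recovery tests check this interval's coverage).

Both modes have the same expectation — the chain evaluated at
replicate-group means — which `analytic_expected_outcome` computes in
closed form and the test suite uses as a convergence oracle.

Two weighting modes govern the dispersed pathway: `DISPERSAL_ONLY`
(default; the deposition probabilities already integrate where seeds
land) and `DISPERSAL_TIMES_COVER` (deposition multiplied by relative
cover and renormalized, for analyses that weight per-microhabitat
recruitment by area).  Results always echo the modes used.

The undispersed pathway mixes the red and yellow fruit-morph treatment
tables at the seed level with weights 0.8/0.2 by default (red fruits are
about four times as frequent as yellow in the study system);
the mix is configurable.

Summaries report the mean and the SD of iteration outputs (the bootstrap
SE convention).  The default iteration count is 500.

### Stage-loss decomposition

On the starting-seed scale the per-iteration quantities `a2 ≥ a3 ≥ a4`
(survived predation, newly emerged, surviving) partition every seed into
predated `1−a2`, ungerminated `a2−a3`, died as seedling `a3−a4` and
surviving `a4`; the four recompose to 1 exactly, which the tests assert
to 1e-9.  Conditional losses (fraction of survivors failing to emerge,
fraction of emerged dying) are means over iterations of per-iteration
ratios; 0/0 iterations are excluded and counted, never imputed.

### Advantage ratio

The dispersal advantage is the ratio of pathway means.  A zero
undispersed mean with a positive dispersed mean is reported as infinite
(this is the situation when no seedling-survival replicate beneath the
mother plant is positive — then no iteration can produce a surviving
undispersed seedling); 0/0 is reported as undefined.  Note that a ratio
of sums of per-microhabitat products is *not* the ratio one would get by
multiplying pathway-aggregate stage survivals: products of stage means
differ from means (and sums) of per-microhabitat products, so aggregate
stage mortalities cannot be recombined into the advantage ratio without
the full joint weighting.  Reports therefore always derive the ratio
from the pathway outcome means directly.

## Microhabitat selection

The selection index per microhabitat is the percentage of droppings
found there minus its percentage cover (percentage points).  Inference
resamples the dropping counts as a multinomial of the observed total,
holding cover fixed (cover comes from long transects with no replicate
structure, so its measurement error is ignored); a microhabitat is
called positively (negatively) selected when the 95% percentile interval
lies above (below) zero.

## Group comparisons

Differences between replicate groups are tested with a two-sided
permutation test on the difference of means: exact enumeration of all
label assignments when requested, otherwise Monte-Carlo with the
`(1 + count) / (1 + n_perm)` convention so p is in (0, 1].  Multiplicity
is handled by the step-down sequential Bonferroni (Holm) adjustment.
Zone and set random effects are acknowledged but not modelled: the
simulation, not these tests, carries the headline result, and the tests
are companions for stage-level contrasts.

## The synthetic-campaign generator

The generator emulates: the five-table campaign structure; the replicate
layout (2 zones × 10 sets, one tray and one station per microhabitat per
set; 10 seeds per tray, 3 × 10 seeds per station); beta-binomial
outcomes — a replicate-level probability drawn from
`Beta(mean·κ, (1−mean)·κ)` then binomial counts, with seedling survival
drawn conditionally on the emerged count; independent tray destruction
(censoring); and multinomial dropping/sighting surveys.

It does **not** emulate: spatial autocorrelation between sets, zone-level
offsets, per-visit longitudinal loss dynamics, seed-density effects, or
disperser behaviour.  Passing recovery tests therefore show the pipeline
recovers its own generative model's truth — necessary but not sufficient
for real data, where the un-modelled structure above adds variance the
bootstrap may not fully capture.

Defaults (free parameters of the generator, not estimates of any real
dataset): κ = 20, i.e. an intraclass correlation of about
1/(κ+1) ≈ 0.05, moderate overdispersion typical of seed-removal trays;
tray destruction probability 7/60; 140 droppings and 200 sightings
surveyed; red:yellow morph ratio 0.8.  The `study_truth()` preset fixes
realistic stage means with deposition skewed to open ground and the
focal-shrub microhabitat harshest at every stage, including zero
seedling survival beneath it.  The packaged reference campaign
(`study_dataset()`, also shipped as CSV under `data/study_design/`) is
drawn from that preset with a fixed seed and carries the observed
censoring pattern (7 trays: 1 open/zone A, 4 open and 2 focal-shrub/zone
B) imposed exactly rather than at random.  Its outcome counts are
synthetic.

### Parameter recovery

`recovery_experiment` repeats generate → estimate → simulate and
compares the estimated newly-emerged advantage ratio with the value the
truth implies analytically.  The ratio estimator divides by a small
undispersed outcome, so it is noisy and biased upward at the original
replicate counts; at five-fold replicates the relative bias falls below
10%, which is the regime the acceptance checks use (100 campaigns, 500
iterations each — a few seconds on one CPU).  Replicates are pooled
across zones throughout.

## Numerical choices

* One seeded `numpy` generator per run with a fixed draw order makes
  every simulation bit-reproducible; dataset generation and the recovery
  experiment spawn child seeds from a `SeedSequence`.
* Probability-sum tolerances are 1e-9 (deposition, treatment mix, fate
  recomposition); replicate proportions are validated into [0, 1].
* Degenerate inputs: beta means of exactly 0 or 1 are point masses;
  single-replicate groups make the simulation deterministic with SE 0;
  empty groups, zero survey totals and all-censored groups raise typed
  errors naming the offending group.
* Microhabitat labels are case-insensitive on input and canonical
  upper-case in memory; CSV booleans are `true`/`false`; a censored tray
  has a blank survivor field.

## Known limitations

* The advantage-ratio estimator's upward small-sample bias (above).
* Cover measurement error is ignored in the selection analysis.
* The two Stage-1 sources (droppings vs. sightings) can disagree; the
  package defaults to droppings as the direct measurement of seed
  arrival but makes the choice explicit and configurable rather than
  asserting either as canonical.
* Zones and sets are pooled; systems with strong spatial structure need
  a hierarchical extension.
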