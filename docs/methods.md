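# Methods

## The analysis

`mealscan` analyses continuous feeding-event records from metabolic cages
(CLAMS-style systems) at the level of individual meals. A feeding-event
record is a list of hopper interactions, each with a start time, end time
and weight of food removed. The pipeline:

1. **Segmentation.** Events separated by less than a minimum intermeal
   interval (IMI) are one meal; the default criterion is 5 min. Merged
   clusters with a total intake of at most 0.03 g ("nibbles") are
   discarded *before* interval computation, so a nibble never terminates
   an IMI. Both thresholds are parameters; the 0.03-g rule is strict
   (`intake > 0.03 g` keeps a meal).
2. **Annotation.** Each meal receives the five microstructure parameters:
   size (kcal = grams x diet energy density), duration (min), IMI to the
   next meal (min, end-to-start), satiety ratio (SR, min per 0.1 kcal =
   IMI divided by the preceding meal's energy), and ingestion rate
   (kcal/min = size/duration). Meals are assigned to the light or dark
   cycle by their start time; each IMI/SR inherits the cycle of its
   preceding meal.
3. **Summaries.** Per-animal per-cycle totals and means; 24 x 1 h intake
   matrices aligned to light onset with pro-rata splitting of
   bin-straddling events; zero-intake hours (bins with exactly 0 g);
   SR-by-time-of-day profiles in 2-h clock bins; raster and radial export
   tables.
4. **Statistics.** Phase contrasts of meal-level parameters use a linear
   mixed model (REML) with phase as fixed effect and animal as random
   intercept, reported as estimated marginal means +/- SEM from the
   fixed-effect covariance; per-animal quantities use classical paired
   t-tests; proportions use one-tailed Fisher's exact tests. p-values are
   reported raw (no multiplicity adjustment). A singular random-effect
   fit falls back to a pooled fixed-effects fit with a warning — with
   few animals and heavy-tailed interval data the REML variance estimate
   legitimately hits the zero boundary on occasion.
5. **Calorimetry and activity.** RER = VCO2/VO2; energy expenditure
   follows the Oxymax convention heat = CV(RER) x VO2 with the linear
   Lusk oxycalorific interpolation CV = 3.815 + 1.232 x RER (kcal/L O2,
   matching the published endpoints 4.686 at RER 0.707 and 5.047 at
   1.0); RER outside [0.7, 1.0] is clamped with a warning. Ambulation is
   counted from X-axis beam breaks: a maximal run of breaks separated by
   less than a quiescence gap (default 1 s) is one episode, ambulatory
   iff two distinct spatially adjacent beams break in succession.
6. **Evoked responses.** Windowed intake after three cues: the first 4 h
   after lights-off (first hour also reported separately), refeeding from
   light onset after a 12-h dark-cycle fast (1-h and 4-h windows are both
   first-class outputs, because published summaries attach the same
   figures to either window), and 2 h after a ghrelin (1 mg/kg i.p.) or
   vehicle injection at 08:00. Events straddling a window edge contribute
   pro-rata by time; starvation windows are verified to be empty before
   analysis.

## The synthetic cohort generator

No raw animal-level records are publicly deposited for the cachexia
cohorts this package targets, so the generator is a first-class component:
it emulates paired cohorts of virtual mice observed healthy (`baseline`)
and 14 days after i.p. KPC pancreatic-tumour implantation (`kpc_d14`),
under a 12:12 photoperiod (lights on 06:00).

**Feeding model.** Meal onsets follow an inhomogeneous renewal process per
12-h cycle: waiting times are a 5-min floor (the segmentation criterion,
so generated meals never re-merge) plus an exponential whose hourly rate
follows a diurnal hazard shape (dawn feeding peak and mid-light trough in
the light; uniform dark at baseline). Gap sampling uses exact time
rescaling across hour boundaries. Meal sizes and durations are
lower-truncated normals whose location is solved so the truncated mean
equals the calibrated target. A quarter of meals are recorded as two
hopper interactions separated by a pause below 1 min; sub-threshold
nibbles (0.01-0.03 g, 0.6/h) are placed at least 5 min from any other
event. Both constructions are therefore *invisible* to segmentation by
design, which the test suite verifies. Intakes are quantized to the
0.01-g balance resolution; event times to 1 s.

**Individual variability.** Each virtual animal carries persistent
lognormal traits — a meal-size scale (CV 0.15, mean one) and an
inter-meal-gap scale (CV 0.20, median one) — that follow the animal
across phases and protocols of a paired study. The magnitudes reflect the
between-animal dispersion implied by published cohort SEMs, and they are
what gives the animal random intercept in the mixed model something real
to estimate. The gap trait's median-one centring splits its Jensen bias
evenly between cohort meal counts and intervals; the residual count
inflation of the sequential sampler (~2%, from span restarts and trait
convexity) is absorbed by a single documented deflation factor on the
rate solver's target.

**Cachectic state.** Fewer meals, longer IMIs, and clock-hour-aligned
zero-intake blocks on spontaneous days: 6 block hours in the light
(placed from 3 h after light onset, sparing the dawn peak) and 5 in the
dark (sparing the first dark hour, since the lights-off response is
preserved in cachexia), partitioned into 2-4 blocks of 2-8 consecutive
hours. Together with the ~1 h/day of stochastically meal-free hours at
cachectic feeding rates, measured zero-intake hours average ~12 per day
(~7 light / ~5 dark). Activity and gas exchange scale by the published
state multipliers (ambulation -67% dark / -48% light; VO2 -22% dark /
-8.5% light; RER setpoints shifted toward lipid oxidation).

**Evoked protocol days.** Food removal over the dark cycle for the
starve-refeed protocol; transient multiplicative boosts to the
meal-initiation hazard (and mean meal size) after food return or ghrelin
injection. Boost amplitudes are solved in closed form so the expected
boosted-window intake equals the published response for each state, using
a renewal-theorem finite-window correction that matters for the dense
1-h refeeding burst. Vehicle days have no boost.

**Seeding.** One master seed; each per-animal, per-stream generator is
derived as `SeedSequence((seed, animal_index, stream_code,
context_code))`, with a separate trait stream shared across phases.
Identical configurations and seeds give byte-identical output.

## Calibration and the reconciliation of over-determined summaries

The defaults are pinned to published cohort statistics (per-cycle intakes
and meal counts, IMIs, meal sizes and durations, zero-intake hours,
evoked-window intakes, activity and gas-exchange contrasts) listed in
`mealscan.calibration`. Three groups of published numbers are mutually
inconsistent and cannot all be reproduced by any feeding-only event
stream; the calibration resolves each by splitting the discrepancy evenly
rather than privileging one number:

* **Counts vs. intervals.** The IMIs of a cycle tile its non-eating time,
  so `mean IMI ~ (720 - N*d)/N` for N meals of mean duration d. The
  published (count, IMI) pairs violate this identity in three of four
  state-cycles (e.g., baseline dark: 22 meals x (26.0 + 1.94) min = 615
  min =/= 720 min) — plausibly because the source segmentation also
  breaks intervals at drinking bouts, which are out of scope here. The
  default per-cycle counts equalize the relative deviation from the
  reported count and from the *measured* mean IMI, modelled a priori as
  the identity value times the trait-heterogeneity (Jensen) inflation
  plus the mean dark-to-light boundary leakage (baseline dark ~24.3
  meals and a measured dark IMI near 28.8 min, each ~10% from the
  reported value; the light cycles use the bare identity, their boundary
  term being negative and roughly offsetting the inflation).
  A corollary is that this calibration preserves the finding that meal
  size is essentially unchanged in cachexia.
* **Cycle intakes vs. the 24-h total.** The cachectic light + dark
  intakes (2.37 + 4.74 kcal) exceed the reported 24-h total (6.07 kcal);
  the cycle targets are rescaled so both deviations match (~9%).
* **Meal mass vs. event mass.** Reported daily intake is a balance
  total, while per-meal summaries exclude sub-threshold events; half the
  expected nibble mass is charged against the meal-size calibration so
  meal-sum and event-sum totals straddle the reported intake
  symmetrically (within ~4%).

Mean meal sizes then follow from energy conservation
(`cycle intake = N x size + nibble mass`), which puts the baseline dark
meal near 0.32 kcal, ~15% above the reported 0.277 kcal — the remaining
irreducible residual of the inconsistencies above.

## What the generator does and does not emulate

It reproduces first and second moments of the meal process, its diurnal
structure, the paired-design trait persistence, and the published state
contrasts. It does not model drinking bouts, post-meal correlations
between meal size and the following interval (satiety feedback at the
single-meal level), day-to-day drift, tumour growth dynamics, body
weight, or meal-coupled calorimetry at scan resolution. Passing
recovery tests therefore shows the *pipeline* is correct and the
*summary statistics* are matched; it does not validate mechanistic
claims about feeding regulation in real animals.

## Numerical choices

* Segmentation boundary: a gap of exactly 5.0 min starts a new meal;
  the size rule is strictly `> 0.03 g`. Both orders of merge-vs-filter
  are implemented (`size_filter="after_merge"` default).
* Zero-duration clusters get a 1-s duration floor before ingestion-rate
  computation.
* Hour bins split straddling events pro-rata by time (switchable to
  start-time attribution); an hour is zero-intake iff its binned mass is
  exactly 0 g on the gram scale (pre-kcal conversion).
* Undefined means (an animal-cycle with no meals/intervals) propagate as
  missing values and reduce n, never as zeros.
* IMI chains are confined to one continuous record per animal and phase;
  recording gaps terminate chains.
* Mixed models are fit by REML on meal-level values; EMMs and their SEMs
  come from the fixed-effect estimates and covariance; the singular-fit
  fallback is a pooled OLS with a warning.
* Percent-change contrasts quoted against published headline values are
  rounded to the nearest whole percent, matching how those values are
  reported.

## Reproducing published quantities

The animal-level raw records behind the published summaries are **not
publicly deposited**, so no result here is a bit-level reproduction.
`scripts/acceptance.py` recomputes every headline quantity in one of two
honest ways: as a **worked example** (contrasts and shares computed by the
package's summary operations from published cohort means), or as a
**calibrated-simulation recovery** (default-parameter synthetic cohorts of
7 animals x 3 days, 40 replicate seeds, pushed through the full
segment -> annotate -> summarize/mixed-model path). Problem sizes match
the published cohorts (6-13 animals; we use 7, the meal-analysis cohort
size). The same computations back the acceptance tests in the test suite.

## Known limitations

* The balanced calibration means simulated baseline dark-cycle meal
  counts and IMIs each sit ~10% above their reported values by
  construction; both cannot be centred simultaneously (see the identity
  above).
* The cachectic dark-onset 4-h intake runs ~15-20% above the reported
  value: zero blocks spare the first dark hour and only probabilistically
  cover hours 2-4, so the simulated post-onset collapse is milder than
  observed.
* The published cachectic dark-cycle IMI (42 min) is unreachable for a
  feeding-only process with 11-13 meals per dark cycle (the identity
  gives ~52-63 min); the simulated value preserves the direction and
  significance of the effect, not its printed magnitude.
* Fisher's exact comparison of zero-intake hours uses the
  hours-with/without-intake 2x2 reading (baseline 1/24 vs. cachectic
  12/24); the exact construction behind the published p-value is not
  stated.
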