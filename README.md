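# mealscan

Meal-microstructure analysis of continuous feeding records from metabolic
cages (CLAMS-style systems), built for studies of ingestive behaviour in
mouse disease models — in particular cancer-cachexia phenotyping, where
daily food intake collapses and the question is *which* component of
feeding behaviour (meal size, frequency, duration, rate, or the intervals
between meals) drives the loss.

## What it computes

A hopper-interaction log (start, end, grams per interaction) is segmented
into meals using the standard microstructure criteria — a minimum
intermeal interval (IMI) of 5 min and a minimum intake of > 0.03 g — and
each meal is annotated with the field's five parameters:

* meal size `kcal = g × energy density`
* meal duration (min)
* IMI (min): end of one meal to the start of the next
* satiety ratio `SR = IMI / (size / 0.1 kcal)` (min per 0.1 kcal): how
  much non-eating time a unit of ingested energy "buys"
* ingestion rate `size / duration` (kcal/min)

On top of that: light/dark-cycle summaries and 24 × 1 h intake matrices,
zero-intake hours, linear mixed-effects phase contrasts with animal
random intercepts (estimated marginal means ± SEM), paired t-tests and
one-tailed Fisher's exact tests, evoked feeding responses (dark onset,
fast–refeed, ghrelin), and indirect-calorimetry analytics (RER, Lusk
caloric value `CV = 3.815 + 1.232·RER`, heat `= CV·V̇O₂`, ambulatory
beam-break counting).

Because raw animal-level records for the target studies are not publicly
deposited, the package ships a seeded synthetic-cohort generator that
emulates healthy-baseline and cachectic (KPC tumour day-14) mice —
feeding events, gas-exchange scans and activity streams with the
published diurnal structure, meal statistics and state contrasts — so the
entire pipeline is exercisable end to end. See `docs/methods.md` for the
model and its calibration.

## Worked example

```bash
mealscan all --seed 7 --out run/
```

simulates a paired study (7 virtual animals observed healthy, then in the
cachectic state, plus evoked-protocol days), writes the raw streams
(`events.csv`, `calorimetry.csv`, `activity.csv`, `manifest.yaml`) and
every analysis table. The mixed-model contrast of the intermeal interval
(`run/lmm_results.csv`) reads:

```
parameter cycle    phase      emm     sem  pvalue
  imi_min light baseline  58.6969  7.2066     0.0
  imi_min light  kpc_d14 128.9034 10.8135     0.0
  imi_min  dark baseline  25.5880  2.2420     0.0
  imi_min  dark  kpc_d14  54.0720  3.0794     0.0
```

i.e. in this run the dark-cycle IMI roughly doubles (25.6 → 54.1 min) and
the light-cycle IMI more than doubles (58.7 → 128.9 min) in the cachectic
state — meals become rarer while meal size stays flat, the microstructure
signature of cachectic hypophagia. Evoked responses
(`run/evoked_results.csv`) shrink without disappearing:

```
     paradigm  window_h    phase  mean_g  sd_g  n  percent_change  pvalue
starve_refeed       1.0 baseline   0.764 0.237  7           -54.0   0.010
starve_refeed       1.0  kpc_d14   0.349 0.135  7           -54.0   0.010
      ghrelin       2.0 baseline   0.646 0.205  7           -45.0   0.052
      ghrelin       2.0  kpc_d14   0.357 0.226  7           -45.0   0.052
```

and `run/tests.csv` holds the paired t-test on daily intake (here
−6.1 kcal/day, p < 1e-5) and the one-tailed Fisher test on zero-intake
hours. The same analyses run on real exports in the documented CSV
dialects via the individual `mealscan segment|summarize|energy|evoked`
commands.

Library use mirrors the CLI:

```python
from mealscan import GeneratorConfig, generate_feeding_events, segment
from mealscan.config import DietSpec, LightSchedule

cfg = GeneratorConfig(seed=7, n_animals=7)
events = generate_feeding_events(cfg, days=3)
meals = segment(events, DietSpec(), LightSchedule())
print(meals[["start", "size_kcal", "duration_min", "imi_next", "sr_next"]].head())
```

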