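# moveprofiles

Movement-behaviour profiling of accelerometer cohorts, and the association of
those profiles with all-cause mortality.

## The problem

Wake-time movement behaviour in older adults is more than total minutes of
activity: the same daily duration of sedentary behaviour (SB), light-intensity
physical activity (LIPA) and moderate-to-vigorous physical activity (MVPA) can
be accumulated in long uninterrupted bouts or in many short fragments, at
different times of day, and with very different intensity distributions.
`moveprofiles` implements the full analytical pipeline for studying this
multidimensionality from epoch-level (60 s) wrist-acceleration data in
milligravity (mg):

1. **synthetic cohort** — because the motivating cohort data are
   access-restricted, the package ships a generator that simulates epoch-level
   acceleration for a cohort with *planted* behaviour archetypes: a semi-Markov
   bout process per state (SB/LIPA/MVPA, cut-points <40 / 40–99 / ≥100 mg),
   lognormal per-state intensities with a diurnal modulation, weekday/weekend
   structure, occasional non-wear, and archetype-dependent exponential
   mortality hazards with administrative censoring.  Every downstream stage is
   therefore testable as a planted-truth-recovery problem.
2. **feature extraction** — 13 daily features over six dimensions: average
   acceleration; total SB/LIPA/MVPA minutes; SB/LIPA/MVPA bout counts; mean
   SB/LIPA/MVPA bout durations; the intensity constant and gradient from the
   log–log regression of time-in-intensity-bin on bin intensity; and the start
   of the most active 5 hours (M5).  Days are valid at ≥2/3 wear of the waking
   window; participants need ≥2 valid weekdays and ≥2 valid weekend days, and
   features are aggregated with 5/7–2/7 weekday/weekend weights.
3. **profiling** — features are z-scored and clustered with k-means (best of
   50 restarts); the number of profiles is selected with the elbow of the
   WSS(k) curve and the Tibshirani gap statistic (uniform reference in the
   PCA-aligned bounding box), and profiles are named deterministically from
   their centroids (activity ranking, with an MVPA-vs-LIPA contrast separating
   "active sitters" from "light movers").
4. **association** — Cox proportional-hazards models on the age timescale
   (delayed entry at enrolment age), with sequential adjustment blocks
   (sociodemographic → +lifestyle → +health-related), Grambsch–Therneau
   proportional-hazards tests, profile×modifier interaction tests,
   reference-profile rotation, a 2-year reverse-causation sensitivity
   analysis, and per-feature ANOVA with Tukey HSD contrasts across profiles.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the default
synthetic cohort (n=1000, five archetypes, 7 days each; seed 1) and write
their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_profile.py
python analysis/04_associate.py
```

`03_profile.py` prints:

```
k selection: elbow=5, gap=5, chosen=5
agreement with planted archetypes: ARI=0.930
profile sizes:
prolonged_sitters    267
light_movers         264
active_sitters       232
active               179
most_sedentary        58
first 2 PCs explain 81.7% of feature variance
```

Both selection criteria recover the five planted archetypes, and the k=5
partition agrees with the planted labels at ARI 0.93.  `04_associate.py` then
fits the three sequentially adjusted Cox models; with only ~100 events at
n=1000 the per-profile hazard ratios are noisy, but the planted ordering is
visible — the fully adjusted model prints

```
model 3 (n=1000, events=103):
  active             1.00 (reference)
  active_sitters     HR 0.99 (0.49 to 2.03)
  light_movers       HR 1.55 (0.80 to 2.99)
  most_sedentary     HR 3.77 (1.73 to 8.19)
  prolonged_sitters  HR 0.94 (0.46 to 1.93)
proportional hazards (global Schoenfeld) p = 0.75
```

i.e. the "most sedentary" profile carries a several-fold hazard versus
"active", proportionality is not rejected, and no interaction with age, sex,
obesity or morbidity is detected.  (At n=4000 the estimator recovers the
planted hazard ratios to within a few percent; see the test suite.)

The same pipeline is available as a library (`moveprofiles.simulate_cohort`,
`extract_features`, `profile_cohort`, `association.cox_fit`, ...), as a single
orchestrated run with a manifest (`moveprofiles.run_all`), and as a CLI
(`moveprofiles run-all --seed 1 --out run/`, plus `simulate`, `extract`,
`profile`, `associate` and `validate` subcommands).

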