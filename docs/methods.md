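# Methods

## Synthetic cohort generator

### Behaviour model

A participant-day is a waking window (mean ≈ 985 min, day-to-day SD 20 min,
start ≈ 06:30, weekend days shifted 45 min later) tiled exactly by alternating
bouts of a semi-Markov process over the three states SB, LIPA and MVPA.  The
next bout's state is drawn from the archetype's `state_entry_probs` with no
immediate self-transition, so a "bout" is a well-defined maximal run; the
no-self-transition chain is simulated by drawing i.i.d. categorical states and
keeping the first draw of every run, which yields transition probabilities
p_j/(1−p_i) exactly.  Bout durations are lognormal with per-state mean
`bout_mean_minutes` and log-scale SD `bout_dispersion`, rounded **up** to
whole epochs; the continuous mean is targeted at `bout_mean_minutes − 0.5`
epochs so that the post-discretisation mean honours the documented contract
(tested at ±5% over ≥1000 bouts).  The last bout is truncated at the window
end, so bouts tile the window with no gaps or overlaps.

Epoch accelerations are lognormal per state (median `intensity_median_mg`,
log-scale SD `intensity_sigma`); medians are constrained to the state's
cut-point interval (SB < 40 ≤ LIPA < 100 ≤ MVPA, in mg).  Non-SB epochs are
multiplied by a raised-cosine diurnal factor `1 + 0.30·cos(2π(t − c)/24)`.
The cosine is centred at `c = diurnal_peak_hour + 2.5 h`, so that the
*start* of the most active 5-hour window recovers `diurnal_peak_hour`
directly — the parameter encodes the quantity the M5 feature measures.  The
amplitude 0.30 was fixed during generator design as the smallest value at
which the planted timing is recoverable against day-level noise (mean
recovered M5 within ±0.5 h of target over 200 days).

With probability `nonwear_prob` (default 0.08/day) one contiguous block
(default 90 min) is flagged non-wear.

### Archetypes

Five default archetypes span the observed behavioural range of older-adult
wrist-accelerometer cohorts, from "active" to "most sedentary".  Entry
probabilities are proportional to per-profile daily bout counts, bout means
span 7.3–24.4 min for SB, and intensity medians are set so implied overall
activity spans ≈ 18–45 mg.  Mixing fractions are 0.182 / 0.223 / 0.259 /
0.260 / 0.076.  Participants jitter around their archetype (mean-one
lognormal multipliers: CV 10% on bout means, 8% on intensity medians; waking
length SD 25 min; M5 target SD 0.5 h), so clusters have realistic within-
profile spread; days are otherwise i.i.d. given archetype and day type, since
the within-person day-to-day covariance structure is not identified by the
summary statistics the calibration uses.

### Survival and covariates

Mortality follows an exponential hazard on the age timescale:
`λ = λ0 · exp(archetype log-hazard + covariate effects)`, with administrative
censoring at `entry_age + 8.1` years and entry ages ≈ N(69.4, 5.7²) clipped
to 60–83.  Archetype hazard ratios default to 1 / 1.57 / 1.75 / 1.67 / 3.25
(most-active reference).  Thirteen binary/count covariates are simulated with
archetype-graded prevalences (e.g. obesity 8.7%→33.4%, diabetes 6.8%→23.8%
from the most to least active archetype); six of them carry non-zero
conditional log-hazards (sex −0.35, smoking 0.45, diabetes 0.30, obesity
0.20, hypertension 0.15, morbidity 0.25/condition), so the sequential
adjustment in the association stage has real confounding to remove.  The
baseline hazard λ0 = 0.00607/person-year was solved by Monte-Carlo so the
full mixture yields ≈ 410 deaths per 3991 participants over the horizon
(≈10.3%).  A constant-in-age baseline keeps every planted log-hazard
analytically recoverable; it understates the age-gradient of real mortality,
so under the memoryless hazard roughly 25–35% of simulated deaths fall in
the first 2 years of follow-up — proportionally more than an ageing cohort
would show — and the 2-year sensitivity analysis excludes accordingly more.

## Feature extraction

* Cut-points applied to 60 s epoch means: SB < 40 mg ≤ LIPA < 100 mg ≤ MVPA
  (closed on the left).  Minimum bout length is one epoch.
* Wear-time rule: a day is valid iff wear ≥ 2/3 of the waking window
  (boundary inclusive); inclusion needs ≥2 valid weekdays **and** ≥2 valid
  weekend days.  Aggregation is `(5·weekday mean + 2·weekend mean)/7`,
  per feature over the days where it is defined; with 5+2 valid days this
  equals the plain mean.
* Non-wear epochs on valid days are imputed with the same-clock-epoch mean
  over the participant's other valid days (falling back to the day's worn
  mean) — a deterministic stand-in that preserves diurnal structure.  Wear
  fractions are always computed pre-imputation.
* Intensity distribution: worn epochs are binned in 25 mg bins from 0 mg;
  `ln(minutes in bin)` is regressed on `ln(bin midpoint)` over non-empty
  bins (natural logs, OLS).  The intercept is the intensity constant, the
  slope the intensity gradient.  Days with fewer than two non-empty bins
  yield a missing value.  The 25 mg width is the convention of the
  intensity-gradient literature; per-day fits are averaged over days rather
  than fit on pooled data, matching the per-waking-period definition of all
  other features.
* M5: the 5 h window is advanced at epoch resolution; ties break to the
  earliest start; windows are means over exactly 300 epochs, so the rolling
  implementation is bit-identical to an exhaustive scan.  Days shorter than
  5 h yield a missing value.
* A state absent from a day has zero duration and bouts and a *missing* mean
  bout duration (excluded from that participant's average for that feature
  rather than fabricating zero-length bouts); participants with a feature
  missing on every valid day are flagged and excluded from clustering.
* Partial epochs at window edges are not modelled: the generator emits whole
  epochs only, and the extractor assumes contiguous whole epochs.

## Profiling

Features are z-scored (population SD; an error names any zero-variance
feature).  k-means uses scikit-learn's Lloyd iterations with k-means++
seeding, `n_init=50` restarts, 300 max iterations, tolerance 1e-6 — enough
restarts that WSS(k) is stable and non-increasing in k.  WSS+BSS equals the
total sum of squares by construction and is asserted in tests at 1e-6
relative.

* **Elbow**: argmax of the discrete second difference of WSS(k); a curve
  with no curvature above 1e-6 of the total WSS drop is flagged
  indeterminate.  The curve is always emitted for inspection.
* **Gap statistic**: B=50 uniform reference sets drawn in the PCA-aligned
  bounding box of the data (the original recommendation for elongated
  clouds); `gap(k) = mean_b log W*_kb − log W_k`,
  `s(k) = sd_b(log W*) · √(1+1/B)`; selected k is the smallest with
  `gap(k) ≥ gap(k+1) − s(k+1)` (largest candidate as fallback).  Reference
  fits use 5 restarts — the reference boxes are unstructured, and 5 restarts
  keep the sweep inside a desk-scale runtime.
* **Choice**: among the contiguous candidate range spanned by the elbow and
  gap solutions, the k with minimal WSS (maximal BSS) wins, ties toward
  larger k; a config override is honoured with diagnostics still reported.
* **Naming** is deterministic from centroids: clusters ranked by the
  average-acceleration coordinate, most active first; for k=5 the canonical
  names are assigned in rank order except that among ranks 2–3 the
  MVPA-minus-LIPA duration contrast distinguishes "active sitters"
  (MVPA-leaning) from "light movers" (LIPA-leaning).  k=1 is "all"; other k
  get rank names.

## Association

Age is the timescale: participants enter the risk set at entry age and exit
at death/censoring age (lifelines `entry_col`; Efron tie handling).  Model 1
adjusts for sociodemographic covariates, model 2 adds lifestyle, model 3
adds health-related covariates.  Hazard ratios are exponentiated
coefficients with Wald 95% CIs.  Schoenfeld residuals are computed under
delayed entry directly (risk set `entry < t ≤ exit`, weights `exp(x'β)`),
and the Grambsch–Therneau chi-square with a rank time transform gives
per-covariate and global proportionality tests; the global test is
calibrated (~5% rejection under a proportional-hazards generator) and
powered (>80% against a sign-reversing effect) in the test suite.
Interactions (profile × age/sex/obesity/morbidity) are likelihood-ratio
tests of the interaction block added to the fully adjusted model; modifier
main effects are added unless already an adjustment covariate.  The
sensitivity analysis drops participants *dying* within 2 years of entry
(follow-up time, not age) and refits.  ANOVA uses `scipy.stats.f_oneway`
per feature with statsmodels Tukey HSD when significant at 0.05.  All tests
are two-sided at α=0.05.

## Problem sizes and determinism

Default study conditions: n=1000 participants × 7 days for profile-recovery
runs, n=3991 (the analytical sample size) for mortality-calibration and
feature-separation runs, n=4000 with ~400 events for hazard-ratio recovery.
The test suite uses 20-seed sweeps for k-selection calibration and 50–100
replicates for Cox bias/coverage/type-I checks; the acceptance script uses
10 pipeline replicates and 20 Cox replicates.  Every stochastic path is
driven by `numpy.random.Generator` seeded through `SeedSequence.spawn`
fan-out (per-participant streams, then covariate and survival streams), so a
cohort is bit-identical under a fixed seed regardless of how later stages
consume randomness.

## Known limitations

* The generator's days are i.i.d. given archetype and day type: no
  within-week autocorrelation, no seasonal or weather structure, and no
  weekday/weekend behavioural contrast beyond a later weekend start.
* Constant-in-age baseline hazard and exponential survival; real mortality
  accelerates with age, so age-interaction power and early-death patterns
  differ from field data.
* Intensity distributions are state-wise lognormal; real epoch distributions
  are heavier-tailed and autocorrelated within bouts, so planted intensity
  constants/gradients shift slightly (≈0.5 units / ≈0.2 units) from their
  nominal targets after classification feedback — rank structure across
  archetypes is preserved, which is what profile recovery tests.
* Passing planted-truth recovery shows the pipeline is correct and
  well-calibrated under this generative model; it does not validate the
  epidemiological conclusions on any real cohort.
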