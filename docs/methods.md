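# Methods notes

This note records the modelling assumptions, parameter choices and numerical
conventions behind `drisleep`, in the spirit of a model-description appendix.

## The measurement model

The unit of observation is one *occupied minute*: contactless under-mattress
sensors emit a record only while the bed is occupied, so absence of data
inside a night is itself the signal (a bed exit). All derived quantities
respect three conventions:

- **Noon-to-noon nights.** A night window is `[12:00, 12:00 next day)` in
  the participant's local wall clock, holding at most 1440 minute cells.
  Grids are indexed by wall-clock minutes, so every window has exactly 1440
  cells; on the autumn daylight-saving transition the repeated hour collapses
  by keep-first. Episodes occupying more than 24 h are excluded — such
  episodes are rare, usually tied to acute medical events, and outside the
  scope of the nightly metrics.
- **Half-open intervals.** Bed periods are `[start, end)`; a minute belongs
  to the period in which it starts.
- **Occupancy is record presence.** A minute whose heart-rate or
  respiration values are missing still counts as occupied; physiology gaps
  never delete occupancy.

The nocturnal occupancy period (NOP) is computed from timestamps as the
*inclusive* first-to-last-minute span. The timing-angle identity
`NOP = (ARISE + 180° − TO_BED)/15 (mod 360)` holds because the two angle
conventions differ by a 180° origin offset; the timestamp arithmetic is
authoritative.

Boundary semantics of the night-quality filter: every printed range is
inclusive (`EXITS ≤ 20`, `IBP ∈ [0.6, 1]`, `HR ∈ [45, 85]`, `RR ∈ [10, 25]`,
`EXIT_DUR ≤ 60`, `IBT ∈ [4, 16]`, bed/wake clock windows) except out-of-bed
time, which is strict (`OBT < 180 min`), and the exit gap rule (`≥ 2 min`).
`EXIT_DUR` is defined as 0 when `EXITS = 0` (the quotient is otherwise
undefined), so exit-free nights trivially pass the 60-minute rule. Nights
missing any required metric are dropped with a `missing_value` verdict; this
includes nights that lack HR/RR entirely — whether such nights should
instead skip the physiology rules is a declared convention, not a derived
fact.

## The synthetic cohort generator

The generator emulates the *structure* of real recordings, not their full
physiology. Per night: going-to-bed and arising times are Gaussian around
profile means; exits are `Poisson(exit_rate)` with log-normal durations
(σ = 0.9 on the log scale, mean `exit_dur_mean`), onsets uniform inside the
in-bed interval; durations are truncated below 30 minutes because a longer
absence is, by the episode-clustering rule, a separate bed period rather
than an exit. Sleep states follow a first-order Markov chain at 1-minute
resolution starting in LIGHT, built as
`P = a·I + (1−a)·1πᵀ` (persistence a = 0.85) so its stationary law equals a
target state mixture. Snoring is per-minute Bernoulli with a *night-level*
beta-distributed propensity (concentration 15) — without that extra level,
the nightly snore proportion concentrates so tightly that it becomes an
implausibly perfect group discriminator. HR/RR are i.i.d. Gaussian around
nightly means; real recordings have within-night autocorrelation that the
generator deliberately omits, so passing tests say nothing about
autocorrelation-sensitive analyses.

Default group profiles encode published cohort descriptives: the AD profile
uses to-bed 22:47 ± 2.8 h, arise 08:29 ± 2.4 h, 3.5 exits/night of mean
9.6 min, state mixture (awake .223, light .532, deep .155, REM .090); the
older-control profile 22:44 ± 2.2 / 07:52 ± 2.5, 3.1 exits of 8.7 min, more
deep sleep and snoring; the young profile 23:59 ± 1.9 / 08:50 ± 2.1 with few
short exits. A per-participant latent disturbance z (standard deviation a
design choice per experiment; 0.4 in the cohort-scale presets) shifts
timing by 0.15 h/z, scales exits by `exp(0.25 z)`, and enters assessment
scores linearly through a per-scale effect map — giving the association
stage a planted ground truth.

The planted three-phenotype benchmark (very early fragmented, prolonged,
normative) keeps published cluster-mean timings but uses roughly half the
printed spreads as generator SDs: observed cluster SDs include
boundary-night assignment noise, and a *planted* benchmark needs classes
that are separable by construction.

`sample_night_records` draws nightly metric rows directly from the same
profile distributions (Dirichlet state mixtures with concentration 60,
binomial snore minutes) without materializing minutes; it exists for
cohort-scale model experiments (tens of thousands of nights) and matches
the minute pipeline's metric identities exactly. Minute-level generation
remains the primary path and is what the recovery tests exercise.

## Clustering choices

- The combined night distance averages min-max-normalized Jaccard (on
  non-occupancy masks; defined as 0 when both masks are empty) and Euclidean
  (on quarter-hour counts) components. Raw scales are incommensurable, so
  equal weighting is applied *after* normalization; the normalization
  constants are dataset-scoped and persisted so new nights project
  consistently.
- Ward linkage is applied to the combined distance directly. Ward formally
  expects squared-Euclidean geometry; using it on this combined measure is a
  deliberate, documented choice (it keeps the two distance components on one
  footing), not an oversight.
- K is selected by minimum Davies–Bouldin over 2–10 (night level, and 2–8 at
  the window level, computed on the aggregate/proportion vectors), and by
  maximum silhouette over 2–8 at the participant level (complete linkage on
  Hellinger distances). Ties break toward smaller K. A best silhouette
  ≤ 0.5 raises a weak-structure flag, following the usual silhouette rule
  of thumb (noise-only inputs score ≈ 0.3 at these sample sizes,
  well-separated archetypes > 0.7).
- Cluster labels are renumbered 1..K by descending mean occupied minutes;
  ties break by cluster size, then original label. The relabeling is
  idempotent.
- Participant-level clustering uses sleep-state proportions only (not
  proportions plus behavioral metrics); the alternative feature set is a
  plausible reading of the upstream design and is noted as such.

## Interpretable boosted models

Wherever an "explainable boosting" classifier is called for, the package
fits gradient-boosted trees of depth 1 (150 stumps, learning rate 0.1).
Depth-1 trees split on a single feature, so the fitted model is a strictly
additive sum of per-feature step functions — the same model family EBMs
represent, with at most 2 leaves per term and no interactions. The state
classifier is the multi-class version; DRI-SI-AD members are the binary
version.

DRI-SI-AD protocol parameters: naive fraction 0.1 (participant-level,
stratified, round-half-down, matching an 83-case cohort yielding 8 held-out
cases), horizon 30 days (participants whose whole span fits inside the
horizon keep their nights in training, logged), 10 temporal blocks with one
pick per block per pass at van der Corput positions (3 passes by default —
"quasi-random temporal sampling" is otherwise underdetermined; the scheme is
deterministic, order-preserving, and swappable), under-sampling to exactly
1:1, night-level internal validation holdout of 15%, probability (not logit)
averaging across members. The dummy baseline shares the member architecture,
is trained on label-shuffled data, and is evaluated out-of-fold (2-fold) so
its calibration reflects genuine absence of signal rather than
memorization. Score categories are six equal-width half-open bins on [0, 1]
with the top bin closed; the cut points are a convention, not estimated.

## Statistics

Welch's ANOVA and Games–Howell comparisons are implemented from the
published closed forms (weights `w_i = n_i/s_i²`, the Welch correction
`Λ = 3Σ(1−w_i/W)²/(n_i−1)/(k²−1)`, studentized-range p-values at
Welch–Satterthwaite df), with a variance floor of 1e-12 for degenerate
zero-variance groups (flagged). Eta-squared is the classical SSB/SST.
Bonferroni correction spans the outcomes of one report invocation at
α = 0.05. The circular correlation is the Fisher–Lee coefficient (O(n)
computational form) with a 1000-resample percentile bootstrap; the choice of
coefficient is a convention, as is matching *without* replacement in the
propensity stage (stable case order, ties by id) and 50 equal-width
Hellinger bins spanning each metric's filter-admissible range.

The association model is fitted per scale by REML:
`SCORE = β0 + β1·mean(DRI) + β2·var(DRI) + β4·AGE + β5·SEX + u_i + ε`,
participant random intercept, sex coded 0/1, age in years uncentered; the
coefficients are named β0, β1, β2, β4, β5 (β3 unused). The windowed
summaries use the same half-open 90-day window and ≥ 15-day rule as the
clinical-window profiles, with the n−1 sample variance. With the random
intercept pinned at zero the model reduces analytically to OLS, which is
what the `fix_re_zero` branch computes.

## Randomness

All randomness descends from one integer seed. Sub-streams are derived via
`SeedSequence(seed, spawn_key=keys)` — the mechanism `spawn()` itself uses.
This matters: seeding sibling generators from `[seed, k]` entropy lists with
small sequential k leaves measurable cross-stream correlation (≈ 14%
overdispersion of simulation z-statistics in our mixed-model calibration,
observable even with oracle GLS), while spawn-key derivation is calibrated.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use sizes chosen to make each
property measurable with comfortable statistical margin on a single CPU:
600 nights for the three-phenotype recovery; 40 participants for the
four-archetype recovery; 20 participants × 30 nights for the
leave-one-participant-out classifier; 40 + 400 participants × 180 nights
(night-level sampler) with a 50-member ensemble for DRI-SI-AD
discrimination; a 60 + 60 × 100 identical-profile cohort with naive
fraction 0.2 for the null calibration, so the naive set holds 12 + 12
unseen participants and participant-level clustering does not dominate AUC
variance; 1000 simulations for the Welch type-I rate; 300 (tests) or 60
(acceptance script) simulations of 80 participants × 6 assessments for
mixed-model slope coverage.

## Known limitations

- Sleep-state sequences are first-order Markov and HR/RR are white noise;
  analyses sensitive to within-night dynamics are untested against realistic
  autocorrelation.
- The generator plants group differences at the *night-metric* level; device
  artefacts (signal dropouts, two-in-bed confusion, pacemaker HR peaks) are
  not modelled.
- Ensemble members are fitted independently; no calibration (Platt/isotonic)
  is applied to the averaged probabilities.
- The silhouette/Davies–Bouldin K-selection is a heuristic; on real data the
  selected K should be inspected against the dendrogram, not trusted blindly.
- Apnea events, physiologically realistic HRV, and raw 250 Hz waveforms are
  out of scope.
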