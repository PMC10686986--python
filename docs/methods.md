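# Methods

This note documents the models, defaults and numerical choices behind
`sow_welfare`, and what the synthetic experiments do and do not show.

## The estimation problem

Each sow × 2-day period is one observation. Manual video coding yields
three valence indices in [−1, 1] (activity, giving, receiving); these
are clustered into welfare-relevant behavioral states. Because manual
coding does not scale, a depth-limited decision tree is then distilled
from 13 automatically recorded features (7 per-sow feeder features, 6
group-level posture percentages) to predict the state of new
sow-periods online. Finally, repeated-measures tests ask whether state
membership depends on housing conditions (control vs. perturbation
weeks), sow covariates, and health.

## Synthetic herd model (`simgen`)

The generator defines the study conditions for every downstream test.

**Latent states.** Each sow-period is gentle, aggressive or scapegoat,
drawn independently given the week type:
control = (0.53, 0.25, 0.22), event = (0.35, 0.39, 0.26)
(gentle, aggressive, scapegoat). States are sampled independently per
period — observed herds switch state frequently and no transition model
is fitted; an optional `stickiness` parameter (default 0) exposes
state persistence without changing the default conditions. Optional
per-event-type probability overrides (`event_modifiers`) default to
off, as do health-linked state biases.

**Herd layout.** 4 groups × 17 sows × 6 periods (408 observations),
each period two feeding days starting at midnight, week types
alternating control/event; event types rotate through
{feed_competition, sound, cold, hot, enrichment, impoverishment} with a
per-group offset.

**Ethogram.** Interaction counts are Poisson with rates
λ_pos = R(1+c)/2, λ_neg = R(1−c)/2 where c is the state's index center
and R = 20 expected interactions per period per axis, so
E[(pos−neg)/(pos+neg)] → c. The index of a ratio of Poisson counts
equals c only asymptotically in R; at R = 20 the bias is below 0.05,
which is the accepted approximation (verified by simulation). The index
centers default to the canonical archetypes: scapegoat
(−0.14, 0.08, −0.75), aggressive (0.07, −0.80, −0.67), gentle
(−0.18, 0.50, 0.00). Active/passive minutes are Gamma around
T(1±c)/2 with T = 1200 observed minutes per period.

**Feeder stream.** Daily nutritive and non-nutritive visit counts are
Poisson at the per-state per-period means divided by 2 (per-period
means: nutritive 2.48/3.11/2.39, non-nutritive 10.4/15.4/11.1 for
scapegoat/aggressive/gentle). Per-visit durations are Gamma with mean
time/count (so per-period total visit time also matches its per-state
mean: nutritive 90.4/105.0/80.6 min, non-nutritive 61.4/88.2/63.5 min)
and coefficient of variation 0.6 × `dispersion_scale`. Note the
per-observation mean-duration features (`avg_nv`, `avg_nnv`) are means
of ratios and therefore deviate slightly from the ratio of the
configured means; the count and total-time features are the calibrated
quantities. The first nutritive visit of the day is Normal around a
state-dependent hour (aggressive 05:00, gentle 05:30, scapegoat 06:30),
which induces the feeder-rank (social hierarchy) signal.

**Postures.** Each state has a fixed individual time budget over six
postures (e.g. eating 3.20/3.93/2.97 %); the group summary is the mean
over the group's sampled states plus Gaussian detector noise
(0.8 × `dispersion_scale` percentage points), clipped to [0, 100] and
rescaled if the six postures exceed 100 %. The budgets sum to ≈ 96.3 %;
the deficit is an explicit "undetected" fraction (animals the detector
misses), not allocated to any posture.

**Dispersion calibration.** All continuous dispersions are multiplied
by a single `dispersion_scale`. Its default (0.05) was fixed once, by
grid search during development, so that the end-to-end depth-3 tree
reaches a realistic 72–80 % accuracy band (median over seeds 1–10:
test ≈ 76 %, train ≈ 84 %). Two consequences are worth knowing:

* visit *counts* stay Poisson at the state means regardless of the
  scale, so class overlap in count features is irreducible and caps
  attainable accuracy;
* at the calibrated scale the feeder order is nearly deterministic in
  the state, so the rank feature separates states more strongly than
  the modest rank differences real herds show.

**Randomness.** One root seed; per-stream generators (states, ethogram,
feeder, postures, registry) are derived deterministically from
(seed, CRC32(stream name)), so each stream is independently
reproducible and `generate_dataset` is bit-identical for equal configs.

### What the generator does not emulate

States are iid given week type, so there is no between-group
heterogeneity (real groups can differ enormously in composition), no
within-sow temporal persistence, and no seasonal or parity trends.
Group posture features therefore carry only weak composition signal at
the default probabilities, and passing tests say nothing about how well
posture features would transfer to herds where group identity is a
strong confounder. Registry covariates (parity, body weight, backfat)
are one static value per sow and independent of state; the covariate
Friedman tests on synthetic data are exact nulls (all within-sow values
tied), which validates the ns verdict path but not covariate effects.
Feeder queue dynamics, pregnancy physiology and health-event dynamics
are out of scope.

## Feature engineering (`features`)

* Visits longer than 360 min are sensor artifacts and are removed
  (fraction logged); negative durations raise. Filtering is idempotent.
* Indices define 0/0 = 0 (neutral); inputs must be non-negative.
* Per-period feeder aggregates: counts, minute totals, and
  averages = total/count with 0 when the count is 0.
* Feeder rank: per day, sows are ranked 1..N by first nutritive visit
  (ties by sow id); a sow with no nutritive visit that day gets rank
  N + 1; the period rank is the mean of daily ranks. This
  first-visit-order reading is the simplest faithful proxy of feeder
  hierarchy.
* Sow-periods without an ethogram tally (or whose group-period lacks a
  posture summary) are dropped with a warning — the observation unit is
  the complete sow-period. Feeder features default to 0 for sows that
  never visited.

## Clustering (`cluster`)

Indices are already normalized to [−1, 1]; the fitter asserts
finiteness and applies no further scaling. K-medoids minimizes the sum
of Euclidean distances to the cluster medoid (inertia). The optimizer
alternates nearest-medoid assignment with within-cluster medoid
updates, then applies a greedy PAM-style swap phase (best
strict-improvement medoid/non-medoid exchange until 1-swap-optimal);
the best of 10 restarts is kept, alternating k-means++ D² seeding with
uniform seeding because D² sampling systematically under-explores
solutions that place two medoids in nearby dense regions. On all tested
instances with n ≤ 12 and k ≤ 3 this matches exhaustive enumeration of
medoid subsets.

Validity indices: mean silhouette (singletons score 0; 0/0 = 0),
Calinski–Harabasz [B/(k−1)]/[W/(n−k)] and Davies–Bouldin with
centroid-based scatter (both match scikit-learn's definitions), and an
elbow candidate maximizing the second difference of inertia. `select_k`
is silhouette-primary with CH, then DB, then smaller-k tie-breaks
(ties at 1e-12); the full report is always emitted so users can apply
their own judgment — the five indices need not agree in general. On
real behavioral data, reported inertia/silhouette values are properties
of that dataset; synthetic analogues are not comparable to them and are
not asserted against.

Labeling (k = 3 only): aggressive = minimum giving index; scapegoat =
minimum receiving index among the rest; gentle = remainder. Exact ties
on a deciding coordinate raise for manual labeling rather than guess.

## Decision tree (`treeclf`)

Standard Gini CART: exhaustive scan over features × midpoints of
consecutive distinct values, maximizing weighted impurity decrease;
ties break by feature-name order then lower threshold, and leaf
predictions break count ties by class order, so trees are
bit-reproducible. Depth limit 3 by default; no pruning and no minimum
leaf size (knobs exist but default off). The 70/30 split is stratified
by class only (per-class test counts = round(n·fraction)); a
group-aware split (same sow never in both partitions) is a documented
possible extension, off by default to match the per-observation
protocol. Evaluation reports the confusion matrix, per-class
precision/recall/F1 with the 0/0 → 0 convention, and both macro and
support-weighted F1. The protocol trains and evaluates against the
*cluster* labels — label transfer, not latent-truth recovery; truth
agreement can be computed separately as a diagnostic.

`reference_tree()` is a fixed, hand-specified example tree (group
eating % → daily non-nutritive visits → group standing %, thresholds
3.39 / 3.5 / 15.28) used in docs and tests as a stable interpretable
rule; its unspecified leaves carry plausible defaults. Note its
non-nutritive-visit feature is per *day* (`nb_nnv_per_day` =
`nb_nnv`/2), unlike the per-period `nb_nnv` the learned trees use.

## Statistics (`stats`)

Cochran's Q uses the closed form
Q = (k−1)[kΣGj² − (ΣGj)²]/(kΣLi − ΣLi²) with χ²(k−1) tails; constant
rows contribute nothing, and an all-constant matrix degenerates to
Q = 0, P = 1. With k = 2 it equals McNemar's statistic (no continuity
correction) on the discordant pairs. Friedman uses within-block
mid-ranks with the standard tie-correction denominator
1 − Σ(t³−t)/(bk(k²−1)); fully tied data degenerate to 0, P = 1. Both
match scipy/statsmodels reference implementations to 1e-9 and hold
nominal size under simulated nulls. Post hoc families: pairwise McNemar
(categorical) or Nemenyi via the studentized range with ∞ df
(continuous), Holm-corrected; unadjusted p-values are reported
alongside because pairwise contrasts are often quoted unadjusted.

`association_report` pairs each sow's *modal* cluster under control and
under event weeks (sows lacking either condition are excluded and
counted); per-period pairing is available as an option. Membership is
encoded one-vs-rest per label, the minimal faithful reading of a
paired test on a 3-class outcome.

## Problem sizes

Defaults were chosen so every experiment is desk-scale: the full
pipeline on 408 sow-periods runs in about a second; the 10-seed
protocol in a few seconds; the 1000-replicate null calibrations in a
few seconds. These sizes are the package's standard experimental
conditions, not truncations of larger prescribed runs.

## Known limitations

* The accuracy band depends on the calibrated `dispersion_scale`; it is
  a statement about the generator's conditions, not about any real herd.
* The labeling sign rule assumes the three archetypes are present; with
  k ≠ 3 clusters are emitted unlabeled (`cluster_0`, ...).
* Silhouette-primary k selection is one defensible aggregation of five
  validity indices; others are plausible, which is why the full report
  is persisted.
* The one-vs-rest Cochran encoding tests each label marginally; it is
  not an omnibus 3-class test of independence.
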