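# Methods

## The study system being emulated

A colony of Egyptian fruit bats roosts in one or two caves at the edge
of a ~19,000 ha agricultural valley containing on the order of 10³–10⁴
mapped fruit trees, of which roughly 7% belong to temporally
unpredictable species (*Ficus*) and exactly two individuals are "focal"
(*F. sycomorus*). Bats are tracked by a reverse-GPS system at 0.125–0.5
Hz with ~5 m median localization error. Each bat commutes nightly from
the roost to a small, strongly revisited set of trees. A manipulation
introduces fruit-pulp odour into the roost on smeared bats; the question
is whether naive roost-mates subsequently visit the (fruitless) focal
trees more than routine movement predicts.

## Synthetic data generator

`figbat.synth` simulates this system with known ground truth.

* **Landscape.** `n_trees` (default 1000) uniform over a 13.8 km square
  (≈19,000 ha). Each tree is unpredictable with probability 0.07;
  `n_focal` = 2 trees are forced unpredictable *F. sycomorus*. The
  roost sits 500 m outside the tree extent so roost clouds never match
  a tree.
* **Memory.** Each bat owns a fixed repertoire of 1–5 non-focal trees;
  each night it visits 1–5 trees, drawn from the repertoire with
  probability `revisit_prob` = 0.8 and by uniform exploration
  otherwise. Focal trees are excluded from repertoires; they enter
  routine itineraries only through a per-night probability calibrated
  so that P(≥1 focal visit in 6 nights) = `routine_focal_window_rate`
  = 0.012.
* **Trips.** Straight constant-speed commutes at 18 m s⁻¹ link roost
  and trees; dwell durations are log-normal with median 9 min and
  σ = 1 (log scale), truncated to [4 s, 50 min]. Nights run 20:00–06:00
  with a jittered departure. Commute speed was set to 18 m s⁻¹ (below
  the 20 m s⁻¹ speed-filter threshold) deliberately: at 4 s sampling the
  commute fix adjacent to a dwell then lies ~72 m from the tree, safely
  outside the 50 m first-passage radius, so segmented visit boundaries
  coincide with the true dwell to within one fix. At slower commute
  speeds boundary fixes fall inside the radius and every segmented
  duration would be biased upward by the geometry of the simulator, not
  by the segmenter.
* **Event-time quantization.** All arrivals/departures are quantized to
  the sampling grid. This makes the ground-truth episode log directly
  comparable with fix-level segmentation (duration errors are then
  bounded by one sampling interval); it discards sub-sample timing
  realism the analyses never use.
* **Fixes.** Emitted on the grid from departure to return; positions
  interpolate the waypoint path and receive isotropic Gaussian noise
  (sd `noise_sd` = 5 m) with the matching diagonal covariance.
* **Manipulation.** `n_manipulated` = 16 bats are smeared, the rest are
  naive. Each naive bat responds with probability `response_prob`
  (default 0.18); a responder gains exactly one focal-tree dwell at a
  lag drawn from `lag_pmf`, default (0.3, 0.2, 0.2, 0.2, 0.0, 0.1) over
  lags 1–6 — the observed response timing of the 10 field responders
  (3 on night 1, four on nights 2–3, two on night 4, one on night 6).
  The injected dwell is appended after the bat's last episode of that
  night, one commute leg away, so per-bat episodes stay disjoint and
  renderable.
* **Routine interval cohorts.** `simulate_routine_blocks` emulates the
  routine (non-fruiting) tracking record as consecutive six-night
  blocks, each with its own cohort of 56 tagged bats visiting a focal
  tree with per-window probability 0.012. Cohorts of 56 force the null
  sampler to pool ≥ 2 intervals to reach 70, exercising the documented
  cumulate-until-threshold rule.

What the generator does **not** emulate: realistic flight tortuosity,
tag dropout and detection gaps, localization error inflation near
clutter, phenology-driven diet shifts, roost switching, or social
attraction between bats (encounters arise only from shared repertoire
trees). Passing tests therefore validate the pipeline's correctness on
idealized telemetry, not the field difficulty of segmentation or the
biological effect sizes.

## Segmentation

Quality filter: drop fixes whose larger covariance eigenvalue exceeds
`quality_var_max` = 400 m² (~20 m sd); the field rule is only
"covariance-based", so the eigenvalue bound is our operationalisation.
Speed filter: single causal pass dropping any fix faster than 20 m s⁻¹
relative to the last retained fix (the arriving fix is removed, not
both endpoints).

First-passage segmentation: a candidate cloud opens when `min_fixes`
= 5 consecutive fixes lie within `fp_radius` = 50 m of their running
mean; the centre is refined by alternating (extend forward, trim edges,
recompute mean) until membership stabilises (centre shift < 1e-6 m,
capped at 200 iterations — in practice 2–3). The visit spans the first
to last member fix; visits shorter than `min_duration` = 4 s (the
shortest visit reported in the field) are discarded. Defaults are ours;
all are configurable. Annotation assigns the nearest tree within
`match_radius` = 50 m, ties to the smallest tree_id. A flyover is a
pass that is both nearly straight (net/cumulative displacement > 0.9)
and shorter than `min_duration`; flyovers are excluded from all
downstream counting. Nights are noon-to-noon local indices, avoiding an
ephemeris dependency.

Degenerate inputs: an empty track or one shorter than `min_fixes`
yields no visits; a fully stationary track yields exactly one visit;
an empty tree table leaves all visits unmatched with a warning.

## Manipulation test

Observed proportion: distinct naive bats with ≥ 1 non-flyover focal
visit in nights (m, m+w], pooled across campaigns (each campaign's
cohort counted over its own window), divided by the pooled naive count.

Null: candidate start nights are all w-night intervals inside the
roster range that avoid `exclude_nights` (fruiting and manipulation
periods; the default exclusion is 14 nights before to w nights after
each manipulation). Per iteration, starts are drawn without replacement
and intervals pooled until the cumulative tracked-bat count reaches
`min_cohort` = 70. A bat counts toward the denominator once per pooled
interval ("interval-bat exposures"); "tracked in an interval" means the
tracking period covers the whole interval, mirroring the manipulation
cohorts which were tracked throughout. 215 iterations by default (the
midpoint of the 200–230 used in the field analysis).

p-value: `(#{null ≥ observed} + 1)/(n_iter + 1)`. The add-one form
avoids p = 0 from a finite null; counting ties as exceedances is
conservative. Under the null the p-value is uniform (KS-checked in the
tests), and at the study's effect sizes (0.18 response probability over
a 0.012 routine rate) the six-night window is significant at p ≤ 0.01
in ≥ 90% of seeds, with type-I error within [0.02, 0.09] at α = 0.05
over 500 replicates.

## Encounter analysis

Encounters are same-tree visit pairs with strictly positive overlap
(zero-length contact excluded). Discovery records follow the 3-night
pre/post windows; lags 1–6 shift the post-window anchor by (lag − 1)
nights (an expanding window is the documented alternative; the shifted
window was chosen so each lag tests a disjoint arrival night). Both
members of a meeting contribute a record as focal. Control dyads are
never-met co-tracked dyads sampled once overall (not per lag), matched
to the meetings' calendar months; with simulated time, months are
30-night bins (`month_of_night` is pluggable for real calendars).
Per-lag models are binomial GLMs with logit link (statsmodels IRLS);
single-class responses and complete separation (a group at 0 or 1) are
flagged instead of fitted. Per-lag p-values are reported raw, matching
the field presentation; no multiplicity correction is applied.

## Problem sizes and determinism

The test-suite and acceptance computations use 50 bat-nights for the
segmentation oracle, 20 seeds for the power check, 500 replicates for
calibration, and 60 routine interval cohorts for the null — sizes at
which every Monte-Carlo tolerance in the tests is comfortably inside
its sampling error. All randomness in a run flows from a single
`numpy.random.Generator` seeded by the configuration; fixed seeds make
`simulate_tracks` and the full pipeline bit-reproducible.

## Known limitations

* The real-data quantities (0.012 pre-manipulation baseline, 31%/42%/25%
  dyad sharing rates, the <6% lag-model differences, 9-min mean visit
  duration) depend on the deposited field tracks; the demo config
  emulates them qualitatively only.
* The first-passage refinement rule (convergence tolerance, re-entry
  handling) follows our reading of the "cloud of fixes" description;
  the original field code's adaptive rule is not fully specified.
* Dwells shorter than `min_fixes` × sampling interval are intrinsically
  invisible to any radius-count segmenter; with the default dwell
  distribution these are ~0.02% of episodes.
* Cohort sizes are taken from the manifest as supplied; the pipeline
  does not attempt to reconcile conflicting published totals.
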