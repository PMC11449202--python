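# figbat

Movement-ecology pipeline for testing roost-based social information
transfer in fruit bats from high-frequency reverse-GPS telemetry.

Egyptian fruit bats (*Rousettus aegyptiacus*) forage on fruit trees that
are spatially predictable but — for some *Ficus* species — temporally
unpredictable. The information centre hypothesis (ICH) predicts that
naive roost-mates learn about newly available resources from successful
foragers. For a species with strong spatial memory, an odour cue picked
up in the cave (e.g. from a roost-mate smeared with fruit pulp) may be
enough: the bat recalls *where* the corresponding trees are and flies
there without following anyone. `figbat` implements the full analysis
chain needed to test this in the field, driven by a synthetic telemetry
generator so every stage runs, and is testable, without any download.

## What it computes

1. **Track segmentation** (`figbat.tracks`). Raw localization fixes
   (x, y, covariance) are cleaned with a covariance quality filter
   (largest eigenvalue ≤ `quality_var_max`) and a causal 20 m s⁻¹ speed
   filter, then segmented by a first-passage rule: a *tree visit* is a
   run of ≥ `min_fixes` fixes inside `fp_radius` of the iteratively
   refined centre of their "cloud"; visits are attributed to the nearest
   mapped tree and straight, brief passes are flagged as flyovers.
2. **Manipulation test** (`figbat.manipulation`). The observed statistic
   is the cumulative proportion of naive bats visiting a focal tree
   within *w* = 1…6 nights of the manipulation,
   `p_obs(w) = #{visiting naive bats} / #{naive bats}`. The null
   resamples *w*-night intervals of routine movement without
   replacement, pooling intervals until ≥ 70 tracked bats accumulate,
   and repeats this 215 times; the one-tailed p-value is
   `p = (#{null ≥ observed} + 1) / (n_iter + 1)`.
3. **Tree encounters** (`figbat.encounters`). Dyadic encounters are
   same-tree visit overlaps of positive duration. For each meeting (and
   month-matched never-met control dyads) a binary *discovery* response
   records whether the focal bat visited, in a 3-night window lagged
   1–6 nights after the meeting, a tree its partner had used in the 3
   nights before and the focal had never used. One logistic regression
   per lag estimates the effect of meeting (log odds ratio of `met`).
4. **Synthetic colony** (`figbat.synth`). Landscape (~7% unpredictable
   species, 2 focal trees), per-bat tree repertoires with strong
   revisitation, nightly roost–trees–roost trips, 0.25 Hz fixes with
   5 m noise, and manipulation scenarios with a configurable response
   probability and night-lag distribution — all with a ground-truth
   episode log for oracle testing.

## Worked example

Simulate the experiment at the study's sizes (72 tagged bats, 16
smeared, naive response probability 0.18 over a 0.012 routine rate) and
run the six windows of the manipulation test:

```python
import numpy as np, pandas as pd
from figbat import synth, manipulation as manip

cfg = synth.SimConfig(n_bats=72, n_manipulated=16, n_nights=8, seed=7)
rng = np.random.default_rng(7)
exp = synth.simulate_experiment(cfg, manipulation_night=0, rng=rng)
focal = list(exp.trees.loc[exp.trees["is_focal"], "tree_id"])

null_visits, null_roster = synth.simulate_routine_blocks(focal_tree_ids=focal, rng=rng)
null_visits["night_index"] += 100
null_roster[["track_start", "track_end"]] += 100

visits = pd.concat([exp.visits, null_visits], ignore_index=True)
report = manip.run_manipulation_test(visits, exp.manifest, null_roster, focal, seed=7)
print(report.round(4).to_string(index=False))
```

```
 window  n_visitors  n_cohort  observed  null_mean  null_lo  null_hi      p
      1           3        56    0.0536     0.0008      0.0   0.0089 0.0046
      2           4        56    0.0714     0.0019      0.0   0.0179 0.0046
      3           7        56    0.1250     0.0037      0.0   0.0179 0.0046
      4          10        56    0.1786     0.0049      0.0   0.0268 0.0046
      5          10        56    0.1786     0.0065      0.0   0.0268 0.0046
      6          11        56    0.1964     0.0066      0.0   0.0268 0.0046
```

Each row is one cumulative window: 11 of the 56 naive bats visited a
focal tree within six nights (19.6%), while the routine-movement null
averages 0.66% with a 97.5th percentile of 2.7%; the observed proportion
exceeds all 215 resampled proportions, so p = 1/216 ≈ 0.005 (one-tailed).
Proportions are non-decreasing in the window by construction.

A complete demonstration pipeline (simulate → segment → manipulation
test → encounter models) ships as `examples/demo.yaml`:

```sh
figbat run-all --config examples/demo.yaml --out demo_out
```

The CLI also exposes the stages separately: `figbat simulate`,
`figbat segment`, `figbat manip-test`, `figbat encounters`.

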