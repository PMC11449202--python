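# Small end-to-end demonstration: a synthetic colony dense enough for tree
# encounters, with an odour-cue manipulation late enough to leave routine
# nights for the resampling null.  Qualitative emulation only: real-data
# quantities (baseline rates, sharing rates, lag effects) depend on the
# deposited field tracks.
seed: 7
simulate: true
manipulation_night: 20
sim:
  n_bats: 8
  n_manipulated: 2
  n_nights: 30
  n_trees: 120
  n_focal: 2
  extent: [5000.0, 5000.0]
  sampling_interval: 8.0
  response_prob: 0.5
windows: [1, 2, 3, 4, 5, 6]
min_cohort: 6
n_iterations: 40
lags: [1, 2, 3, 4, 5, 6]
log_level: WARNING
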