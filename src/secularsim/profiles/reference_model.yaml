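provenance:
  tool: secularsim.calibration
  seed: 1
  horizon: 500
  replicates_per_candidate: 2
  restarts: 2
  budget: 15
  score: 0.008215582479187541
  date: '2026-09-26'
demography:
  rep_cost: 0.152407
  rep_mid_threshold: 0.873779
  rep_curve_shape: 12.375054
  wb_age_threshold: 34.70784
  wb_intercept_C: 0.00512
  wb_exp_gain: 4.249714
  wb_exp_loss: 0.53869
  wb_max_inc: 0.070929
  marriage_age_diff: 11.350401
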