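{
  "planted_recall_threshold_alpha_0.01": 0.15,
  "lag1_delay_preference_threshold": 0.5,
  "calibration_run": {
    "config": "SimConfig() defaults: 120 OTUs, 3x8x8 design, depth 3000, 10 planted pairs rho=0.95 (5 lag-0, 5 lag-1)",
    "n_seeds": 20,
    "grand_mean_recall": 0.298,
    "min_per_seed_mean_recall": 0.100,
    "min_3seed_rolling_mean_recall": 0.244,
    "lag1_delay_counts": {"-1": 22, "0": 34, "1": 244}
  }
}
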