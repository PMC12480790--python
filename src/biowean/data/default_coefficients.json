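{
  "intercept": -1.61,
  "betas": {
    "slow_response": 0.55,
    "rf_positive": 0.57,
    "flare_history": 1.36,
    "joint_damage": 0.87,
    "uveitis_history": 1.28,
    "spine_involvement": 0.75,
    "tmj_involvement": 0.35,
    "treatment_failure": 1.09,
    "prefer_continue": 1.85
  },
  "baseline_intercept": -1.2861,
  "baseline_slope": 0.7557
}
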