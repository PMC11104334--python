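# Two-discrimination probabilistic reversal task, wide-window cohort
learner: {kind: window, W: 9, prior_ev: 0.0}
schedule:
  pairs: ["100:0", "80:20"]
  total_trials: 270
  reversal_trial: 136
  seed: 7
policy: {kind: greedy}
criterion: {k_consecutive: 8}
cohort: {n_participants: 1000, master_seed: 11}
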