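# Change-point Bernoulli stream, wide window learner
learner: {kind: window, W: 32}
stream:
  p_before: 0.25
  p_after: 0.75
  n_before: 400
  n_after: 400
  seed: 3
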