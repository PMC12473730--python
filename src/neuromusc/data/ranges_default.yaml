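# Default perturbation ranges for sensitivity and robustness analyses
# (version 1). Multiplicative ranges are applied as common per-family
# multipliers (per-muscle mode available via the API); the tendon
# stiffness multiplier is sampled log-uniformly, all others uniformly.
ranges:
  fmax_mult:        {kind: multiplicative, lo: 0.90, hi: 1.10, baseline: 1.0}
  lopt_mult:        {kind: multiplicative, lo: 0.95, hi: 1.05, baseline: 1.0}
  lslack_mult:      {kind: multiplicative, lo: 0.95, hi: 1.05, baseline: 1.0}
  tendon_k_mult:    {kind: multiplicative, lo: 0.50, hi: 2.00, baseline: 1.0,
                     distribution: loguniform}
  contact_mult:     {kind: multiplicative, lo: 0.75, hi: 1.25, baseline: 1.0}
  mass_mult:        {kind: multiplicative, lo: 0.95, hi: 1.05, baseline: 1.0}
  length_mult:      {kind: multiplicative, lo: 0.95, hi: 1.05, baseline: 1.0}
  grf_noise_level:  {kind: additive,       lo: 0.00, hi: 0.03, baseline: 0.0}
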