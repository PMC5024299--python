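# Demo pipeline configuration: simulate 3 enrichment rounds of a synthetic
# E-box-binding factor, then filter, QC, score k-mers and build the PWM.
# Run with:  selexmer run examples/config.yaml
outdir: selexmer_demo
simulate:
  n_rounds: 3
  reads_per_round: 100000
  consensus: CACGTG
  mismatch_factor: 5.0        # per-mismatch affinity penalty (lambda)
  composition_bias: [0.27, 0.23, 0.27, 0.23]   # round-0 A,C,G,T skew
  seed: 7
ks: [6, 8, 10]                # word sizes to score
background_order: 5           # Markov order for long-word round-0 estimates
background_min_k: 10          # use the background for k >= this
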