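# Desk-scale profile used by the test suite, examples and acceptance
# script: 3 trials of 300 s trains, 20 null randomisations, kappa = 0.2.
# 300 s is the shortest train length at which the order-5 plug-in transfer
# entropy separates connected from unconnected pairs cleanly.
build:
  rows: 10
  cols: 10
  p_rw: 0.4
  p_r: 0.4
  p_d: 0.5
  inhibitory_fraction: 0.2
sim:
  duration_ms: 300000.0
methods: [te, cc]
kappas: [0.2]
n_trials: 3
n_null: 20
null_iterations: 100
seed: 0
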