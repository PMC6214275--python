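# Full-scale experiment profile: 10 trials of 600 s (ten-minute) spike
# trains from 100-neuron networks, both correlation measures, three
# thresholds, 100 null randomisations per trial.
build:
  rows: 10
  cols: 10
  p_rw: 0.4
  p_r: 0.4
  p_d: 0.5
  inhibitory_fraction: 0.2
sim:
  duration_ms: 600000.0
methods: [te, cc]
kappas: [0.2, 0.5, 0.8]
n_trials: 10
n_null: 100
null_iterations: 100
seed: 0
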