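# Desk-scale preset: same conditioning chain, reduced sizes and epochs so a
# full run finishes in minutes on one CPU.
n_pre: 100
n_post: 100
simulation:
  sampling_rate: 1000.0
  duration: 2.0
  n_motor_units: 20
  noise_sigma: 0.05
  seed: 0
lesion:
  recruitment_fraction: 0.5
  rate_scale: 0.8
  amplitude_scale: 0.6
filter_spec:
  order: 4
  low_hz: 10.0
  high_hz: 450.0
  notch_hz: 60.0
  notch_q: 30.0
  zero_phase: true
window_length: 1000
test_fraction: 0.2
k_neighbors: 9
training:
  learning_rate: 0.001
  batch_size: 128
  epochs: 15
  seed: 0
cv_folds: 0
master_seed: 0
output_dir: run_output
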