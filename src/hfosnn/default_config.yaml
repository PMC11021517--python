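seed: 0
filter:
  order: 64
  block_size: 32
  eeg_band:
  - 4.0
  - 80.0
  hfo_band:
  - 250.0
  - 500.0
adm:
  tuning_duration: 5.0
  eeg_window_len: 0.05
  hfo_window_len: 0.005
  eeg_percentile: 40.0
  hfo_percentile: 50.0
  delta_min: 0.1
  eeg_refractory: 0.0
  hfo_refractory: 0.0
snn:
  dt: 0.0001
  mismatch_cv: 0.2
  eeg:
    membrane_tau: 0.02
    synapse_tau: 0.01
    threshold: 1.0
    reset: 0.0
    refractory: 0.1
    input_weight: 0.5
    gain: 1.0
  hfo:
    membrane_tau: 0.01
    synapse_tau: 0.004
    threshold: 1.0
    reset: 0.0
    refractory: 0.03
    input_weight: 0.55
    gain: 1.0
evolution:
  samples_per_iteration: 20
  n_elites: 4
  n_iterations: 10
  shrink_factor: 0.7
  seed: 0
  weights:
    alpha: 2.0
    beta: 1.0
    gamma: 1.0
  dt: 0.0001
detection:
  kernel_duration: 0.1
  kernel_shape: boxcar
  min_up_activations: 2
  min_dn_activations: 2
  min_total_neurons: 6
  max_hfo_duration: 0.03
  max_eeg_coactivity: 0.5
  max_ied_duration: 0.3
  mixing_min_overlap: 0.0
  separation_min_gap: 0.01
  span_trim: 0.05
  grid_dt: 0.001
stats:
  rate_threshold: 1.0
reconstruction:
  rnn:
    n_units: 300
    g: 0.9
    tau: 0.01
    dt: 0.001
    input_scale: 4.0
    hint_scale: 0.3
    smoothing_tau: 0.02
    seed: 0
  rls:
    lam: 1.0
    update_interval: 2
    n_passes: 3
    readout_ridge: 0.0001
  max_span: 0.5
  margin: 0.1
synthetic:
  n_channels: 2
  duration: 60.0
  fs: 2000.0
  seed: 0
  background_amplitude: 50.0
  event_counts:
    ied: 0
    hfo: 0
    ied_hfo: 0
    step_artifact: 0
    long_artifact: 0
  hfo_freq_range:
  - 250.0
  - 500.0
  hfo_duration_range:
  - 0.015
  - 0.03
  ied_duration_range:
  - 0.1
  - 0.18
  hfo_amplitude: 20.0
  ied_amplitude: 300.0
  step_amplitude: 500.0
  step_hold: 0.05
  long_artifact_amplitude: 800.0
  long_artifact_duration_range:
  - 1.0
  - 1.6
  min_event_gap: 0.25
  background_exponent: 2.0
  edge_pad: 0.5
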