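# Example pipeline configuration (all keys optional; defaults shown in docs/methods.md)
synth:
  n_units: 24
  duration: 1800000.0        # ms; 30 min stable phase
  pop_event_rate: 0.1        # Hz
  participation_prob: 0.8
  background_rate: 0.3       # Hz per unit
treatment_multipliers:
  background_rate: 1.5
  spikes_per_burst_mean: 1.5
  pop_event_rate: 1.5
n_per_group: 8
div: 14
seed: 1
criteria:
  max_isi_start: 40.0
  min_isi_end: 200.0
  min_interburst_interval: 100.0
  min_burst_duration: 10.0
  min_spikes: 2
descriptors:
  bin_width: 60000.0
  event_window: 300.0
  event_unit_fraction: 0.5
  hamming_bin: 10000.0
perceptron:
  max_epochs: 1000
  seed: 1
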