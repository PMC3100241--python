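# Full four-condition study: control/EphA4 at 7 and 14 DIV.
# Empty blocks pull the built-in calibrated fixture of the same name;
# any SimulationParams field may be overridden inside a block.
seed: 1
mode: spike_level
output_dir: burstnet_run
conditions:
  control_7div: {}
  epha4_7div: {}
  control_14div: {}
  epha4_14div: {}
detection:
  hp_cutoff_hz: 25.0
  threshold_k: 5.0
  dead_time_ms: 1.0
bursts:
  min_spikes: 20
  max_isi_ms: 20.0
  motif_gap_max_ms: 50.0
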