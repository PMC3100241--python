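# Scaled-down two-condition run for smoke tests and demos (~1 min recordings).
seed: 1
mode: spike_level
output_dir: burstnet_quick
conditions:
  control_7div:
    duration_s: 120.0
    n_electrodes: 12
  epha4_14div:
    duration_s: 120.0
    n_electrodes: 12
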