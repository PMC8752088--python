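# Synthetic acute session: electrode insertion at t = 30 s triggers a
# spreading-depression wave (3 mm/min) with a persistent undershoot.
seed: 8
mode: csd
simulate:
  grid: [32, 32]
  frame_rate: 1.0
  pixel_pitch_um: 150.0
  active_center: [16, 16]
  active_radius: 4
  csd:
    origin: [16, 16]
    speed_mm_per_min: 3.0
    undershoot_decay_tau: 1.0e+9
windows:
  baseline: [0.0, 25.0]
csd_analysis:
  t_insert: 30.0
plots: true
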