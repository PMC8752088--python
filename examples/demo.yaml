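# Synthetic stimulation session: 12 whisker-stimulation trials (2 s @ 5 Hz
# imaging), 4-wavelength reflectance with 1% noise, 8-channel ephys.
seed: 7
mode: evoked
simulate:
  grid: [48, 48]
  active_center: [24, 24]
  active_radius: 8
  kernel:
    peak_fraction: 0.05
    time_to_peak: 3.0
  neural:
    n_channels: 8
trials:
  n_trials: 12
  stim_duration: 2.0
  first_onset: 10.0
  period: 25.0
plots: true
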