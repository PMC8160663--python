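# End-to-end demo: two-factor diagonal design (25 samples, built-in test
# set), synthetic two-component visible/NIR spectra, GA channel
# optimization, MLR calibration with multilevel validation.
seed: 7
out_dir: demo_out

design:
  designation: d20v125
  ranges: [[1.0, 13.0], [1.0, 13.0]]

simulate:
  components:
    - [{center: 550.0, fwhm: 60.0, amplitude: 1.0}]
    - [{center: 900.0, fwhm: 60.0, amplitude: 0.8}]
  noise_replicate: 0.002
  axis_step: 5.0

channels:
  target: y_1
  population_size: 16
  generations: 15
  n_restarts: 2
  n_channels_min: 2
  n_channels_max: 3

calibrate:
  model_type: mlr
  levels: [sample]
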