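seed: 42
simulate:
  unit_size: 5
  multiple_weights:
    1: 0.5
    2: 0.3
    3: 0.2
  maturation_prob: 1.0
  brightness: 56.0
  bleach_prob: 0.03
  n_complexes: 14
  diffusion_coeff: 0.01
  frame_count: 250
  image_shape:
  - 100
  - 100
  roi:
  - 8
  - 8
  - 92
  - 92
  background_rate: 5.0
  read_noise_sd: 2.0
  placement: grid
  n_acquisitions: 24
tracking:
  smooth_sigma: 1.5
  threshold_sd: 2.5
  threshold_method: median_mad
  min_track_length: 10
  extend_frames: 60
counting:
  calibration: self
  min_steps: 20
periodicity:
  kernel_width: 0.7
  pairwise: true
  bootstrap: 1000
  group_size: 3
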