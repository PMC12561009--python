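# Frozen default run configuration.
# Training/optimization settings follow the published protocol; the
# network block is the frozen full-scale architecture whose parameter
# and FLOP accounting is checked against the efficiency table.
seed: 0
io:
  target: 256            # in-plane grid after bicubic resize
  n_train: 8
  n_test: 4
network:
  in_channels: 1
  out_channels: 1
  depth: 5
  widths: [32, 64, 128, 256, 512]
  gn_groups: 8
  leaky_slope: 0.01
  scse_reduction: 4
  dilation_second_conv: 2
  gate_init: 0.0
  msblocks_per_node: 1
train:
  lr: 1.0e-4
  weight_decay: 1.0e-5
  epochs: 100
  batch_size: 1
  threshold: 0.5
  augment: true
phantom:
  dims: [64, 64, 32]
  spacing_range: [0.6, 0.8]
  white_intensity: 1.0
  gray_intensity: 0.7
  csf_intensity: 0.15
  background_intensity: 0.02
  noise_sigma: 0.04
  bias_amplitude: 0.2
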