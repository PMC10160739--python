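# Desk-scale configuration for 32x32 phantom experiments on one CPU.
# Full-scale defaults (T = 4000, slope 5e-6, 250 epochs, depth_preset: full,
# base_channels: 32) apply to any key left out.
network:
  base_channels: 8
  window_size: 4
  num_heads: 2
  groupnorm_groups: 4
  depth_preset: reduced
  dtype: float32
  init_scale: 0.02
train:
  T: 200
  slope: 2.0e-4
  epochs: 100
  batch_size: 8
  learning_rate: 2.0e-5
  weight_decay: 1.0e-4
  gamma: 0.01
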