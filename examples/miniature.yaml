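# Desk-scale configuration: 64px model, 4+4 layers, width 128, n_max = 3,
# trained on the 3-class synthetic shape corpus. Runs in minutes on one CPU.
seed: 1
model:
  image_size: 64
  patch_size: 8
  enc_layers: 4
  enc_dim: 128
  enc_heads: 4
  window_size: 8
  window_layers: [2, 4]
  neck_dim: 128
  dec_layers: 4
  dec_dim: 128
  dec_heads: 4
  n_max: 3
train:
  lr: 0.001
  betas: [0.9, 0.95]
  schedule: constant
  grad_clip: 1.0
  augment: false
  epochs: 3
  steps_per_epoch: 250
  n_pairs: 3
  batch_episodes: 2
synthetic:
  image_size: 64
  samples_per_class: 40
  eval_samples: 16
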