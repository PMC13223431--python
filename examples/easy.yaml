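# Desk-scale run on the "easy" synthetic dataset: 4 classes, 10 patients,
# 5 volumes per patient and class, 16 x 32 x 32 voxels.
manifest: null
output_dir: runs/easy
seed: 0
model:
  n_classes: 4
  seed: 0
  backbone:
    in_channels: 1
    stem_channels: 16
    stem_kernel: 3
    stem_stride: 2
    stem_pool: false
    stage_channels: [16, 32, 64]
    stage_blocks: [1, 1, 1]
    stage_strides: [2, 2, 1]
    frozen: true
    seed: 0
  encoder:
    n_pre_layers: 2
    n_heads: 4
    width: 64
    mlp_ratio: 2.0
    dropout: 0.0
train:
  epochs: 26
  warmup_epochs: 2
  proto_epochs: 8
  batch_size: 8
  learning_rate: 0.003
  proto_learning_rate: 0.001
  weight_decay: 0.01
  seed: 0
  ablation_mode: fsm_pcm
  G: 2
  loss:
    alpha: 1.0
    beta: 0.05
    ce_weight: 1.0
    temperature: 1.0
  refresh_interval: 0
  proto_ce: fc
augment:
  crop_shape: [16, 32, 32]
  scale_prob: 0.75
  scale_range: [0.8, 1.25]
  flip_prob: 0.5
  seed: 0
synthetic:
  n_classes: 4
  n_patients: 10
  volumes_per_patient_per_class: 5
  shape: [16, 32, 32]
  cue_kind: blob-position
  cue_contrast: 0.9
  intensity_shift_sd: 0.05
  body_scale_range: [0.95, 1.05]
  noise_sd: 0.03
  difficulty: easy
  seed: 1
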