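# Desk-scale synthetic benchmark: 120 eyes (20 FTMH / 100 ERM), 64x64 slices,
# small CNN encoder, 3 disjoint 5+20 holdout replicates, 20-eye lamellar
# challenge set.  Mirrors rascl.benchmark.DESK_BENCHMARK.
seed: 0
output_root: runs/desk_benchmark
phantoms:
  n_ftmh: 20
  n_erm: 100
  n_challenge: 20
  image_height: 64
  image_width: 64
  n_slices: 7
  speckle_sigma: 0.30
# augmentation intensity scaled down with the resolution (clinical ranges are
# calibrated to 224x224 views of 496x512 scans)
augmentation:
  output_size: [64, 64]
  crop_area_range: [0.8, 1.0]
  noise_mu_range: [-0.05, 0.05]
  noise_var_range: [0.0, 0.01]
  brightness_delta_range: [-0.1, 0.1]
  contrast_factor_range: [0.9, 1.1]
contrastive:
  max_offset: 2
  temperature: 0.5
  batch_pairs: 16
encoder:
  architecture: small_cnn
  feature_dim: 64
head:
  hidden_layers: 3
  hidden_width: 128
training:
  pretrain:
    epochs: 100
    val_interval: 10
    learning_rate: 0.001
  finetune:
    epochs: 300
    val_interval: 10
    learning_rate: 0.001
    encoder_mode: frozen
    augment: true
    n_aug_variants: 3
    class_weight: none
  baseline: true
splitting:
  n_replicates: 3
  test_counts: {FTMH: 5, ERM: 20}
  k_folds: 8
  n_restarts: 20
  n_swaps: 300
evaluation:
  threshold: 0.5
  bit_depth: 8
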