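# Desk-scale GFP-production run: simulate -> register -> gate -> 3D CAE -> CV
sim:
  n_cells: 60
  image_height: 16
  image_width: 16
  trans_height: 16
  trans_width: 16
  scenario: gfp_production
  class_fraction: 0.10        # matches the top-10% expression gate
  effect_size: 2.0
  cell_to_bead_ratio: 2.0
  deletion_rate: 0.0
  displacement_rate: 0.0
training:
  total_epochs: 5
  recon_only_epochs: 1
  batch_size: 4
  latent_dim: 8
  conv_channels: [4, 8]
gate_fraction: 0.10
use_registration: true
cv_folds: 3
seed: 0
output_dir: cytofuse_example_run
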