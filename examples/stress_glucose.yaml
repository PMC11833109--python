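# Glucose-deprivation history detection with the fused 2D+3D CAE.
# Large class separation; completes in under a minute on one CPU.
sim:
  n_cells: 120
  image_height: 16
  image_width: 16
  trans_height: 16
  trans_width: 16
  scenario: glucose_deprivation
  class_fraction: 0.5         # stressed vs control
  effect_size: 2.0
  cell_to_bead_ratio: 2.0
  deletion_rate: 0.02
  displacement_rate: 0.01
training:
  total_epochs: 15
  recon_only_epochs: 2
  batch_size: 4
  latent_dim: 16
  conv_channels: [4, 8, 16]
gate_fraction: 0.10           # unused in stress scenarios
use_registration: true
cv_folds: 3
seed: 0
output_dir: cytofuse_stress_run
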