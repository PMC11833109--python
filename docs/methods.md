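# Methods

## The problem setting

A 3D imaging flow cytometer (3D-IFC) records, for every cell in flow, a
label-free 3D side-scatter (SSC) volume that sections the cell into 10
slices, plus a 2D transmission image. The cells are then dispensed
first-in-first-out onto a cell placement platform (CPP) interleaved with
marker beads, so each imaged cell can be located again later and its
subsequent behaviour (protein production over 48 h, or post-stress changes)
paired with its day-zero images. `cytofuse` implements this workflow's
computational chain — simulation, sequence registration, expression gating,
CAE classification, cross-validated evaluation — as a reusable package.
Real instrument data is not publicly deposited, so the package ships a
synthetic generator whose statistical structure matches what the analysis
assumes, and all quantitative claims in the test suite are about recovery of
that generator's known ground truth.

## Synthetic data generator

**3D SSC volume.** Each cell is a soft-edged ellipsoid intensity envelope
(logistic fall-off of width 0.08 in normalized radius, peak 0.25) with
per-slice scattering centers: the count on each of the D slices is
Poisson(λ), each center lands uniformly on the slice's elliptical
cross-section and is rendered as a Gaussian blob (σ = 0.8 px) with amplitude
jittered ±30% around a class amplitude. Gaussian pixel noise
(`noise_sd`, default 0.02) is added, intensities are clipped at 0 and
rescaled to [0, 1], stored as float32.

**2D transmission image.** The depth-projected silhouette: the same
elliptical footprint with a sharper soft edge, multiplied by smoothed
texture noise (10% contrast), plus pixel noise, normalized identically.

**Class structure.** The positive class shifts three morphological
parameters by `effect_size` times a per-parameter gap, scaled per scenario:

| parameter | class-0 base | gap per unit effect |
|---|---|---|
| scattering-center rate λ (centers/slice) | 4.0 | +1.0 |
| center amplitude (arb.) | 1.0 | +0.15 |
| cell radius (fraction of half-extent) | 0.30 | +0.035 |

Scenario presets scale the gap — thermal stress ×0.6, glucose deprivation
×1.5, GFP production ×1.0 — so glucose-deprived populations are markedly
easier to separate than thermally stressed ones, reproducing the ordering of
difficulty between the two stressors. With `effect_size = 0` the two classes
are drawn from identical distributions, which is the package's negative
control: any classifier must then sit at chance.

**Fluorescence.** In the GFP-production scenario, `fl_0h` is log-normal
(log-mean 3.9, log-SD 0.25, arbitrary fluorescence units) and the 48-h
production rate is a two-component Gaussian mixture — N(50, 15²) for the
ordinary class and N(110, 20²) for the high producers — so the top-10% gate
on `fl_48h − fl_0h` largely recovers the generative class. Stress scenarios
carry no fluorescence (set to 0); their labels are the stress history
itself.

**Dispense sequences.** Cells are streamed in order; before each cell a
marker bead (type uniform over the configured alphabet, default {A, T, C})
is inserted by a Bernoulli process with probability 1/(1 + ratio) per draw,
giving a realized cell:bead ratio near the configured 2:1; the first and
last tokens are forced beads so every cell lies in a bead-delimited segment.
The CPP copy deletes each cell independently with `deletion_rate`, and with
`displacement_rate` per interior bead lets the preceding cell hop across the
bead (a cell/bead token swap). A displacement therefore moves a cell into
the neighbouring segment, changing both segment counts — the kind of
position scrambling the registration scheme is designed to catch. The
perturbed cell ids are recorded as ground truth.

**What the generator does not emulate:** optical physics (point-spread
functions, light-sheet scanning artefacts), fluorescent-channel 3D images,
cell debris/doublets, bead detection errors, and focus drift. Passing tests
demonstrate correct recovery of the generator's statistical structure, not
instrument-grade performance on real cells.

## Registration

Bead labels are treated as reliably observed anchors (beads are large and
distinct); cell counts are the noisy signal. If the bead-label sequences of
the IFC and CPP sides are identical, segments are compared pairwise;
otherwise bead labels are aligned by longest common subsequence (ties broken
leftmost, for determinism) and unaligned spans flagged `bead_mismatch`.
An aligned pair with equal counts is matched and its cells mapped in order
to consecutive CPP positions; with fewer CPP cells it is flagged `deletion`,
with more, `displacement`. Error granularity is a single segment. Two
limitations are inherent to count-based registration and documented rather
than patched: a permutation of cells *within* a segment is undetectable, and
a displacement across a bead flags both adjacent segments (the losing side
reads as a deletion).

## Gating

The production rate is the plain difference `fl_48h − fl_0h` (it may be
negative). The gate is an exact empirical quantile: exactly
`round(fraction·n)` cells with the largest rates are labelled HIGH (Python's
banker's rounding; at the default 10% and n ≥ 100 this is exact), ties at
the threshold resolved by ascending cell id so the count never wobbles. At
least 10 rates are required — below that an empirical 10% quantile is
meaningless. No colony-size normalization is applied to the 48-h values.

## CAE classifiers

Each branch: L levels of (3×3(×3) same-padded convolution, ReLU, max-pool)
with channel widths doubling (default (8, 16, 32); the desk-scale
experiments use (4, 8, 16)), then a dense map to a `latent_dim` code
(default 64; desk scale 16). Spatial axes pool by 2 per level and must be
divisible accordingly; the depth axis pools by 2 only while it stays even
(10 → 5 → 5 → 5), since 10 slices do not survive three halvings. Decoders
mirror the encoder with transposed convolutions whose kernel equals the
pooling factor (exact upsampling), ReLU between levels and a sigmoid output
matching the [0, 1] input range. Inputs are per-image min-max normalized.
The classification head is a single fully connected layer on the
(concatenated) latent code followed by softmax. The 3D-only classifier is
the fused network with the 2D branch and the concatenation removed and
`w1 = 0`; both models derive their 3D-branch initialization from the same
named seed stream, so with `w1 = 0` the fused model's reconstruction loss
on 3D inputs reproduces the 3D-only model's bit-for-bit.

**Training.** Adam (lr 1e-3, β = 0.9/0.999), batch size 4, 150 epochs by
default with the first 20 reconstruction-only — counted inside the 150, the
most literal reading of the protocol. During the pre-phase the classifier
head receives no gradient (exactly equivalent to `w2 = 0` with the head
excluded from updates); afterwards the weighted loss with the configured
`w2` is optimized end-to-end. `w1` and `w2` default to 0.5 each — symmetric
weighting absent any guidance — and are exposed in `LossWeights`.
Cross-entropy probabilities are clamped at 1e-12; softmax uses
max-subtraction. All weight initialization, shuffling and simulation draw
from named seed streams fanned out of a single global seed (SHA-256 of
stage/component name + seed), so every stage is independently reproducible
and bit-identical across reruns.

## Evaluation

Stratified k-fold (k = 5 by default) with a fresh model per fold; test
indices are asserted disjoint from the training split. Balanced accuracy is
the mean of per-class recalls; "balanced F1" is macro-averaged F1 (the
natural reading consistent with balanced accuracy under the 10% gate's
imbalance); cross-fold aggregation is arithmetic mean ± SD. Fold splitting
and metric arithmetic are delegated to scikit-learn; t-SNE or UMAP of the
exported latent matrices is left to standard libraries and is not a tested
computation.

## Problem sizes in the test suite

The recovery experiments run at desk scale, chosen once as the smallest
sizes at which the effects are unambiguous: 400 cells, 10×16×16 SSC volumes
and 16×16 transmission images, channels (4, 8, 16), latent 16 per branch,
30 epochs with a 4-epoch reconstruction pre-phase (the 150/20 default scaled
proportionally), batch 4, 5-fold CV. The positive control (effect size 2,
glucose-deprivation preset) must reach ≥ 0.85 mean balanced accuracy; the
negative control (effect size 0) is evaluated on one held-out fold for each
of 5 independent simulation/training seeds — five independent chance
estimates — and their mean must lie in [0.40, 0.60].

## Known limitations

* The generator's morphology model is deliberately simple (ellipsoid +
  point scatterers); it supports method validation, not biological
  inference about real scattering patterns.
* Count-based registration cannot see within-segment permutations, and a
  single displacement consumes two segments' worth of yield.
* The numpy layer core is single-threaded and intended for desk-scale
  inputs; instrument-scale training (thousands of 3D volumes at full
  resolution) would require a GPU framework behind the same interfaces.
* Headline accuracies from instrument data are not reproducible here: the
  real images are not public, and synthetic separability is set by
  `effect_size`, not measured biology.
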