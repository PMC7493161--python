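# Methods

## Models

Each modality `m` has an autoencoder: encoder `q_m` (one hidden fully
connected ReLU layer, width = geometric mean of input and latent widths
unless overridden, then a linear map to the latent `z_m`) and a mirrored
decoder `p_m` whose final layer is a sigmoid, matching inputs scaled to
[0, 1]. Task heads consume the (fused) latent directly, with no extra
activation in between: the classifier is a single linear layer to `C`
logits; the survival head is a two-layer network (hidden width 32, ReLU)
to a scalar log relative hazard. These are the smallest architectures
consistent with the autoencoder framing and [0, 1] data; widths and
depths are configurable through `NetworkSpec`.

Latent sizes follow the convention latent ≈ input/10 (10 for 100
principal components, 100 for 1000 top-variance features). For the
784-pixel image experiments the package uses a compact latent of 32 with
a 128-unit hidden layer — wide enough to classify ten glyph classes,
small enough to train in seconds per epoch on one CPU.

Networks are implemented on a minimal seeded NumPy feedforward engine
(`omicsfuse.nn`): dense layers with uniform fan-in initialization,
explicit backward passes, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias
correction folded into the step size). All parameters are float32;
training is bit-reproducible from the seed.

## Losses

* Reconstruction: mean squared error. The batch-mean formulas leave the
  feature dimension ambiguous; we average over *all* entries
  (batch × features) so losses are comparable across modalities of
  different widths; multi-modality reconstruction losses then sum the
  per-modality means, making the relative modality weighting explicit
  (equal) rather than width-dependent.
* Classification: softmax cross-entropy
  `-x[class] + log Σ_j exp(x[j])`.
* Survival: negative log Cox partial likelihood with the Breslow
  convention — the risk set for an event at `T_i` is every sample with
  `T_j ≥ T_i` (tied event times share the full tied risk set). The loss
  is exactly shift-invariant in `h` and permutation-invariant, and is
  verified against a double-loop risk-set enumeration to 1e-10. Risk
  sets are batch-local during minibatch training; evaluation always uses
  the full split. Batches with zero observed events are skipped (the
  partial likelihood is undefined there), and training data with no
  events at all is rejected.

## Training schedules

Single-modality / ConcatAE: per epoch, one full minibatch pass updating
encoder+decoder with the reconstruction loss, then one full pass updating
encoder(s)+head with the task loss. CrossAE: three sequential phases —
(1) per-modality autoencoding, (2) cross-modality reconstruction
(`p₂(z₁) → x₂`, `p₁(z₂) → x₁`), (3) task training on averaged latents —
with budgets `epochs_per_cross_step`, default (100, 100, 200): the
representation phases split the 200-epoch task budget equally. An
interleaved schedule (one epoch of each phase per cycle) is available as
an option; phase order within the defaults was the main genuinely open
design choice. Cross-modality training currently supports two modalities
(the fusion ops accept more).

Defaults: Adam, learning rate 0.001, 200 epochs, batch 32 for
classification and 128 for survival. When a validation split is supplied,
the checkpoint with the best validation metric (accuracy or C-index) is
restored at the end; test data never influences selection.

## Preprocessing and cross-validation

The pipeline for omics matrices: remove features with any missing value →
`log2(x+1)` for expression-like modalities only → min-max to [0, 1] →
top-k variance selection (default k = 1000, ties to the lower index) or
PCA (default 100 components, components sign-fixed so the
largest-magnitude loading is positive). Every transform is fitted on
training rows only and refitted per fold. Out-of-range values on
validation/test after min-max are kept by default (an optional clip flag
exists); constant training features map to 0. Because PCA scores are not
confined to [0, 1], the pipeline min-max rescales them (train-fitted)
before the sigmoid-output autoencoder.

Splitting is stratified four-fold 60/15/25: the four test sets (25%)
partition the cohort; the remaining 75% is split 60/15 of the total into
train/validation, stratified by class label (classification) or event
indicator (survival).

## Synthetic data

**Two-view images.** Ten glyph classes are drawn as connected random
polylines (4 strokes) on a 28×28 canvas from a fixed class-keyed
alphabet; per sample the stroke endpoints are jittered (σ = 1.8 px), the
glyph translated (±2 px), smoothed (Gaussian σ = 0.7), intensity-scaled
and lightly speckled. The jitter level is set so a linear classifier
reaches ~0.95 on clean glyphs but corruption leaves real headroom
(≈ 0.75 single-view accuracy under erasing, ≈ 0.88 under Gaussian
noise) — the regime where integration can help. View 1 is the glyph,
view 2 its 90° counter-clockwise rotation; each view is *independently*
corrupted once at creation time (static noise). Random erasing fills one
rectangle (area fraction uniform in [0.1, 0.3], aspect ratio in
[0.5, 2], fill 0) — visible but non-destructive occlusion; Gaussian
noise adds i.i.d. N(0, 0.3²) per pixel with clipping to [0, 1]. Erasing
removes *different* information from the two views (a complementary
regime favoring ConcatAE); Gaussian noise corrupts both views globally
(a consensus regime favoring CrossAE).

**Multi-omics survival.** Standard-normal latent factors `u_shared`
(common) and `u_unique,m` (per modality); modality `m` observes
`[u_shared, u_unique,m] · L_m / √d + N(0, noise_sd²)`, min-max scaled.
True risk = `effect_shared (w_s·u_shared) + effect_unique Σ_m
(w_m·u_unique,m)` with fixed unit-norm weights, so effect = 1 gives risk
of unit variance per term. Event times are exponential with rate
`baseline_hazard · exp(risk)` (0.001/day at risk 0, i.e. median survival
around two years); censoring times are exponential with the rate solved
by root-finding so the expected censored fraction matches the target
(default 0.3, in the range typical of cohort overall-survival data). The
returned true risk gives an oracle C-index upper reference.

What the generators do *not* emulate: platform artifacts (probe
chemistry, FPKM/RPM biases), discrete copy-number states, non-linear
factor-to-feature maps, informative censoring, or MNIST pixel
statistics. Passing tests therefore demonstrate correctness of the
machinery and the qualitative complementary/consensus behavior, not
clinical performance on real cohorts. A loader hook (`make_two_view`
accepts any image array in [0, 1]) lets users substitute real image or
omics data.

## Problem sizes and numerical choices

Shipped experiment protocols use 2,000 train / 500 test images with 50
task epochs, and n = 600 omics samples (200 features per modality,
latent 20) with 150 epochs — sizes chosen so each experiment family runs
in minutes on a single CPU while the integration contrasts remain
clearly resolved. The consensus-distance analysis uses n = 400,
latent 10.

Degenerate inputs: empty images, zero-area erasing patches, σ = 0 noise,
constant features, all-censored splits and zero-event batches are all
defined or rejected explicitly (see the respective docstrings). C-index
hazard ties count ½ (Harrell); variance ties select the lower feature
index; PCA uses the deterministic sign convention above.

## Known limitations

* Cross-modality training is implemented for two modalities.
* No L1/L2 regularization on network weights; no Efron tie correction in
  the Cox loss.
* Supervised feature selection (mRMR, mutual information) and
  decision-level integration are out of scope.
* The survival head's calibration is not assessed (only ranking via
  C-index); time-dependent metrics are not implemented.
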