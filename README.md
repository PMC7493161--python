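# omicsfuse

Feature-level integration of multi-modality data with autoencoders, for
multi-class classification and survival-risk regression on
high-dimensional omics.

## The problem

Cancer cohorts such as breast-cancer studies increasingly profile each
patient on several omics platforms at once — gene expression, DNA
methylation, miRNA expression, copy-number variation. Each modality is a
wide continuous matrix (samples × features) carrying partly *unique*
(complementary) and partly *shared* (consensus) information about outcome.
`omicsfuse` implements two feature-level integration strategies for such
data, built from per-modality autoencoders (encoder `q(x) → z`, decoder
`p(z) → x̂`) plus a task head on the hidden feature `z`:

* **ConcatAE** (complementary principle): train an independent autoencoder
  per modality, concatenate the hidden features `[z₁, z₂]` and feed the
  concatenation to the task head, preserving modality-unique signal.
* **CrossAE** (consensus principle): after per-modality pre-training,
  train the encoders/decoders with *cross-modality reconstruction* —
  `x̂₂₁ = p₂(z₁)` and `x̂₁₂ = p₁(z₂)` — so the latents become
  modality-invariant, then feed the element-wise average `(z₁+z₂)/2` to
  the task head.

Two task endpoints are provided. Classification minimizes softmax
cross-entropy. Survival regression replaces the linear Cox proportional
hazards model with a network `s(z)` producing a log relative hazard `h`,
trained with the negative log partial likelihood

```
L_sur = -(1/N_ob) Σ_{i: C_i=1} ( h_i - log Σ_{j: T_j ≥ T_i} exp(h_j) )
```

and evaluated by Harrell's concordance index
`C = Pr{h_i > h_j | T_i < T_j, C_i = 1}` (ties in `h` count ½).

Because real cohort data cannot be redistributed, the package ships two
fully seeded generators that reproduce the study conditions end to end: a
two-view image benchmark (glyph + 90° counter-clockwise rotation, each
view independently corrupted by random erasing or pixel-wise Gaussian
noise) and a latent-factor multi-omics survival simulator with
controllable shared/unique signal and a known true risk.

## Worked example

```python
from omicsfuse import (SyntheticOmicsConfig, simulate_omics_survival,
                       TrainConfig, run_cross_validation)

mats, survival, true_risk = simulate_omics_survival(
    SyntheticOmicsConfig(n_samples=600, features_per_modality=(200, 200),
                         effect_shared=1.0, censoring_fraction=0.3, seed=7))

result = run_cross_validation(
    mats, integration="concat", survival=survival,
    feature_mode="pca", n_components=50, latent_dim=10,
    config=TrainConfig(endpoint="survival", epochs=60, seed=7), seed=7)
print(result.reports["c_index"])
```

prints

```
0.715 ± 0.02
```

the mean ± standard deviation of the test concordance index over the four
stratified folds (60% train / 15% validation / 25% test each; transforms
and checkpoints are selected using training and validation data only).
A C-index of 0.5 is random ranking, 1.0 perfect; here the ConcatAE
survival network recovers most of the simulated prognostic signal.

The same pipeline is available from the shell:

```sh
omicsfuse simulate omics --n 600 --modalities 2 --seed 7 --out data/
omicsfuse train --modality data/m1.csv --modality data/m2.csv \
    --survival-file data/survival.csv --integration concat \
    --features pca --n-components 50 --latent-dim 10 --epochs 60 \
    --seed 7 --out runs/concat
omicsfuse evaluate --run-dir runs/concat --fold 0
```

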