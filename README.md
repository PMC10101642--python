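# tgand

Risk stratification of breast-cancer transcriptome cohorts with a
**trained-GAN-discriminator classifier (T-GAN-D)**.

Bulk transcriptome cohorts pair tens of thousands of transcripts with at
most a few thousand patients, which makes directly trained deep classifiers
prone to overfitting. This package implements a data-augmentation route
around that imbalance: patient expression profiles are embedded as square
images and used to train an auxiliary-classifier Wasserstein GAN with
gradient penalty (AC-WGAN-GP). During the adversarial game the
discriminator (critic) is exposed, every epoch, to real profiles and to
synthetic profiles of hypothetical patients drawn per risk class by the
generator. After training, the discriminator is **frozen** and its
auxiliary softmax head is reused, transfer-learning style, as a standalone
classifier separating low- from high-risk patients (composite endpoint:
disease-specific death, locoregional/distant recurrence or progression
within 10 years of diagnosis). Stratification quality is evaluated with
pooled 5-fold cross-validated survival analysis: Kaplan–Meier curves,
log-rank tests, areas between curves, Cox hazard ratios and confusion
metrics.

The package is aimed at computational-biology groups who want to reproduce
or extend this training scheme on their own cohorts, or to benchmark it
against conventional CNNs on synthetic data with known ground truth.

## Method sketch

- **Cross-platform integration** — expression is rescaled gene-wise so that
  each gene's 2.5th percentile maps to −1 and its 97.5th to +1, making a
  microarray cohort and an RNA-seq cohort comparable; cohorts are merged on
  shared genes (genes missing in more than 5 patients are dropped, patients
  with remaining gaps excluded).
- **Image embedding** — the m rescaled values fill, row-major, the smallest
  square grid whose side is a multiple of 8 and whose area holds all genes
  (m = 18543 → 144×144 from an 18×18 seed grid; m = 14042 → 120×120 from
  15×15); surplus cells get Uniform(−1, 1) noise, fixed per patient.
- **AC-WGAN-GP** — generator: latent z (size 250) + class embedding →
  dense seed grid → three stride-2 transposed convolutions (batch norm,
  LeakyReLU) → single-filter smoothing convolution → tanh. Critic: stride-2
  convolutional trunk, *no* normalisation, with two heads — a linear
  Wasserstein score and class logits. Losses: Wasserstein difference +
  λ·(‖∇x̂ score‖−1)² on real/fake interpolates (λ = 10) + auxiliary
  cross-entropy. RMSprop (lr 5·10⁻⁵) for both networks; critic-only
  warm-up epochs precede the adversarial run.
- **Evaluation** — native Kaplan–Meier and log-rank implementations
  (oracle-tested), lifelines-backed Cox models, and a pooled-CV driver in
  which each patient is predicted exactly once by a model that never saw it.

Everything is importable as scikit-learn-style estimators
(`TGanDClassifier`, `BenchmarkCNN`) that compose with sklearn model
selection, plus module-level functions for each pipeline stage.

## Worked example

Simulate a two-class cohort (informative genes carry a mean shift; event
hazards differ by class), embed it and run the full pooled cross-validated
stratification at desk scale:

```python
import numpy as np
from tgand import (SynthConfig, simulate_cohort, to_risk_labeled, plan_layout,
                   cohort_to_images, TGanDClassifier, SurvivalData,
                   make_cv_plan, crossval_pool)

cfg = SynthConfig(n=120, m=200, n_informative=48, delta=3.0, seed=0)
labeled = to_risk_labeled(simulate_cohort(cfg))
layout = plan_layout(labeled.expression.gene_ids)
X, y, patients = cohort_to_images(labeled, layout, run_seed=0)

times = np.array([labeled.survival[p][0] for p in patients])
events = np.array([labeled.survival[p][1] for p in patients])
clf = TGanDClassifier(epochs=150, batch_size=32, z_dim=64, label_embed_dim=16,
                      gen_filters=(8, 4), critic_filters=(8, 16),
                      aux_on_fake=False, critic_steps_per_gen=3, random_state=0)
report = crossval_pool(X, y, SurvivalData(times, events),
                       make_cv_plan(y, k=5, seed=0), clf, patient_ids=patients)

print(f"layout: {layout.m} genes -> {layout.side}x{layout.side} image "
      f"({layout.start_side}x{layout.start_side} seed grid, "
      f"{len(layout.pad_indices)} noise pads)")
print(f"images: {X.shape}, {int(y.sum())} high-risk of {len(y)}")
print(f"pooled accuracy:  {report.accuracy:.3f}")
print(f"sensitivity:      {report.sensitivity:.3f}")
print(f"specificity:      {report.specificity:.3f}")
print(f"log-rank chi2:    {report.logrank_chi2:.1f}  (p = {report.logrank_p:.3g})")
print(f"ABC (months):     ({report.abc[0]:.1f}, {report.abc[1]:.1f}, {report.abc[2]:.1f})")
hr = report.hazard_ratio["covariates"]["predicted_high"]
print(f"hazard ratio:     {hr['hr']:.2f}  [95% CI {hr['ci_low']:.2f}-{hr['ci_high']:.2f}]")
```

Output (about two minutes on one CPU):

```
layout: 200 genes -> 16x16 image (2x2 seed grid, 56 noise pads)
images: (120, 16, 16), 57 high-risk of 120
pooled accuracy:  0.850
sensitivity:      0.702
specificity:      0.984
log-rank chi2:    77.8  (p = 1.17e-18)
ABC (months):     (22.5, 74.6, 3.9)
hazard ratio:     8.81  [95% CI 5.00-15.53]
```

Reading the numbers: each of the 120 patients was classified once by a
discriminator trained on the other four folds. The predicted groups
separate sharply in survival (log-rank p ≈ 10⁻¹⁸); predicted-high patients
face an 8.8-fold hazard of the composite event. The ABC triple gives the
areas (in months of 10-year restricted survival) between the true-low and
predicted-low curves, the two predicted curves, and the predicted-high and
true-high curves, top to bottom: a large middle value with small outer
values means the predicted stratification closely tracks the true one.

A CNN baseline (`BenchmarkCNN`) accepts the same images and identical CV
splits, and `augment_with_synthetic` extends a training fold with n×2
generator samples.

There is also a small CLI:

```bash
tgand simulate --config synth.yaml --out data/
tgand train-gan --images data/images.h5 --epochs 1000 --seed 1 --out gan.npz
tgand evaluate --predictions preds.csv --clinical clin.csv --out report.json
```

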