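# Methods

This note records the models, parameter choices and numerical conventions
behind `tgand`, and what the synthetic-data experiments do and do not
establish.

## Cohort integration and risk labelling

Expression matrices arrive platform-normalised (e.g. median Z-scores per
gene). To make two platforms comparable, each gene row is mapped affinely
so that its 2.5th percentile becomes −1 and its 97.5th percentile becomes
+1. Quantiles are linear-interpolation quantiles over the gene's
non-missing values — a convention had to be fixed, and this is the common
default. The transform is applied **per gene and per cohort, before
merging**: gene-wise scaling is what removes per-gene platform effects
(scale and offset differences between, say, a bead microarray and RNA-seq
quantification); a matrix-wide rescaling would leave per-gene effects in
place. Values outside the percentile window intentionally land outside
[−1, 1] — the transform stays invertible; the bounded range is only
enforced when images are built. A constant gene row has no percentile
spread and is a hard error naming the gene.

Merging keeps genes present in both cohorts with at most
`max_missing_patients = 5` missing values across the concatenated patient
axis, then removes any patient still missing a retained gene (the removal
is logged patient by patient).

Risk labels implement a 10-year composite endpoint, with 10 years carried
as 120 months throughout (day-scaled inputs should be divided by 30.44
before entry). A patient is HIGH if any qualifying event — disease-specific
death, locoregional recurrence, distant recurrence, or progression — is
recorded **strictly before** 120 months; an event at exactly 120 months is
not "before 10 years". LOW requires no qualifying event and at least 120
months of follow-up; otherwise the patient is ineligible and excluded.
The qualifying-event set is configurable per cohort (`"mb"`: death +
locoregional + distant; `"tcga"`: those plus progression; default
`"union"`), since endpoint availability differs between cohorts.
Normal-like intrinsic-subtype samples are excluded before labelling.

## Image embedding

The generator upsamples its seed grid by a factor of 8 (three stride-2
stages), so a profile of m genes is embedded in the smallest square whose
side is a multiple of 8 and whose area is ≥ m. This reproduces the two
published geometries (18543 → 144×144 from 18×18; 14042 → 120×120 from
15×15) and fixes the layout for any other gene universe.

Genes fill the grid row-major in lexicographic symbol order. No biological
ordering is imposed — adjacency in the image carries no meaning — and a
canonical order makes runs reproducible regardless of input file ordering
(`order="given"` preserves caller order when that is wanted). Expression is
clipped to [−1, 1] at this point so that gene cells, pad cells and
generator output share one bounded range; unbounded pixels would hand the
critic class-irrelevant scale cues. Trailing cells are filled with
Uniform(−1, 1) draws. Pads are drawn **once per patient per run** — seeded
by `run_seed XOR crc32(patient_id)` — and reused across epochs, which makes
training fully deterministic given a seed; resampling pads each epoch would
inject per-epoch noise with no compensating benefit at this scale.

## AC-WGAN-GP

**Generator.** Latent z (default 250) concatenated with a learned class
embedding (size 50) → dense projection to the seed grid → three stride-2
transposed convolutions (kernel 4, padding 1, each batch-normalised with
LeakyReLU 0.2) → a single-filter stride-1 3×3 smoothing convolution → tanh.
Default channel widths (128, 64) along the path.

**Critic.** Two stride-2 convolutions (kernel 4, widths 64 → 128, LeakyReLU
0.2, **no normalisation anywhere** — batch statistics would break the
per-sample gradient penalty and destabilise training), flattened into two
heads sharing the trunk: a linear Wasserstein score and two-class logits.

**Losses.** Critic: `mean score(fake) − mean score(real) + gp + aux`,
where `gp = λ·E[(‖∇x̂ score(x̂)‖₂ − 1)²]` on per-sample interpolates
x̂ = ε·real + (1−ε)·fake, ε ~ U(0,1), with λ = 10 (the standard
gradient-penalty coefficient), and `aux` is the cross-entropy of the
auxiliary head on real samples plus, by default, on fake samples against
their conditioning labels (the standard auxiliary-classifier formulation,
weight 1 per term; `aux_on_fake=False` disables the fake term). Generator:
`−mean score(fake) + cross-entropy(aux head on fakes, conditioning
labels)`. The norm inside the penalty carries a 10⁻¹² floor to keep its
derivative finite at zero gradient.

**Optimisation.** RMSprop (decay 0.9, lr 5·10⁻⁵ — the classic WGAN
setting) for both networks; batch 32 with final partial batches kept.
Each run starts with `warmup_runs = 3` critic-only epochs, the generator
frozen at initialisation; the interpretation of the warm-up as whole
epochs is the default, with the per-step alternative (`critic_steps_per_gen
= n`) available and used in the scaled experiments (below). Default
training length is 1000 epochs. All randomness — both initialisations,
batch order, z draws, interpolation ε, conditioning labels — derives from
one seed, and two runs with equal seed and data are bit-identical.
Non-finite losses abort with epoch/step context rather than training
through NaNs.

Because no deep-learning framework is part of the dependency set, the
networks run on `tgand._autodiff`, a compact reverse-mode engine over NumPy
whose primitives implement their vector-Jacobian products in terms of other
primitives; gradients are therefore differentiable again
(`create_graph=True`), which is exactly what optimising the gradient
penalty requires. The convolution family (forward, input-gradient,
weight-gradient) is closed under differentiation; batch normalisation is a
fused first-order primitive (it raises if differentiated twice — only the
generator uses it, and nothing differentiates through the generator twice).
The engine is validated against central finite differences, including the
double-backprop path.

## Classification

`tgand_predict` freezes the trained critic (parameter digests are compared
before and after every call) and computes P(HIGH) as the softmax of the
auxiliary head. The decision threshold is 0.5 with **ties predicting
HIGH**: in prognostication, sending an uncertain case to the alert class is
the conservative choice. `BenchmarkCNN` mirrors the critic's trunk shape
with batch normalisation and ReLU, a softmax head, cross-entropy loss and a
fixed default length of 1250 epochs — the comparison to the GAN-trained
discriminator then isolates the training procedure rather than the
architecture. `augment_with_synthetic` appends `multiplier × n` generator
samples to a training fold, with synthetic class counts following the real
fold's class proportions (prevalence is preserved; the labels are the
generator's conditioning classes).

## Survival evaluation

Kaplan–Meier estimation and the two-group log-rank test are implemented
natively — they carry the pipeline's headline statistics, and a from-
scratch implementation can be asserted equal to brute-force risk-set
enumerations on exhaustive small tables (the test suite does this on
hundreds of random datasets, and checks the log-rank p against a
2000-permutation null). All KM/log-rank/area computations truncate
follow-up at 120 months: later events count as censoring at the horizon.
The ABC statistic is the ordered triple of differences between exact
step-function integrals of the four KM curves (true-low − predicted-low,
predicted-low − predicted-high, predicted-high − true-high); its components
telescope to AUC(true-low) − AUC(true-high) by construction. Cox models
delegate to lifelines' `CoxPHFitter` (Breslow ties) — a standard fit there
is no reason to reimplement — with Wald 95% CIs on exponentiated
coefficients and an explicit `converged` flag instead of silent failures.

Cross-validation uses stratified folds by default (the risk classes are
imbalanced in realistic cohorts, and small cohorts can otherwise produce
single-class folds); plain random folds are available via a flag. The
pooled driver fits a fresh clone per fold — optionally adding a second
cohort to every training set — predicts the held-out fold, and asserts that
the pooled table contains each target patient exactly once. Per-fold
seeds derive deterministically from the plan seed. p-values are reported at
full floating precision with no multiple-testing correction.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
two risk classes (prevalence 0.5) whose `n_informative` genes carry a mean
shift of `delta` (±delta/2 by class) against N(0, sigma²) noise;
exponential event times with class-specific monthly hazards; and a second
cohort produced by per-gene affine platform distortion (scale U(0.6, 1.6),
offset U(−0.5, 0.5)) plus fresh N(0, 0.1²) measurement noise. High-risk
patients draw their qualifying event from the exponential **conditioned**
on landing before 120 months (inverse-CDF sampling keeps the distribution
smooth, rather than clipping at the horizon); the event type is drawn
uniformly from the four qualifying kinds, and non-fatal events carry
continued follow-up. Low-risk patients are event-free with follow-up
U(120, 240) months; 15% of them carry a post-horizon event, which
exercises the strictness of the 10-year rule. By construction,
re-deriving labels from the generated clinical records reproduces the
ground truth exactly — the test suite asserts this.

The default study condition is n = 300 patients, m = 512 genes (image side
24), delta = 2, sigma = 1, 64 informative genes, hazards 0.05 vs 0.005 per
month. What the generator does **not** model: realistic microarray/RNA-seq
noise spectra, gene–gene correlation, subtype structure, or batch effects
beyond per-gene affine shifts. Tests passing on this data show that the
pipeline recovers class structure a linear model can also see and that no
stage destroys it — they do not certify performance on real cohorts, where
the signal is far weaker and correlated.

## Desk-scale experiment configuration

The end-to-end experiments (5-fold pooled CV × 3 dataset seeds, 150 epochs
per fold) run on one CPU in a few minutes with `scaled_config()`: widths
(8, 4) generator / (8, 16) critic, z = 64, class embedding 16, batch 32,
lr 5·10⁻⁵, three critic steps per generator step, auxiliary cross-entropy
on real samples only. The last two choices are deliberate departures from
the full-scale defaults, made for short training runs: with a 1:1 step
ratio at 150 epochs the growing Wasserstein term progressively erodes the
shared trunk that the class head depends on (fold accuracy was observed to
peak near epoch 60 and decay afterwards), while the n-critic regime —
standard in Wasserstein-GAN training — keeps the critic near-optimal and
stable; and early-training fakes carry no class information, so their
auxiliary term only injects label noise into a short run. At the
full-scale defaults (1000 epochs, 1:1 stepping, auxiliary loss on both) the
same code path is stable, and small-image experiments with ~600 epochs
reach perfect conditioning fidelity: class-conditional generated profiles
are assigned to their conditioning class by an independently trained
logistic model.

Under the default study condition this configuration attains pooled
accuracies around 0.9 with log-rank p-values far below 0.01 (the test
suite recomputes these, not this note).

## Known limitations

- Pure-NumPy training is single-threaded and practical up to roughly
  side-24 images and a few hundred patients; full-scale runs (144×144,
  1000 epochs) are expressible but slow.
- The critic's published layer widths are not recoverable from the
  architecture description, so printed parameter totals cannot be matched;
  widths are configuration, not contract.
- Batch normalisation supports first-order gradients only (fused VJP); it
  must not be placed in any network that is differentiated twice — the
  critic therefore cannot contain it, which coincides with the design
  requirement.
- Cox fits near complete separation return infinite CI bounds (flagged,
  not silenced).
- No competing-risks modelling; censoring is treated as non-informative.
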