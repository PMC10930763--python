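# Methods

## Problem setting

A whole-slide image is represented as a bag of patch feature vectors with a
single continuous label per bag (a gene's expression in that sample, or the
sample's survival outcome). The package's pipeline mirrors the
surrogate-biomarker study design: (1) screen candidate genes for prognostic
value on measured expression; (2) learn to predict each prognostic gene's
expression from the image bags under confounder-aware cross-validation;
(3) evaluate whether the *predicted* expression carries the same prognostic
information as the measured one; (4) deploy the best model on an external
cohort and stratify patients into risk groups.

## Attention-based MIL regressor

Architecture per bag: patch embedding `D → 256` (single linear layer +
ReLU); attention scores `a_k = softmax_k(wᵀ tanh(V h_k))` with
`V ∈ R^{128×256}`, `w ∈ R^{128}` and no biases in the attention module (the
score definition has none); pooled representation `h_sum = Σ a_k h_k`;
head = batch normalization → dropout → linear → output activation. The
logistic output keeps expression predictions in (0, 1), matching min–max
scaled targets; survival risk scores use an identity output (a Cox partial
likelihood is shift-invariant, so an unbounded score is the natural scale).
A softmax over the single output unit would be constant and is therefore
not meaningful; the logistic function is the one-dimensional analogue.

Implementation is plain NumPy with hand-derived gradients (verified against
central finite differences to ~1e-7 relative error in the test suite) and
an Adam optimizer. At the bag sizes this package targets, a forward/backward
pass is a few small matrix products, so no deep-learning framework is
needed; inference uses stored batch-norm statistics and no dropout and is
deterministic and independent of batch composition.

### Losses

* Balanced MSE `(1/N) Σ w_i (y_i − ŷ_i)²`. The weights are not pinned down
  by the loss definition itself; we use inverse-frequency weights over 10
  equal-width bins of the scaled target, normalized so `mean(w) = 1`
  (uniform occupancy ⇒ plain MSE). Bin count is configurable.
* Cox loss: negative Breslow partial log-likelihood averaged over events,
  risk sets `{j : t_j ≥ t_i}`. During minibatch training the risk sets are
  formed within each minibatch — the standard stochastic approximation —
  and all-censored minibatches are skipped (an all-censored *training set*
  is an error).

### Training schedules

`TrainConfig()` defaults to the reference regime: 25 epochs, minibatches of
64 bags, at most 512 patches subsampled per bag per epoch (redrawn each
epoch, no replacement), dropout 0.5, Adam at 1e-4. Those values are
calibrated for cohorts of ~460 samples with 768-d pretrained patch features.

For the synthetic scale this package tests at (n = 200 bags, 32-d features,
64 patches per bag) that schedule yields only ~75 optimizer steps, and
dropout 0.5 on the pooled 256-d representation injects noise that is large
relative to the low-dimensional planted signal. Empirically the attention
module then either stays uniform or, with longer training, converges to
degenerate optima (winner-take-all on one informative patch, or one-sided
scoring that ranks half the informative patches below noise) — the bag
prediction stays accurate, but attention is no longer interpretable.
`amil.small_cohort_config()` (75 epochs, Adam 3e-3, dropout 0) is the
package's schedule for such cohorts; under it the attention converges to
even, positive selection of the informative patches (ranking AUC
≳ 0.9 across cohort seeds) while held-out R stays ≥ 0.9. Examples, tests
and the acceptance script use this preset on synthetic cohorts.

### Scaling and inversion

Expression targets are min–max scaled on the *training* data only; the
(min, max) pair is stored with the parameters and inverted on request
(`predict(..., inverse_transform=True)`). For external deployment the
training-cohort scaler is the default inverse; correlation metrics are
scale-invariant either way.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, so every
downstream claim is checkable against ground truth:

* **Expression** — per-gene Gaussian with gene-specific mean (N(10, 3)) and
  sd (U(0.5, 2)). The location/scale are arbitrary (downstream stages
  standardize per gene); the Gaussian is a neutral stand-in, not a claim
  about processed RNA-seq distributions.
* **Bags** — `round(informative_fraction·K)` patches per bag have their
  mean shifted along the gene's signal direction by the sample's
  standardized expression; the directions are orthonormal across genes;
  remaining patches are isotropic N(0, noise_sd²). With zero noise and all
  patches informative, the per-patch projection equals the standardized
  expression exactly. An external cohort reuses the signal directions
  (shared biology) with fresh samples.
* **Sites** — contiguous blocks with unequal sizes from a flat Dirichlet
  (largest-remainder rounding, minimum one sample), making fold balancing
  non-trivial, as in multi-centre archives.
* **Survival** — Weibull-baseline Cox model (scale 60 months, shape 1.2) on
  standardized expression plus (age−65)/10, sex ∈ {0,1} and ordinal
  stage−1; event times by inverse-transform sampling; independent
  exponential censoring whose rate is bisected deterministically so the
  realized censoring fraction hits the configured rate. Defaults: one
  harmful gene (β = 1), mild covariate effects (0.2/0.1/0.3), 30% censoring.
* **Tiles** — 224×224 RGB fixtures: uniform background, sharp two-stain
  tissue (nuclei-like haematoxylin blobs over smooth eosin fields, mixed
  through unit-norm H/E optical-density vectors, with a dye-saturation cap
  so normalization cannot blow out dark nuclei), a Gaussian-blurred copy,
  and a checkerboard. Optional OD noise for robustness checks.

What the generator does **not** emulate: real H&E texture and morphology,
RNA-seq count distributions, batch effects correlated with site, multiple
slides per patient, or informative censoring. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure — not clinical performance on real cohorts.

## Preprocessing

Non-overlapping 224×224 tiling (partial border tiles dropped; optional
resampling to 0.5 µm/px when source resolution is given). Tiles are
rejected when their Canny edge percentage is ≤ 2% (the edge threshold is
read as a percentage of pixels; hysteresis thresholds default to 50/150 on
8-bit grayscale). Brightness is standardized by mapping the 90th-percentile
luminance to 240 (a near-black tile is returned unchanged with a warning).
Macenko normalization works in optical density `OD = −log10((I+1)/256)`:
pixels above 0.15 OD in every channel are the tissue set; the top-2
eigenvectors of their covariance span the stain plane; the 1st/99th
percentile extreme angles give the stain vectors (haematoxylin first,
identified by its larger red-channel OD — the blue-purple dye absorbs red);
concentrations are solved by exact two-column nonnegative least squares.
The 99th-percentile reference concentrations are computed over **all**
pixels: that population is invariant under re-rendering, which makes
re-normalizing an already-normalized tile a near-identity (≤ 2 intensity
levels on the synthetic fixtures). Patch embedding is a pluggable callable;
built-ins are a channel-wise mean/sd summary and a passthrough for bags
already in feature form. No pyramidal WSI parsing and no learned feature
extractor are included.

## Fold assignment

Samples are binned into 5 quantiles of the target (survival targets:
quantile edges from uncensored samples only; censored samples binned by
censoring time against the same edges). Sites are then assigned to folds to
minimize `Σ_folds Σ_bins (count − total/5)²` under the hard constraint that
a site never spans folds. Instances with ≤ 10 sites are solved exactly by
vectorized enumeration (one site pinned to fold 0 by label symmetry);
larger instances by ≥ 100-restart seeded local search over single-site
moves, which matches the exhaustive optimum on every instance small enough
to verify and is never worse than a size-sorted round-robin baseline. The
achieved objective is reported so solver-grade solutions can be compared.

## Survival statistics

Cox models maximize the Breslow partial likelihood (statsmodels `PHReg`),
with Wald 95% CIs; "CI excludes β = 0" and "HR CI excludes 1" are the same
criterion on two scales and are implemented once on the β scale. Constant
covariates are structurally uninformative and reported as β = 0 with
infinite SE rather than an error; monotone likelihood is flagged
(`separation_flag`) and a singular information matrix raises. The PH
diagnostic is the scaled-Schoenfeld correlation test against rank-
transformed event times; its empirical type-I error is verified at ~5% over
500 null simulations. Harrell's C uses standard tie handling (score ties
count ½; event-vs-censored at the same time is orderable, two events at the
same time are not). The 1-D two-cluster cutoff is solved exactly by
scanning sorted split points (the optimal 2-means solution in one dimension
is a threshold), with the cutoff at the midpoint of the two cluster means.
Stage enters Cox models ordinally (1–4); BH adjustment is the step-up
procedure (note it is *not* idempotent in general, so that is not claimed).

## Pipeline gates and evaluation protocol

Screen: per gene, Cox on (standardized expression, age, sex, stage); genes
whose PH test rejects at 0.05 are excluded before BH; prognostic ⇔ CI
excludes the null and adjusted p < 0.05. Predictability gate: cross-
validated Pearson R (mean over held-out folds) > 0.4; per-gene folds are
balanced on that gene's own expression. Surrogate evaluation: per fold, a
univariate Cox model fitted on *real* training-fold expression scores the
*predicted* test-fold expression; mean ± sd C-index over folds, plus an
adjusted Cox model on the CV-aggregated predictions for the significance
gate. External validation: the fold model with the highest held-out R (ties
→ lowest fold index) predicts the external cohort; requires external
R > 0.4, a significant adjusted Cox fit, and a passing PH test; external
p-values are reported raw (BH across externally tested genes can be applied
by the caller — both views are defensible and the table carries the raw
values). The direct-survival benchmark trains the Cox-loss model on the
same bags and folds, so surrogate-vs-direct is a controlled comparison.

## Numerical choices and limitations

Softmax scores are computed with max-subtraction; the Cox loss uses
log-sum-exp; batch-norm ε = 1e-5; running statistics use momentum 0.1;
minibatches of one bag are skipped (batch norm undefined); k-means split
points between equal values are invalid by construction; fold-label
permutation symmetry is broken by pinning the largest site. All randomness
flows through `numpy.random.default_rng` seeded substreams, so every
generator, training run and fold assignment is bitwise reproducible given
its seed. Known limitations: no GPU path, no learned feature extractor, no
time-varying-coefficient Cox models or Efron ties, one bag per sample, and
the synthetic cohort's simplifications listed above.
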