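# histomark

Surrogate gene-expression biomarkers from whole-slide images, with
survival evaluation.

Molecular profiling is prognostic in lung adenocarcinoma but expensive and
slow; H&E slides are routine. `histomark` implements the surrogate-biomarker
route between the two: predict the expression of prognostic genes directly
from histology with an attention-based multiple-instance-learning (AMIL)
regressor, then evaluate overall survival from the *predicted* expression —
prognostic screening with adjusted Cox models, tissue-source-site-preserved
cross-validation, cross-validated concordance of the surrogate, external
deployment of the best fold model, and low/high risk-group stratification.
A synthetic-cohort generator with planted, recoverable structure makes every
stage testable end to end without any data download.

It is intended for computational-pathology and biostatistics researchers who
want a transparent, dependency-light (NumPy/SciPy/pandas, lifelines,
statsmodels, scikit-image) reference implementation of this analysis design.

## The model

Each sample is a *bag* of K patch feature vectors $x_k \in \mathbb{R}^D$.
A one-hidden-layer MLP with ReLU embeds each patch to
$h_k \in \mathbb{R}^{256}$; attention scores

$$a_k = \frac{\exp\!\big(w^\top \tanh(V h_k)\big)}
             {\sum_{j=1}^{K}\exp\!\big(w^\top \tanh(V h_j)\big)},
\qquad V \in \mathbb{R}^{128\times256},\; w \in \mathbb{R}^{128},$$

pool the bag into $h_{\mathrm{sum}} = \sum_k a_k h_k$, and a head (batch
normalization → dropout → linear) emits one value: logistic-activated for
expression (targets min–max scaled to $[0,1]$), identity for survival risk.
Expression models minimize a balanced MSE,
$\tfrac1N\sum_i w_i\,(y_i-\hat y_i)^2$, with inverse-frequency weights over
ten equal-width target bins; survival models minimize the negative Breslow
partial log-likelihood

$$\mathcal{L}(\theta) = -\frac{1}{|S|}\sum_{i\in S}
\Big[\hat h_\theta(x_i) - \log\!\!\sum_{j:\,t_j\ge t_i}\!\! e^{\hat h_\theta(x_j)}\Big].$$

Cross-validation folds are assigned per *site* (hard constraint: no site
spans folds) minimizing the squared imbalance of target-quantile counts
across folds — exactly for small site counts, by seeded multi-start local
search otherwise. Downstream survival statistics (Cox with age/sex/stage,
Schoenfeld-residual PH diagnostics, BH correction, Harrell's C, log-rank,
Kaplan–Meier, exact 1-D 2-means cutoffs) live in `histomark.survstats`.

## Worked example

```bash
python examples/04_surrogate_survival_evaluation.py
```

runs the full evaluation on the default synthetic cohort (200 samples, one
harmful planted gene, 30% of patches informative) and prints:

```
G000: per-fold R [0.975 0.975 0.961 0.985 0.871], cross-validated R = 0.953 (passes the R > 0.4 gate)
real-expression C-index:  0.723 +/- 0.033
surrogate C-index:        0.700 +/- 0.029
direct survival-AMIL C-index: 0.603 +/- 0.061 (image-to-risk baseline, same bags)
```

Reading: the planted gene's expression is predictable from the bags
(R = 0.95, far above the 0.4 predictability gate); a Cox model fitted on
*real* expression in the training folds and scored on *predicted* expression
in the held-out fold loses only ~0.02 C-index against scoring the real
values; and the surrogate route beats the model trained to predict survival
directly from the images — the qualitative ordering this analysis design is
built to demonstrate. `examples/01`–`05` walk the individual capabilities
(simulation, tile preprocessing, model training, evaluation, external
deployment and risk stratification).

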