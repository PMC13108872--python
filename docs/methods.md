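# Methods

## Diffusion over latent embeddings

Every modality is represented as a low-dimensional latent vector
(autoencoder embeddings for omics tables, PCA for pre-embedded WSI
vectors), and all generative modelling happens in those latent spaces.
The forward process is the standard Gaussian diffusion with a fixed
variance schedule {β_t}: closed-form marginals
q(x_t | x_0) = N(√ᾱ_t x_0, (1−ᾱ_t) I) allow direct sampling of any
timestep during training, and the reverse transition uses the
ε-parameterized posterior mean with additive noise of variance β_t.

Choices the diffusion literature leaves open, resolved here:

* **Schedule.** Linear β from 1e-4 to 0.02 over T = 1000 steps by
  default (both configurable). Desk-scale runs in the tests and the
  acceptance script use T = 200 with β up to 0.05 so that the terminal
  signal retention ᾱ_T ≈ 6e-3 stays negligible — with T = 200 at the
  T = 1000 bounds, ᾱ_T ≈ 0.13 would leave a visible mean bias because
  generation starts from N(0, I).
* **Timesteps are 1-based** (t ∈ 1..T); `betas[t−1]` is the variance of
  step t.
* **Final step adds no noise**: generation ends at the posterior mean.
* **Schedule math in float64** throughout; the ᾱ recursion
  ᾱ_t = ᾱ_{t−1}·α_t holds to machine precision and is tested as such.
* **Degenerate inputs**: n = 0 sample requests return an empty matrix;
  predictor failures during the reverse loop re-raise with the step
  index attached.

A closed-form Gaussian oracle predictor
E[ε | x_t] = √(1−ᾱ_t)(ᾱ_t Σ₀ + (1−ᾱ_t) I)⁻¹(x_t − √ᾱ_t μ₀) serves as
the independent reference for the sampler: reverse diffusion driven by
it must recover the data distribution's mean and covariance within
Monte-Carlo error, which pins down the update algebra end to end.

## The noise-prediction network

A deliberately simple MLP (tabular latent vectors do not benefit from
convolutional inductive bias): input [x_t ‖ sinusoidal time embedding ‖
condition embeddings], hidden layers of linear → batch-norm → ReLU with
the time embedding re-concatenated after every hidden layer, and a
linear head back to the latent dimension. Each conditioning modality
has its own linear projection to a shared condition-embedding width; a
masked modality contributes an exact zero block, making the network's
output provably independent of whatever values a masked modality
carries (tested as exact equality). The projections are trained jointly
with the backbone.

The network, batch normalization, and the Adam optimizer are
implemented in double-precision numpy with hand-written
backpropagation. This keeps the package dependency-light and makes
training a bit-reproducible function of the seed; the backward pass is
verified against central finite differences in the test suite.
Defaults (4 hidden layers × 256, time embedding 64, condition embedding
16, learning rate 1e-3, batch 128) sit inside the ranges that a grid
search at full scale would explore; the desk-scale tests use 3 × 128.

The sinusoidal embedding uses dim/2 geometric frequencies
f_i = 10000^(−(i+1)/(dim/2)); for dim = 2 this gives the single
frequency 1/10000 (so t = 10000 maps to [sin 1, cos 1]), and every
component is bounded in [−1, 1].

## Training and early stopping

The loss is the simplified DDPM objective: mean squared error between
true and predicted noise, with t drawn uniformly per training example.
Early stopping follows *generation* quality rather than the denoising
loss: every `eval_interval` (default 100) epochs the model fully
denoises the validation set conditioned on the real validation
conditions, and the MSE against the real targets decides improvement;
training stops after `patience` (default 10) evaluations without one,
and the best checkpoint is kept. This is slower per evaluation but
selects for exactly the behaviour that matters downstream. A NaN loss
aborts with diagnostics rather than continuing silently.

Multi-condition training draws a condition subset per batch from a
configurable distribution — uniform over all 2^k subsets by default,
empty set included, which is what later enables unconditional
generation from a fully masked input. With a degenerate subset
distribution pinned to the full set, multi-condition training reduces
exactly to single-condition training (same seed, same loss trajectory);
this identity is tested.

## Coherent denoising

The ensemble generates a target modality from several single-condition
models: at each reverse step every member predicts a noise vector from
the same x_t and its own conditioning modality, and the consensus is
the weighted average with weights inversely proportional to each
member's validation reconstruction MSE. The weighted average is
computed as p₀ + Σᵢ wᵢ(pᵢ − p₀), algebraically identical (weights sum
to one) but bit-exact when members agree — so single-member and
duplicated-member ensembles reproduce plain conditional sampling
exactly.

Coherence is measured by pairwise cosine distances between member
predictions, averaged per sample with pair weights ∝ wᵢwⱼ (normalized
over pairs i < j); zero-norm predictions are treated as non-conflicting
(distance 0). A sample whose fraction of steps with mean distance above
the threshold (default 1.0) *strictly exceeds* the allowed fraction
(default 5%) is rejected: exactly at the boundary it is accepted, and
the 5-of-100 / 6-of-100 boundary is unit-tested. Rejected samples are
re-generated from a deterministically advanced seed (stride 1,000,003,
modulo 2³¹−1) up to `max_retries` times (default 5), after which the
trajectory with the smallest incoherent fraction is returned flagged as
not accepted — a generator must return something, and the flag makes
the quality judgement auditable. Rejection is decided per sample;
diagnostics report the batch-mean per-step distance and the worst
per-sample incoherent fraction.

The unconditional privacy probe feeds every ensemble member a zero
*value* as its condition (single-condition models have no masking
pathway), with rejection disabled; the multi-condition probe masks all
modalities. Note the rejection filter conditions the retained sample
set on geometric agreement, which can bias the output distribution —
the oracle-consensus test therefore disables rejection when comparing
against the closed-form blended sampler.

## Preprocessing conventions

RNA-seq arrives as log2(count+1): counts are recovered, normalized to
counts per million, re-logged, and genes kept only if CPM > 1.0
(strict) in at least 20% of samples (inclusive). CNA absolute copy
numbers become log2(v/2) clipped to [−2, 2], with zeros (undefined
under the log) treated as missing. RPPA is median-centered per protein.
Features missing in strictly more than 10% of samples are dropped;
remaining gaps are filled by KNN (k = 5, nan-aware Euclidean, the
convention RNA-seq/RPPA use) or the feature-wise training median (CNA).
All boundary conventions are unit-tested exactly.

Splitting is stratified by cancer type with largest-remainder rounding
per stratum and the test partition drawn only from samples with all
modalities observed; a stratum with too few complete samples gets a
reduced test quota with a logged warning, and the freed slots are
reabsorbed proportionally by train/validation. Scalers, imputers and
embedding models are fit exclusively on training samples —
per-feature standardization is applied before embedding, and latent
tables are standardized again on training statistics before diffusion
so that the terminal N(0, I) of the reverse process matches the data
scale. An optional robust z-score outlier filter exists but is off by
default, since no principled threshold is universal.

## Synthetic cohorts

The generator emulates the statistical regime the framework assumes, at
the latent level: samples carry one of n_types tumour types; a shared
factor s ~ N(center_type, σ_shared² I) drives every modality through
per-modality loadings, while a modality-private factor u_m (invisible
to the other modalities) and isotropic noise complete each latent:
x_m = A_m s + B_m u_m + ε. Making one modality's private variance
dominant (the "cna-like" default, σ_private = 3 versus 0.5–1 for the
others) reproduces the regime in which that modality is poorly
reconstructible cross-modally while still carrying its own signal.
Stage labels come from an ordinal threshold model on a linear score of
s (quantile cuts, so levels are balanced); survival from an exponential
proportional-hazards model with per-type baseline rates and
administrative censoring at a configurable horizon. Missingness is
MCAR per modality. Loadings, factors and noise draws are stored as
ground truth, so tests verify the generative equations exactly and
regress latents on the truth as an oracle.

What the generator does **not** emulate: gene-level count
distributions, batch effects, informative missingness, or inter-type
imbalance. Tests passing on these cohorts therefore demonstrate that
the machinery behaves as specified under its own assumptions, not that
real pan-cancer data meets those assumptions.

Two scenario constructors support specific experiments:

* the **well-separated configuration** used by the privacy probes
  (σ_shared = 0.5, noise 0.2, type centers at sd 6) puts clusters many
  within-cluster standard deviations apart, the regime in which a
  mean-collapsed unconditional probe cannot graze any cluster's k-NN
  radius and its coverage F1 is exactly zero at test scale;
* the **private-signal scenario** re-derives stage labels for a seeded
  minority of tumour types from the target modality's private factor.
  Tying the minority to *types* (observable context) rather than to
  random samples is essential: a classifier can then learn that stage
  depends on the private dimensions within those types, generated
  completions become unstable exactly there, and the counterfactual
  variance score can identify the affected patients. With a random
  per-sample minority the score has nothing observable to correlate
  with and informed acquisition cannot beat random.

## Evaluation metrics

R² is pooled over samples × features with the total sum of squares
about the real data's per-feature means, so predicting the mean scores
exactly 0 (on standardized latents this coincides with the per-feature
averaging convention). Output variance across repeated generations uses
unbiased per-sample variances, averaged and expressed as a percentage
of the real data's mean per-feature variance — i.i.d. runs matching the
real variance calibrate to 100%. Energy distance is the un-rooted
V-statistic (all ordered pairs, diagonals included), zero iff the
multisets coincide. Manifold precision/recall use k-NN radii (k = 5,
self excluded) on each support, F1 the harmonic mean with 0/0 → 0; the
implementation is checked against a brute-force radius-membership
oracle. Macro F1 averages per-class F1 over the union of observed and
predicted labels (a predicted-only class contributes 0); Harrell's C
counts risk ties as one half and is cross-checked against lifelines.

## Downstream harnesses

Downstream models are bought, not built: scikit-learn random forests
and scikit-survival random survival forests (500 trees at full scale;
150–300 in tests), both of which natively accept NaN inputs — an
ablated modality is passed as NaN feature columns, exactly the
"flagged as missing" protocol. The completion experiment reports the
drop from ablation (relative to the full-data score) and the gain from
generative completion (relative to the ablated score); with an
identity "oracle generator" returning the real data, the gain cancels
the drop exactly, an invariant the tests assert to 1e-12. A label-only
baseline (the same model on one-hot cancer type) isolates signal beyond
the type signature.

The counterfactual variance score generates N = 10 versions of a
patient's missing modality, collects the classifier's probability
vectors, and averages the across-version variance over classes
(population variance; a deterministic generator or an insensitive
classifier scores exactly 0). Prioritization curves acquire the real
modality for a growing fraction of the test set — descending score
order (ties broken by sample ID) versus a fresh random order per run —
re-generating the unacquired remainder per fraction with fixed seeds;
each run pairs one generation seed with one random order, so the
per-run curve areas are comparable head-to-head.

## Problem sizes

Desk-scale defaults throughout: latent dimension 8, T = 200, networks
of 3 × 128, cohorts of 600–2000 samples, 5–10 probe or generation runs.
These sizes keep the full test suite and the acceptance script in the
minutes range on one CPU while preserving every qualitative regime the
framework is designed around; the full-scale configuration (latent 32,
T = 1000, 4–7 × 256–1024 networks, 20,000-epoch budgets) is expressible
through the same config objects.

## Known limitations

* The consensus average is a heuristic proxy for the joint conditional
  score; a formal Bayes composition would need an unconditional term
  the ensemble deliberately avoids training.
* Coherence-based rejection conditions accepted samples on member
  agreement, slightly biasing the output distribution relative to
  unfiltered consensus sampling.
* The numpy training loop is single-threaded; it is sized for latent
  embeddings, not for raw feature spaces.
* MCAR missingness and Gaussian factor structure are idealizations;
  conclusions about informative missingness or heavy-tailed omics
  noise are out of scope.
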