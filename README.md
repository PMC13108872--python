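# coherentgen

Cross-modal generative diffusion for multi-omics data integration.

Multimodal patient cohorts — copy-number alterations (CNA), bulk
transcriptomics (RNA-seq), reverse-phase protein arrays (RPPA),
whole-slide-image (WSI) embeddings — are chronically incomplete: assays
are expensive, tissue runs out, scanners differ. `coherentgen`
synthesizes any missing modality from any subset of available ones, so
that multimodal predictive models (tumour-type and stage classifiers,
survival forests) keep working on sparse patient profiles. It is aimed
at computational-biology groups working with latent-embedded pan-cancer
cohorts and at methods researchers studying conditional generation over
tabular embeddings.

## The model

All modalities live in low-dimensional latent spaces (32-d autoencoder
or PCA embeddings). Generation uses denoising diffusion probabilistic
models (DDPMs): a fixed forward process corrupts a latent vector
*x*₀ over *T* steps,

    q(x_t | x_0) = N( √ᾱ_t x_0, (1 − ᾱ_t) I ),    ᾱ_t = ∏_{s≤t} (1 − β_s),

and an MLP ε_θ(x_t, t, C) learns to predict the injected noise given
sinusoidal time embeddings and linearly projected condition vectors C.
Reverse sampling applies

    x_{t−1} = (x_t − β_t/√(1−ᾱ_t) · ε_θ) / √α_t + √β_t z.

Two conditioning regimes are provided:

* **multi-condition** — one network per target modality accepts any
  subset of conditioning modalities; absent modalities have their
  projected activations zeroed (masking), and training draws random
  condition subsets (the empty set included), which also teaches the
  model unconditional generation;
* **coherent denoising** — an ensemble of independently trained
  single-condition models. At every reverse step each member predicts a
  noise vector from its own conditioning modality; the predictions are
  combined by a weighted average (weights ∝ 1/validation-MSE),

      ε_consensus = Σᵢ wᵢ ε_θᵢ(x_t, Cᵢ, t),

  and their pairwise cosine distances d_ij = 1 − cos(ε_θᵢ, ε_θⱼ) are
  monitored: a trajectory whose mean pairwise distance exceeds a
  threshold (default 1.0) on more than a small fraction of steps
  (default 5%) is rejected and re-sampled. The ensemble is modular (a
  new modality only needs new pairwise models) and privacy-preserving:
  fed null conditions it collapses to the distribution mean instead of
  regenerating the training manifold.

Downstream, the package scores reconstruction (pooled R², across-run
output variance), distributional similarity (energy distance, k-NN
manifold precision/recall/F1), classifier parity (macro F1, balanced
accuracy), survival concordance (Harrell's C), ablation-vs-completion
gains, and a counterfactual variance score that ranks patients by how
much a missing modality would change their prediction — the basis for
informed prioritization of data acquisition.

## Worked example

```python
import numpy as np
from coherentgen import (CohortConfig, ConditionSet, ConditionalDiffusion,
                         PredictorConfig, generate_cohort, make_schedule)
from coherentgen.metrics import r_squared

cohort = generate_cohort(CohortConfig(
    n_samples=2000, n_types=6,
    modality_dims={"cna": 8, "rnaseq": 8},
    missing_rates={"cna": 0.0, "rnaseq": 0.0}, seed=7))

tables = {m: df.to_numpy() for m, df in cohort.latents.items()}
std = {m: ((x - x[:1700].mean(0)) / x[:1700].std(0)) for m, x in tables.items()}
train = {m: z[:1700] for m, z in std.items()}
val = {m: z[1700:] for m, z in std.items()}

model = ConditionalDiffusion(
    train, val, target="rnaseq", conditions=["cna"],
    config=PredictorConfig(n_hidden_layers=3, hidden_size=128,
                           time_embed_dim=32, cond_embed_dim=16,
                           max_epochs=800, patience=4, eval_interval=100),
    schedule=make_schedule(200, 1e-4, 0.05))
fit = model.fit(seed=1)
print(fit.summary())

gen = fit.sample(ConditionSet({"cna": val["cna"]}), seed=9)
print("conditional R^2:", round(r_squared(val["rnaseq"], gen), 3))
```

Output from this exact script:

```
Conditional diffusion fit
================================================
target modality     : rnaseq
conditioning        : cna
masking strategy    : off
schedule            : linear, T=200, beta 0.0001..0.05
hidden layers       : 3 x 128
epochs run          : 800
best val gen MSE    : 0.339
final train loss    : 0.17431
================================================
conditional R^2: 0.663
```

The best validation MSE (0.34) is the full-generation error against the
held-out targets; the conditional R² of 0.66 says that about two thirds
of the held-out rnaseq latent variance is recovered from the cna latent
alone — the rest is modality-private signal plus noise the generator
correctly refuses to invent deterministically.

A command-line surface wraps the same pipeline
(`coherentgen simulate|preprocess|embed|train|generate|evaluate|experiment`,
each taking `--config`, `--seed`, `--out`).

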