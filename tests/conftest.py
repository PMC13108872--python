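"""Shared fixtures.

The heavy fixtures (trained diffusion models) are session-scoped so the
copy-task benchmark, the privacy probes and the ensemble identity tests
all reuse the same fits.  Every fixture is deterministic: fixed seeds,
no environment dependence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coherentgen import (
    CohortConfig,
    ConditionSet,
    ConditionalDiffusion,
    EnsembleSpec,
    PredictorConfig,
    generate_cohort,
    make_schedule,
    train_multi_condition,
    train_single_condition,
)
from coherentgen.cohort import private_signal_scenario
from coherentgen.preprocess import stratified_split

# desk-scale training configuration used by every trained-model fixture
TEST_PREDICTOR_CONFIG = PredictorConfig(
    n_hidden_layers=3,
    hidden_size=128,
    time_embed_dim=32,
    cond_embed_dim=16,
    learning_rate=1e-3,
    batch_size=128,
    max_epochs=800,
    patience=4,
    eval_interval=100,
)
TEST_SCHEDULE = make_schedule(200, 1e-4, 0.05)


@pytest.fixture(scope="session")
def copy_task_fit():
    """Single-condition model trained on the 2-D three-cluster copy task.

    The conditioning latent equals the target latent, so a correct
    conditional sampler must reproduce its input almost exactly.
    """
    rng = np.random.default_rng(0)
    centers = np.array([[2.0, 2.0], [-2.0, 1.0], [0.0, -2.5]])
    lab = rng.integers(0, 3, 700)
    X = centers[lab] + rng.standard_normal((700, 2)) * 0.3
    X = (X - X.mean(0)) / X.std(0)
    train = {"target": X[:600], "cond": X[:600]}
    val = {"target": X[600:], "cond": X[600:]}
    cfg = PredictorConfig(
        n_hidden_layers=3, hidden_size=128, time_embed_dim=32, cond_embed_dim=16,
        learning_rate=1e-3, batch_size=128, max_epochs=1500, patience=5,
        eval_interval=100,
    )
    model = ConditionalDiffusion(train, val, "target", ["cond"], cfg, TEST_SCHEDULE)
    fit = model.fit(seed=0)
    return {"fit": fit, "val": val}


@pytest.fixture(scope="session")
def privacy_setup():
    """Well-separated clustered cohort with trained multi-condition and
    single-condition models over two modalities.

    Tight within-cluster spread and wide type centers put the cohort in
    the strongly separated regime where an unconditional probe around the
    global mean cannot touch any cluster.
    """
    cfg = CohortConfig(
        n_samples=2000,
        n_types=6,
        modality_dims={"cna": 8, "rnaseq": 8},
        private_signal_sd={"cna": 3.0, "rnaseq": 0.3},
        missing_rates={"cna": 0.0, "rnaseq": 0.0},
        shared_signal_sd=0.5,
        noise_sd=0.2,
        type_center_sd=6.0,
        seed=7,
    )
    cohort = generate_cohort(cfg)
    n_tr = 1700
    tr, va = {}, {}
    for m in ("cna", "rnaseq"):
        X = cohort.latents[m].to_numpy(float)
        mu, sd = X[:n_tr].mean(0), X[:n_tr].std(0)
        Z = (X - mu) / sd
        tr[m], va[m] = Z[:n_tr], Z[n_tr:]
    multi = train_multi_condition(
        tr, va, "rnaseq", ["cna"], TEST_PREDICTOR_CONFIG, TEST_SCHEDULE, seed=1
    )
    single = train_single_condition(
        tr, va, "rnaseq", "cna", TEST_PREDICTOR_CONFIG, TEST_SCHEDULE, seed=2
    )
    ensemble = EnsembleSpec.from_checkpoints([single])
    return {
        "cohort": cohort,
        "train": tr,
        "val": va,
        "multi": multi,
        "single": single,
        "ensemble": ensemble,
        "schedule": TEST_SCHEDULE,
    }


@pytest.fixture(scope="session")
def prioritization_setup():
    """Cohort where a minority of tumour types carry modality-private
    stage signal, plus a trained multimodal stage classifier and
    counterfactual variance scores for every test sample."""
    from sklearn.ensemble import RandomForestClassifier

    from coherentgen.experiments import (
        TruthPosteriorGenerator,
        counterfactual_variance_score,
    )

    cfg = CohortConfig(
        n_samples=800,
        n_types=6,
        seed=11,
        private_signal_sd={"cna": 3.0, "rnaseq": 2.0, "rppa": 0.7, "wsi": 1.0},
        missing_rates={m: 0.0 for m in ("cna", "rnaseq", "rppa", "wsi")},
    )
    cohort = private_signal_scenario(generate_cohort(cfg), "rnaseq", fraction=0.25, seed=5)
    split = stratified_split(
        list(cohort.sample_ids),
        cohort.type_label.to_dict(),
        completeness={i: True for i in cohort.sample_ids},
        seed=3,
    )
    X_tr = pd.concat(
        [cohort.latents[m].loc[split.train_ids] for m in cohort.modalities], axis=1
    )
    clf = RandomForestClassifier(n_estimators=300, random_state=0, n_jobs=1)
    clf.fit(X_tr.to_numpy(float), cohort.stage_label.loc[split.train_ids])
    gen = TruthPosteriorGenerator(cohort)
    scores = []
    for sid in split.test_ids:
        profile = {m: cohort.latents[m].loc[[sid]] for m in cohort.modalities}
        scores.append(
            counterfactual_variance_score(
                clf, profile, gen, "rnaseq", X_tr.columns,
                n_versions=10, seeds=list(range(10)),
            )
        )
    return {
        "cohort": cohort,
        "split": split,
        "classifier": clf,
        "generator": gen,
        "scores": scores,
        "feature_columns": X_tr.columns,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 600-sample cohort with the default four modalities."""
    cfg = CohortConfig(
        n_samples=600,
        n_types=6,
        seed=11,
        missing_rates={m: 0.0 for m in ("cna", "rnaseq", "rppa", "wsi")},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return stratified_split(
        list(small_cohort.sample_ids),
        small_cohort.type_label.to_dict(),
        completeness={i: True for i in small_cohort.sample_ids},
        seed=3,
    )
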