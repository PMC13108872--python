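"""Downstream experiment harnesses.

Implements the evaluation protocol around the generative models:

* **parity** — do classifiers trained on real data perform equally on
  generated data?
* **completion** — how much downstream performance is lost when
  modalities are ablated, and how much is recovered by generating them?
* **privacy probe** — can the models reconstruct the training manifold
  unconditionally?
* **counterfactual prioritization** — rank patients by how much a
  missing modality would change their prediction, and acquire it for the
  highest-variance patients first.

Downstream models are tree ensembles with native missing-value support
(scikit-learn random forests and scikit-survival random survival
forests, 500 trees by default); an ablated modality is passed as NaN
feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sksurv.ensemble import RandomSurvivalForest

from .cohort import SyntheticCohort
from .ensemble import EnsembleSpec, coherent_sample, multi_condition_sample, unconditional_probe
from .metrics import (
    MetricReport,
    balanced_accuracy,
    concordance_index,
    energy_distance,
    macro_f1,
    manifold_precision_recall_f1,
)
from .models import ConditionSet, PredictorCheckpoint
from .preprocess import CohortSplit

__all__ = [
    "ExperimentConfig",
    "CounterfactualScore",
    "OracleGenerator",
    "TruthPosteriorGenerator",
    "DiffusionGenerator",
    "CoherentGenerator",
    "parity_experiment",
    "completion_experiment",
    "privacy_probe_experiment",
    "counterfactual_variance_score",
    "prioritization_curves",
]


@dataclass
class ExperimentConfig:
    """Shared experiment settings."""

    n_runs: int = 10
    n_estimators: int = 500
    seed: int = 0
    acquisition_fractions: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.linspace(0, 1, 11), 2))
    )

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")


@dataclass
class CounterfactualScore:
    """Prediction instability of one sample under generated completions."""

    sample_id: str
    target_modality: str
    score: float
    n_versions: int = 10

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be non-negative")


# ---------------------------------------------------------------------------
# generators: anything with .generate(target, cond_tables, seed) -> DataFrame

class OracleGenerator:
    """Returns the real data — the identity generator used for protocol checks."""

    def __init__(self, latents: Mapping[str, pd.DataFrame]):
        self.latents = latents

    def generate(self, target: str, cond_tables: Mapping[str, pd.DataFrame], seed: int = 0):
        ids = next(iter(cond_tables.values())).index
        return self.latents[target].loc[ids]


class TruthPosteriorGenerator:
    """Samples a modality from the synthetic cohort's generative truth.

    Reconstructs the cross-modally shared contribution exactly (the
    stored shared factor) and redraws the modality-private factor and
    noise — the best any cross-modal generator can do on this cohort, with
    honest uncertainty about private information.
    """

    def __init__(self, cohort: SyntheticCohort):
        self.cohort = cohort
        self._pos = {sid: i for i, sid in enumerate(cohort.sample_ids)}

    def generate(self, target: str, cond_tables: Mapping[str, pd.DataFrame], seed: int = 0):
        ids = next(iter(cond_tables.values())).index
        rows = np.array([self._pos[i] for i in ids])
        truth = self.cohort.truth
        cfg = self.cohort.config
        A = truth["loadings_shared"][target]
        B = truth["loadings_private"][target]
        shared = truth["shared"][rows]
        rng = np.random.default_rng(seed)
        sd = cfg.private_signal_sd.get(target, 1.0)
        u = rng.standard_normal((len(rows), cfg.private_dim)) * sd
        eps = rng.standard_normal((len(rows), A.shape[0])) * cfg.noise_sd
        X = shared @ A.T + u @ B.T + eps
        return pd.DataFrame(X, index=ids, columns=self.cohort.latents[target].columns)


class DiffusionGenerator:
    """Wraps a multi-condition diffusion checkpoint as a completion generator."""

    def __init__(self, checkpoint: PredictorCheckpoint):
        self.checkpoint = checkpoint

    def generate(self, target: str, cond_tables: Mapping[str, pd.DataFrame], seed: int = 0):
        if target != self.checkpoint.target_modality:
            raise ValueError(
                f"checkpoint generates {self.checkpoint.target_modality!r}, not {target!r}"
            )
        usable = {
            m: df for m, df in cond_tables.items()
            if m in self.checkpoint.condition_modalities
        }
        ids = next(iter(cond_tables.values())).index
        cond = ConditionSet({m: df.to_numpy(float) for m, df in usable.items()}, n=len(ids))
        X = multi_condition_sample(self.checkpoint, cond, seed=seed)
        cols = [f"{target}_{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X, index=ids, columns=cols)


class CoherentGenerator:
    """Wraps a coherent-denoising ensemble as a completion generator."""

    def __init__(self, ensemble: EnsembleSpec, threshold: float = 1.0,
                 max_fraction: float = 0.05, max_retries: int = 5):
        self.ensemble = ensemble
        self.threshold = threshold
        self.max_fraction = max_fraction
        self.max_retries = max_retries
        self.last_result = None

    def generate(self, target: str, cond_tables: Mapping[str, pd.DataFrame], seed: int = 0):
        if target != self.ensemble.target_modality:
            raise ValueError(
                f"ensemble generates {self.ensemble.target_modality!r}, not {target!r}"
            )
        ids = next(iter(cond_tables.values())).index
        needed = [m for _, m in self.ensemble.members]
        cond = ConditionSet(
            {m: cond_tables[m].to_numpy(float) for m in needed}, n=len(ids)
        )
        schedule = self.ensemble.members[0][0].schedule
        result = coherent_sample(
            self.ensemble, cond, schedule, n=len(ids), seed=seed,
            threshold=self.threshold, max_fraction=self.max_fraction,
            max_retries=self.max_retries,
        )
        self.last_result = result
        cols = [f"{target}_{j}" for j in range(result.samples.shape[1])]
        return pd.DataFrame(result.samples, index=ids, columns=cols)


# ---------------------------------------------------------------------------
# feature assembly

def _concat(latents: Mapping[str, pd.DataFrame], ids, missing: Sequence[str] = ()) -> pd.DataFrame:
    """Concatenate modality tables over ``ids``; ``missing`` become NaN blocks."""
    parts = []
    for m, df in latents.items():
        block = df.loc[ids]
        if m in missing:
            block = pd.DataFrame(np.nan, index=block.index, columns=block.columns)
        parts.append(block)
    return pd.concat(parts, axis=1)


def _survival_y(time: pd.Series, event: pd.Series) -> np.ndarray:
    y = np.empty(len(time), dtype=[("event", bool), ("time", float)])
    y["event"] = event.to_numpy(bool)
    y["time"] = time.to_numpy(float)
    return y


# ---------------------------------------------------------------------------
# experiments

def parity_experiment(
    cohort: SyntheticCohort,
    split: CohortSplit,
    generators: Mapping[str, object],
    config: Optional[ExperimentConfig] = None,
    modalities: Optional[Sequence[str]] = None,
    tasks: Sequence[str] = ("type", "stage"),
) -> pd.DataFrame:
    """Classifier parity between real and generated single-modality data.

    Trains one random-forest classifier per modality and task on real
    training data, evaluates it on the real test set and on ``n_runs``
    seeded synthetic test sets per generator (each target modality
    generated conditioned on the remaining real modalities), and reports
    mean +/- sd macro F1 and balanced accuracy.
    """
    cfg = config or ExperimentConfig()
    modalities = list(modalities or cohort.modalities)
    labels = {"type": cohort.type_label, "stage": cohort.stage_label}
    reports: List[MetricReport] = []
    for task in tasks:
        y_tr = labels[task].loc[split.train_ids]
        y_te = labels[task].loc[split.test_ids]
        for m in modalities:
            clf = RandomForestClassifier(
                n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1
            )
            clf.fit(cohort.latents[m].loc[split.train_ids].to_numpy(float), y_tr)
            y_hat = clf.predict(cohort.latents[m].loc[split.test_ids].to_numpy(float))
            reports.append(MetricReport(
                "macro_f1", macro_f1(y_te, y_hat),
                context={"task": task, "modality": m, "method": "real"},
            ))
            reports.append(MetricReport(
                "balanced_accuracy", balanced_accuracy(y_te, y_hat),
                context={"task": task, "modality": m, "method": "real"},
            ))
            cond_tables = {
                o: cohort.latents[o].loc[split.test_ids]
                for o in cohort.modalities if o != m
            }
            for gname, gen in generators.items():
                f1s, bas = [], []
                for run in range(cfg.n_runs):
                    synth = gen.generate(m, cond_tables, seed=cfg.seed + run)
                    y_hat = clf.predict(synth.to_numpy(float))
                    f1s.append(macro_f1(y_te, y_hat))
                    bas.append(balanced_accuracy(y_te, y_hat))
                ctx = {"task": task, "modality": m, "method": gname}
                reports.append(MetricReport(
                    "macro_f1", float(np.mean(f1s)),
                    dispersion=float(np.std(f1s, ddof=1)) if cfg.n_runs > 1 else None,
                    n_runs=cfg.n_runs, context=ctx,
                ))
                reports.append(MetricReport(
                    "balanced_accuracy", float(np.mean(bas)),
                    dispersion=float(np.std(bas, ddof=1)) if cfg.n_runs > 1 else None,
                    n_runs=cfg.n_runs, context=ctx,
                ))
    return pd.DataFrame([r.as_row() for r in reports])


def completion_experiment(
    cohort: SyntheticCohort,
    split: CohortSplit,
    generators: Mapping[str, object],
    patterns: Sequence[Sequence[str]],
    config: Optional[ExperimentConfig] = None,
    tasks: Sequence[str] = ("stage", "survival"),
) -> pd.DataFrame:
    """Ablation drop and generative-completion gain on multimodal models.

    For each missing-data pattern, evaluates a multimodal stage
    classifier (macro F1) and a random survival forest (Harrell's C) on
    (a) the full test data, (b) the ablated data with the pattern's
    modalities flagged missing, (c) data completed by each generator,
    over ``n_runs`` generation seeds.  A label-only baseline (the same
    model on a one-hot cancer-type input) isolates the signal beyond the
    type signature.  Drops are relative to the full-data score, gains
    relative to the ablated score.
    """
    cfg = config or ExperimentConfig()
    latents = cohort.latents
    X_tr = _concat(latents, split.train_ids)
    X_te_full = _concat(latents, split.test_ids)

    fitted = {}
    if "stage" in tasks:
        clf = RandomForestClassifier(
            n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1
        )
        clf.fit(X_tr.to_numpy(float), cohort.stage_label.loc[split.train_ids])
        fitted["stage"] = clf
    if "survival" in tasks:
        rsf = RandomSurvivalForest(
            n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1
        )
        rsf.fit(
            X_tr.to_numpy(float),
            _survival_y(
                cohort.survival_time.loc[split.train_ids],
                cohort.survival_event.loc[split.train_ids],
            ),
        )
        fitted["survival"] = rsf

    y_stage = cohort.stage_label.loc[split.test_ids]
    t_te = cohort.survival_time.loc[split.test_ids]
    e_te = cohort.survival_event.loc[split.test_ids]

    def _score(task: str, X: pd.DataFrame) -> float:
        if task == "stage":
            return macro_f1(y_stage, fitted["stage"].predict(X.to_numpy(float)))
        risk = fitted["survival"].predict(X.to_numpy(float))
        return concordance_index(t_te, e_te, risk)

    # label-only baseline: one-hot cancer type as the only input
    type_onehot_tr = pd.get_dummies(cohort.type_label.loc[split.train_ids]).astype(float)
    type_onehot_te = pd.get_dummies(cohort.type_label.loc[split.test_ids]).astype(float)
    type_onehot_te = type_onehot_te.reindex(columns=type_onehot_tr.columns, fill_value=0.0)
    baseline_scores = {}
    if "stage" in tasks:
        b = RandomForestClassifier(n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1)
        b.fit(type_onehot_tr.to_numpy(float), cohort.stage_label.loc[split.train_ids])
        baseline_scores["stage"] = macro_f1(y_stage, b.predict(type_onehot_te.to_numpy(float)))
    if "survival" in tasks:
        b = RandomSurvivalForest(n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1)
        b.fit(
            type_onehot_tr.to_numpy(float),
            _survival_y(cohort.survival_time.loc[split.train_ids],
                        cohort.survival_event.loc[split.train_ids]),
        )
        baseline_scores["survival"] = concordance_index(
            t_te, e_te, b.predict(type_onehot_te.to_numpy(float))
        )

    rows = []
    for task in tasks:
        full_score = _score(task, X_te_full)
        rows.append({"task": task, "pattern": "", "quantity": "full_data",
                     "mean": full_score, "sd": 0.0, "n_runs": 1})
        rows.append({"task": task, "pattern": "", "quantity": "label_only_baseline",
                     "mean": baseline_scores[task], "sd": 0.0, "n_runs": 1})
        for pattern in patterns:
            pattern = list(pattern)
            tag = "+".join(pattern)
            ablated_score = _score(task, _concat(latents, split.test_ids, missing=pattern))
            rows.append({"task": task, "pattern": tag, "quantity": "drop_from_ablation",
                         "mean": ablated_score - full_score, "sd": 0.0, "n_runs": 1})
            for gname, gen in generators.items():
                gains = []
                for run in range(cfg.n_runs):
                    completed = dict(latents)
                    for m in pattern:
                        cond_tables = {
                            o: latents[o].loc[split.test_ids]
                            for o in latents if o not in pattern
                        }
                        block = gen.generate(m, cond_tables, seed=cfg.seed + run)
                        block.columns = latents[m].columns
                        filled = latents[m].copy()
                        filled.loc[split.test_ids] = block.loc[split.test_ids].to_numpy()
                        completed[m] = filled
                    comp_score = _score(task, _concat(completed, split.test_ids))
                    gains.append(comp_score - ablated_score)
                rows.append({
                    "task": task, "pattern": tag, "quantity": f"gain_{gname}",
                    "mean": float(np.mean(gains)),
                    "sd": float(np.std(gains, ddof=1)) if cfg.n_runs > 1 else 0.0,
                    "n_runs": cfg.n_runs,
                })
    return pd.DataFrame(rows)


def privacy_probe_experiment(
    train_data: np.ndarray,
    multi_model: PredictorCheckpoint,
    ensemble: EnsembleSpec,
    config: Optional[ExperimentConfig] = None,
    n_probe: Optional[int] = None,
    k: int = 5,
) -> pd.DataFrame:
    """Unconditional-generation privacy probe.

    Generates unconditional samples from the multi-condition model (fully
    masked input) and from the coherent-denoising ensemble (zero-vector
    conditions), ``n_runs`` times each, and reports manifold-coverage F1
    and energy distance against the training data.  An ensemble of
    single-condition models cannot generate realistic data without
    conditioning, so its probe collapses toward the distribution mean —
    the privacy-preserving outcome.
    """
    cfg = config or ExperimentConfig()
    train_data = np.asarray(train_data, dtype=np.float64)
    n_probe = n_probe or len(train_data)
    rows = []
    for name, model in (("multi_condition", multi_model), ("coherent_ensemble", ensemble)):
        schedule = model.schedule if isinstance(model, PredictorCheckpoint) else (
            model.members[0][0].schedule
        )
        f1s, eds = [], []
        for run in range(cfg.n_runs):
            gen = unconditional_probe(model, schedule, n_probe, seed=cfg.seed + run)
            _, _, f1 = manifold_precision_recall_f1(train_data, gen, k=k)
            f1s.append(f1)
            eds.append(energy_distance(gen, train_data))
        rows.append({
            "model": name,
            "coverage_f1_mean": float(np.mean(f1s)),
            "coverage_f1_sd": float(np.std(f1s, ddof=1)) if cfg.n_runs > 1 else 0.0,
            "energy_distance_mean": float(np.mean(eds)),
            "energy_distance_sd": float(np.std(eds, ddof=1)) if cfg.n_runs > 1 else 0.0,
            "n_runs": cfg.n_runs,
        })
    return pd.DataFrame(rows)


def counterfactual_variance_score(
    classifier,
    profile: Mapping[str, pd.DataFrame],
    generator,
    target_modality: str,
    feature_columns: Sequence[str],
    n_versions: int = 10,
    seeds: Optional[Sequence[int]] = None,
) -> CounterfactualScore:
    """Prediction instability of one profile under generated completions.

    Generates ``n_versions`` versions of the hidden modality conditioned
    on the profile's other modalities, runs each completed profile
    through the classifier, and returns the variance of the class
    probabilities across versions, averaged over classes.  Zero means the
    hidden modality is redundant for this sample's prediction.
    """
    seeds = list(seeds) if seeds is not None else list(range(n_versions))
    if len(seeds) != n_versions:
        raise ValueError("one seed per version required")
    cond_tables = {m: df for m, df in profile.items() if m != target_modality}
    sample_id = str(next(iter(cond_tables.values())).index[0])
    probas = []
    for s in seeds:
        block = generator.generate(target_modality, cond_tables, seed=s)
        completed = dict(cond_tables)
        completed[target_modality] = block
        X = pd.concat(completed.values(), axis=1)[list(feature_columns)]
        probas.append(classifier.predict_proba(X.to_numpy(float))[0])
    P = np.stack(probas)  # (n_versions, n_classes)
    score = float(P.var(axis=0, ddof=0).mean())
    return CounterfactualScore(sample_id, target_modality, score, n_versions)


def prioritization_curves(
    cohort: SyntheticCohort,
    split: CohortSplit,
    classifier,
    generator,
    target_modality: str,
    scores: Sequence[CounterfactualScore],
    config: Optional[ExperimentConfig] = None,
    task: str = "stage",
) -> pd.DataFrame:
    """Informed vs random acquisition curves for one hidden modality.

    For each acquisition fraction, the hidden modality is replaced by
    real data for the selected subset (descending counterfactual score,
    ties broken by sample ID, vs a fresh random order per run) and
    generated for the rest; the classifier's macro F1 over the test set
    traces the curve.  Returns the per-fraction scores plus the area
    under each strategy's curve.
    """
    cfg = config or ExperimentConfig()
    latents = cohort.latents
    test_ids = list(split.test_ids)
    y_te = (cohort.stage_label if task == "stage" else cohort.type_label).loc[test_ids]
    score_map = {s.sample_id: s.score for s in scores}
    if set(score_map) != set(map(str, test_ids)):
        raise ValueError("scores must cover exactly the test samples")
    informed_order = sorted(test_ids, key=lambda i: (-score_map[str(i)], str(i)))
    cond_tables = {
        o: latents[o].loc[test_ids] for o in latents if o != target_modality
    }
    feature_cols = _concat(latents, test_ids).columns

    def _evaluate(acquired_ids, gen_seed):
        block = generator.generate(target_modality, cond_tables, seed=gen_seed)
        block.columns = latents[target_modality].columns
        mixed = block.copy()
        if len(acquired_ids):
            mixed.loc[acquired_ids] = latents[target_modality].loc[acquired_ids].to_numpy()
        completed = dict(latents)
        filled = latents[target_modality].copy()
        filled.loc[test_ids] = mixed.loc[test_ids].to_numpy()
        completed[target_modality] = filled
        X = _concat(completed, test_ids)[feature_cols]
        return macro_f1(y_te, classifier.predict(X.to_numpy(float)))

    n_test = len(test_ids)
    fracs = [float(f) for f in cfg.acquisition_fractions]
    inf_scores = np.zeros((cfg.n_runs, len(fracs)))
    rand_scores = np.zeros((cfg.n_runs, len(fracs)))
    for run in range(cfg.n_runs):
        gen_seed = cfg.seed + 7919 * run
        rng = np.random.default_rng(cfg.seed + run)
        rand_order = list(rng.permutation(test_ids))
        for j, frac in enumerate(fracs):
            n_acq = int(round(frac * n_test))
            inf_scores[run, j] = _evaluate(informed_order[:n_acq], gen_seed)
            rand_scores[run, j] = _evaluate(rand_order[:n_acq], gen_seed)
    curves = pd.DataFrame({
        "fraction": fracs,
        "informed_mean": inf_scores.mean(axis=0),
        "informed_sd": inf_scores.std(axis=0, ddof=1) if cfg.n_runs > 1 else 0.0,
        "random_mean": rand_scores.mean(axis=0),
        "random_sd": rand_scores.std(axis=0, ddof=1) if cfg.n_runs > 1 else 0.0,
    })
    # per-run curve areas: each run pairs one generation seed with one
    # random acquisition order, so runs are comparable head-to-head
    curves.attrs["areas_informed"] = [
        float(np.trapezoid(inf_scores[r], fracs)) for r in range(cfg.n_runs)
    ]
    curves.attrs["areas_random"] = [
        float(np.trapezoid(rand_scores[r], fracs)) for r in range(cfg.n_runs)
    ]
    curves.attrs["area_informed"] = float(np.trapezoid(inf_scores.mean(axis=0), fracs))
    curves.attrs["area_random"] = float(np.trapezoid(rand_scores.mean(axis=0), fracs))
    return curves
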