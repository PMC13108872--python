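"""Synthetic multimodal cohorts with known generative ground truth.

Emulates the statistical regime of a pan-cancer multi-omics cohort at
the latent-embedding level: samples belong to one of ``n_types`` tumour
types; a cross-modally *shared* factor (type-specific mean plus
within-type spread) drives every modality, while each modality also
carries a *private* factor invisible to the others.  Making one
modality's private variance dominant reproduces the regime in which that
modality (the "cna-like" one) is poorly reconstructible from the rest,
while its cross-modal signal remains recoverable.  Ordinal stage labels
and exponential proportional-hazards survival times are derived from the
shared factor, and per-modality missingness is applied completely at
random.

Every random element is a pure function of the config seed, and the
factor loadings and noise draws are stored, so tests can verify the
generative equations exactly and compute oracle regressions against the
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "degrade",
    "private_signal_scenario",
]

DEFAULT_MODALITIES = ("cna", "rnaseq", "rppa", "wsi")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic multimodal cohort.

    ``private_signal_sd`` controls how much of each modality's variance
    is invisible to the others; the default makes the ``cna`` modality
    private-dominated (poorly cross-modally reconstructible) and the rest
    shared-dominated.  ``missing_rates`` are per-modality MCAR fractions.
    """

    n_samples: int = 1000
    n_types: int = 6
    modality_dims: Mapping[str, int] = field(
        default_factory=lambda: {m: 8 for m in DEFAULT_MODALITIES}
    )
    shared_dim: int = 4
    private_dim: int = 2
    shared_signal_sd: float = 1.0
    type_center_sd: float = 3.0
    private_signal_sd: Mapping[str, float] = field(
        default_factory=lambda: {"cna": 3.0, "rnaseq": 0.5, "rppa": 0.7, "wsi": 1.0}
    )
    noise_sd: float = 0.3
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {"cna": 0.14, "rnaseq": 0.06, "rppa": 0.32, "wsi": 0.25}
    )
    stage_levels: int = 4
    stage_effect: float = 2.0
    stage_noise_sd: float = 1.0
    survival_baseline: Optional[Sequence[float]] = None  # per-type rate
    survival_effect: float = 1.0
    censor_horizon: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 2:
            raise ValueError("n_types must be at least 2")
        if self.shared_signal_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("signal and noise sds must be positive")
        for m, sd in self.private_signal_sd.items():
            if sd < 0:
                raise ValueError(f"private sd for {m} must be non-negative")
        for m, r in self.missing_rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing rate for {m} must lie in [0, 1)")
        missing = set(self.missing_rates) - set(self.modality_dims)
        if missing:
            raise ValueError(f"missing_rates name unknown modalities: {sorted(missing)}")


@dataclass
class SyntheticCohort:
    """A generated cohort: latent tables, labels, outcomes and truth."""

    config: CohortConfig
    sample_ids: np.ndarray
    latents: Dict[str, pd.DataFrame]
    type_label: pd.Series
    stage_label: pd.Series
    survival_time: pd.Series
    survival_event: pd.Series
    available: pd.DataFrame  # boolean, samples x modalities
    truth: Dict[str, object]

    @property
    def modalities(self):
        return list(self.latents)

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            config=self.config,
            sample_ids=self.sample_ids.copy(),
            latents={m: df.copy() for m, df in self.latents.items()},
            type_label=self.type_label.copy(),
            stage_label=self.stage_label.copy(),
            survival_time=self.survival_time.copy(),
            survival_event=self.survival_event.copy(),
            available=self.available.copy(),
            truth=dict(self.truth),
        )

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type": self.type_label,
                "stage": self.stage_label,
                "survival_time": self.survival_time,
                "survival_event": self.survival_event.astype(int),
            }
        )

    def write_dir(self, path) -> None:
        """Export to the delimited-table layout the preprocessing reads."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for m, df in self.latents.items():
            df.to_csv(path / f"{m}.tsv", sep="\t", index_label="sample_id")
        self.labels_frame().to_csv(path / "labels.tsv", sep="\t", index_label="sample_id")
        self.available.astype(int).to_csv(
            path / "availability.tsv", sep="\t", index_label="sample_id"
        )


def _resolve_map(mapping: Mapping[str, float], modalities, default: float):
    return {m: float(mapping.get(m, default)) for m in modalities}


def generate_cohort(config: CohortConfig, complete_ids: bool = False) -> SyntheticCohort:
    """Draw a cohort from the documented generative model.

    Per sample: a type is drawn uniformly; the shared factor
    ``s ~ N(center_type, shared_signal_sd^2 I)``; each modality's latent is
    ``A_m s + B_m u_m + noise`` with a fresh private factor ``u_m``.  Stage
    comes from an ordinal threshold model on a linear score of ``s``;
    survival from an exponential proportional-hazards model with a
    per-type baseline rate, administratively censored at the horizon.

    With ``complete_ids=True`` no missingness is applied (every
    availability flag true) — the mode used to earmark fully observed
    test samples.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    modalities = list(cfg.modality_dims)
    q, p = cfg.shared_dim, cfg.private_dim

    sample_ids = np.array([f"S{i:06d}" for i in range(n)])
    types = rng.integers(0, cfg.n_types, size=n)
    centers = rng.standard_normal((cfg.n_types, q)) * cfg.type_center_sd
    shared = centers[types] + rng.standard_normal((n, q)) * cfg.shared_signal_sd

    private_sd = _resolve_map(cfg.private_signal_sd, modalities, 1.0)
    loadings_A, loadings_B, privates, noises = {}, {}, {}, {}
    latents: Dict[str, pd.DataFrame] = {}
    for m in modalities:
        d = cfg.modality_dims[m]
        A = rng.standard_normal((d, q)) / np.sqrt(q)
        B = rng.standard_normal((d, p)) / np.sqrt(p)
        u = rng.standard_normal((n, p)) * private_sd[m]
        eps = rng.standard_normal((n, d)) * cfg.noise_sd
        X = shared @ A.T + u @ B.T + eps
        loadings_A[m], loadings_B[m] = A, B
        privates[m], noises[m] = u, eps
        latents[m] = pd.DataFrame(
            X, index=sample_ids, columns=[f"{m}_{j}" for j in range(d)]
        )

    # ordinal stage from a linear score of the shared factor
    w_stage = rng.standard_normal(q)
    w_stage /= np.linalg.norm(w_stage)
    score = cfg.stage_effect * (shared @ w_stage) + rng.standard_normal(n) * cfg.stage_noise_sd
    cuts = np.quantile(score, np.linspace(0, 1, cfg.stage_levels + 1)[1:-1])
    stage = np.searchsorted(cuts, score, side="right") + 1  # stages 1..L

    # exponential proportional hazards with per-type baseline
    if cfg.survival_baseline is None:
        baseline = 0.2 * np.exp(rng.standard_normal(cfg.n_types) * 0.5)
    else:
        baseline = np.asarray(cfg.survival_baseline, dtype=np.float64)
        if baseline.shape != (cfg.n_types,):
            raise ValueError("survival_baseline must have one rate per type")
    w_surv = rng.standard_normal(q)
    w_surv /= np.linalg.norm(w_surv)
    lin_pred = cfg.survival_effect * (shared @ w_surv) / max(cfg.shared_signal_sd, 1e-12)
    hazard = baseline[types] * np.exp(lin_pred - lin_pred.mean())
    raw_time = rng.exponential(1.0 / hazard)
    event = raw_time <= cfg.censor_horizon
    time = np.minimum(raw_time, cfg.censor_horizon)

    missing_rates = _resolve_map(cfg.missing_rates, modalities, 0.0)
    avail = {}
    for m in modalities:
        if complete_ids or missing_rates[m] == 0:
            avail[m] = np.ones(n, dtype=bool)
        else:
            avail[m] = rng.random(n) >= missing_rates[m]
    available = pd.DataFrame(avail, index=sample_ids)

    truth = {
        "shared": shared,
        "centers": centers,
        "loadings_shared": loadings_A,
        "loadings_private": loadings_B,
        "private": privates,
        "noise": noises,
        "stage_weights": w_stage,
        "survival_weights": w_surv,
        "survival_linpred": lin_pred,
        "baseline": baseline,
    }
    return SyntheticCohort(
        config=cfg,
        sample_ids=sample_ids,
        latents=latents,
        type_label=pd.Series(types, index=sample_ids, name="type"),
        stage_label=pd.Series(stage, index=sample_ids, name="stage"),
        survival_time=pd.Series(time, index=sample_ids, name="survival_time"),
        survival_event=pd.Series(event, index=sample_ids, name="survival_event"),
        available=available,
        truth=truth,
    )


def private_signal_scenario(
    cohort: SyntheticCohort,
    target_modality: str,
    fraction: float = 0.25,
    seed: int = 0,
) -> SyntheticCohort:
    """Make one modality's private factor predictive for a minority.

    Returns a copy in which, for the samples of a seeded minority subset
    of tumour types (about ``fraction`` of the cohort), the stage label
    is re-derived from the first private-factor component of
    ``target_modality`` (quantile-binned into the existing stage levels)
    instead of from the shared factor.  For those types the stage signal
    lives only in the target modality — invisible to every other modality,
    so a cross-modal generator cannot recover it, while the tumour type
    itself (observable from any modality) marks where that happens.  This
    is the regime in which counterfactual variance scores should single
    out the affected samples for data acquisition.
    """
    if target_modality not in cohort.latents:
        raise KeyError(f"unknown modality {target_modality!r}")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    n_minority_types = max(1, int(round(fraction * out.config.n_types)))
    minority_types = rng.choice(out.config.n_types, size=n_minority_types, replace=False)
    minority = np.isin(out.type_label.to_numpy(), minority_types)
    u1 = out.truth["private"][target_modality][:, 0]
    levels = out.config.stage_levels
    cuts = np.quantile(u1, np.linspace(0, 1, levels + 1)[1:-1])
    private_stage = np.searchsorted(cuts, u1, side="right") + 1
    stage = out.stage_label.to_numpy().copy()
    stage[minority] = private_stage[minority]
    out.stage_label = pd.Series(stage, index=out.sample_ids, name="stage")
    out.truth = dict(out.truth)
    out.truth["private_stage_mask"] = minority
    out.truth["private_stage_types"] = minority_types
    return out


def degrade(
    cohort: SyntheticCohort,
    pattern: Mapping[str, Union[bool, float]],
    seed: int = 0,
) -> SyntheticCohort:
    """Copy of ``cohort`` with additional missingness applied.

    ``pattern`` maps modality name to either ``True`` (remove the
    modality for every sample) or a fraction in [0, 1] (remove it for a
    seeded random subset of that size).  The original cohort is untouched.
    """
    unknown = set(pattern) - set(cohort.latents)
    if unknown:
        raise KeyError(f"unknown modalities in pattern: {sorted(unknown)}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for m, spec in pattern.items():
        if spec is True:
            out.available[m] = False
        elif spec is False:
            continue
        else:
            frac = float(spec)
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction for {m} must lie in [0, 1]")
            mask = rng.random(len(out.sample_ids)) < frac
            out.available.loc[mask, m] = False
    return out
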