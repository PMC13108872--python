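"""Coherent-denoising consensus sampling.

An ensemble of single-condition diffusion models generates a target
modality jointly: at every reverse step each member predicts a noise
vector from the same ``x_t`` and its own conditioning modality, the
predictions are combined into a consensus by a reliability-weighted
average (weights inversely proportional to each member's validation
reconstruction MSE), and the geometric agreement of the members is
monitored through pairwise cosine distances.  A trajectory whose mean
pairwise distance exceeds a threshold on more than a small fraction of
steps is rejected and re-sampled with a fresh noise stream — conflicting
conditional evidence produces incoherent denoising directions, and such
samples are discarded rather than returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .diffusion import reverse_trajectory
from .models import ConditionSet, PredictorCheckpoint, predict_noise
from .schedule import NoiseSchedule

__all__ = [
    "EnsembleSpec",
    "StepDiagnostics",
    "GenerationResult",
    "compute_weights",
    "consensus_noise",
    "coherence_distance",
    "coherent_sample",
    "multi_condition_sample",
    "unconditional_probe",
]

# deterministic seed advance between rejection retries
_RETRY_STRIDE = 1_000_003
_SEED_MOD = 2**31 - 1


def compute_weights(val_mses: Sequence[float]) -> np.ndarray:
    """Ensemble weights inversely proportional to validation MSE."""
    mses = np.asarray(val_mses, dtype=np.float64)
    if mses.size == 0:
        raise ValueError("need at least one member")
    if np.any(mses <= 0):
        raise ValueError("validation MSEs must be strictly positive")
    inv = 1.0 / mses
    return inv / inv.sum()


@dataclass
class EnsembleSpec:
    """Members of a coherent-denoising ensemble and their weights."""

    members: List[Tuple[PredictorCheckpoint, str]]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.members) != self.weights.size:
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        targets = {ck.target_modality for ck, _ in self.members}
        if len(targets) != 1:
            raise ValueError(f"members target different modalities: {targets}")
        conds = [m for _, m in self.members]
        if len(set(conds)) != len(conds):
            raise ValueError("condition modalities must be distinct")

    @property
    def target_modality(self) -> str:
        return self.members[0][0].target_modality

    @property
    def D(self) -> int:
        return self.members[0][0].network.D

    @classmethod
    def from_checkpoints(cls, checkpoints: Sequence[PredictorCheckpoint]) -> "EnsembleSpec":
        """Build with inverse-validation-MSE weights."""
        members = [(ck, ck.condition_modalities[0]) for ck in checkpoints]
        weights = compute_weights([ck.best_val_mse for ck in checkpoints])
        return cls(members, weights)

    def manifest(self) -> str:
        lines = ["# coherent-denoising ensemble", f"target\t{self.target_modality}"]
        for (ck, cond), w in zip(self.members, self.weights):
            lines.append(f"member\t{cond}\tval_mse={ck.best_val_mse:.8g}\tweight={w:.8g}")
        return "\n".join(lines) + "\n"


@dataclass
class StepDiagnostics:
    """Per-step coherence record of a generation trajectory."""

    per_step_distance: np.ndarray  # length T, batch-averaged weighted d-bar
    incoherent_fraction: float  # worst per-sample fraction of steps above threshold
    threshold: float
    max_fraction: float


@dataclass
class GenerationResult:
    samples: np.ndarray
    accepted: bool
    diagnostics: StepDiagnostics
    retries_used: int

    def export(self, path, sample_ids=None) -> None:
        """Write samples as a delimited table plus a diagnostics sidecar."""
        import pandas as pd

        path = Path(path)
        idx = sample_ids if sample_ids is not None else range(len(self.samples))
        pd.DataFrame(self.samples, index=idx).to_csv(path, sep="\t")
        side = path.with_suffix(path.suffix + ".coherence.tsv")
        pd.DataFrame(
            {
                "t": np.arange(1, len(self.diagnostics.per_step_distance) + 1),
                "mean_pairwise_distance": self.diagnostics.per_step_distance,
            }
        ).to_csv(side, sep="\t", index=False)


def consensus_noise(predictions: Sequence[np.ndarray], weights) -> np.ndarray:
    """Element-wise weighted average of member noise predictions.

    Computed as ``p_0 + sum_i w_i (p_i - p_0)`` — algebraically the
    weighted mean (weights sum to one) but bit-exact when every member
    agrees, which keeps duplicated-member ensembles identical to a single
    model.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if len(predictions) != weights.size:
        raise ValueError("one weight per prediction required")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
        raise ValueError("weights must be non-negative and sum to 1")
    base = np.asarray(predictions[0], dtype=np.float64)
    if len(predictions) == 1:
        return base
    out = base.copy()
    for w, p in zip(weights[1:], predictions[1:]):
        p = np.asarray(p, dtype=np.float64)
        if p.shape != base.shape:
            raise ValueError("prediction shapes differ")
        out += w * (p - base)
    return out


def _pairwise_distances(predictions, weights):
    """Per-sample weighted mean pairwise cosine distance, shape (n,)."""
    N = len(predictions)
    n = predictions[0].shape[0]
    if N < 2:
        return np.zeros(n)
    num = np.zeros(n)
    wsum = 0.0
    norms = [np.linalg.norm(p, axis=1) for p in predictions]
    for i in range(N):
        for j in range(i + 1, N):
            dot = np.einsum("nd,nd->n", predictions[i], predictions[j])
            denom = norms[i] * norms[j]
            with np.errstate(invalid="ignore", divide="ignore"):
                d = 1.0 - dot / denom
            d = np.where(denom > 0, d, 0.0)  # zero-norm pair: non-conflicting
            pw = weights[i] * weights[j]
            num += pw * d
            wsum += pw
    return num / wsum if wsum > 0 else np.zeros(n)


def coherence_distance(predictions: Sequence[np.ndarray], weights) -> float:
    """Batch-averaged weighted mean pairwise cosine distance, in [0, 2].

    Each member's per-sample prediction is flattened to a vector; pairwise
    cosine distances are weighted by ``w_i * w_j`` (normalized over pairs
    ``i < j``) and averaged over the batch.  Returns 0 for a single member.
    """
    preds = [np.atleast_2d(np.asarray(p, dtype=np.float64)) for p in predictions]
    weights = np.asarray(weights, dtype=np.float64)
    return float(_pairwise_distances(preds, weights).mean())


def _ensemble_predictions(ensemble: EnsembleSpec, xt, t, conditions, zero_condition=False):
    preds = []
    for ck, cond_name in ensemble.members:
        if zero_condition:
            member_cond = ConditionSet.zeros(
                {cond_name: ck.network.cond_dims[cond_name]}, n=xt.shape[0]
            )
        else:
            member_cond = ConditionSet(
                {cond_name: conditions.entries[cond_name]},
                {cond_name: conditions.present[cond_name]},
                n=conditions.n,
            )
        preds.append(predict_noise(ck, xt, t, member_cond))
    return preds


def _run_consensus_trajectory(
    ensemble, conditions, schedule, n, seed, zero_condition=False
):
    """One consensus reverse trajectory; returns (samples, dbar (T, n))."""
    T = schedule.T
    dbar = np.zeros((T, n))

    def predictor(xt, t, cond):
        preds = _ensemble_predictions(ensemble, xt, t, cond, zero_condition)
        dbar[t - 1] = _pairwise_distances(preds, ensemble.weights)
        return consensus_noise(preds, ensemble.weights)

    samples = reverse_trajectory(predictor, schedule, n, ensemble.D, conditions, seed)
    return samples, dbar


def coherent_sample(
    ensemble: EnsembleSpec,
    conditions: ConditionSet,
    schedule: NoiseSchedule,
    n: int,
    seed: int = 0,
    threshold: float = 1.0,
    max_fraction: float = 0.05,
    max_retries: int = 5,
) -> GenerationResult:
    """Consensus sampling with coherence-based rejection.

    Runs the reverse loop with the consensus noise at every step and
    records the weighted mean pairwise cosine distance ``d_bar_t``.  A
    sample whose fraction of incoherent steps (``d_bar_t > threshold``)
    strictly exceeds ``max_fraction`` is rejected and re-generated from a
    fresh, deterministically advanced noise stream, up to ``max_retries``
    times; afterwards the best-effort trajectory (minimal incoherent
    fraction) is returned flagged as not accepted.  Rejection is decided
    per sample; a fraction exactly equal to ``max_fraction`` is accepted.
    """
    for _, cond_name in ensemble.members:
        if cond_name not in conditions.entries or not conditions.present[cond_name].all():
            raise KeyError(
                f"condition modality {cond_name!r} must be present for every sample"
            )
    T = schedule.T
    best_samples = np.zeros((n, ensemble.D))
    best_dbar = np.zeros((T, n))
    best_frac = np.full(n, np.inf)
    remaining = np.arange(n)
    retries_used = 0

    for attempt in range(max_retries + 1):
        eff_seed = (seed + attempt * _RETRY_STRIDE) % _SEED_MOD
        cond_sub = conditions.rows(remaining) if remaining.size < n else conditions
        samples, dbar = _run_consensus_trajectory(
            ensemble, cond_sub, schedule, remaining.size, eff_seed
        )
        frac = np.mean(dbar > threshold, axis=0)
        better = frac < best_frac[remaining]
        rows = remaining[better]
        best_samples[rows] = samples[better]
        best_dbar[:, rows] = dbar[:, better]
        best_frac[rows] = frac[better]
        remaining = remaining[frac > max_fraction]
        if remaining.size == 0:
            break
        if attempt < max_retries:
            retries_used += 1

    accepted = bool(np.all(best_frac <= max_fraction))
    diagnostics = StepDiagnostics(
        per_step_distance=best_dbar.mean(axis=1),
        incoherent_fraction=float(best_frac.max()),
        threshold=threshold,
        max_fraction=max_fraction,
    )
    return GenerationResult(best_samples, accepted, diagnostics, retries_used)


def multi_condition_sample(
    checkpoint: PredictorCheckpoint,
    conditions: ConditionSet,
    schedule: Optional[NoiseSchedule] = None,
    n: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample from a multi-condition model given any condition subset.

    ``conditions`` may present any subset of the checkpoint's modalities,
    including none at all — the fully masked input is the unconditional
    mode the masking strategy trains for.
    """
    unknown = set(conditions.entries) - set(checkpoint.condition_modalities)
    if unknown:
        raise KeyError(f"modalities not recognized by checkpoint: {sorted(unknown)}")
    schedule = schedule or checkpoint.schedule
    n = conditions.n if n is None else n
    # fill in any modality the checkpoint knows but the caller omitted
    entries = dict(conditions.entries)
    present = dict(conditions.present)
    for m in checkpoint.condition_modalities:
        if m not in entries:
            entries[m] = None
            present[m] = np.zeros(n, dtype=bool)
    full = ConditionSet(entries, present, n=n)
    return reverse_trajectory(
        checkpoint.predictor(), schedule, n, checkpoint.network.D, full, seed
    )


def unconditional_probe(
    target: Union[EnsembleSpec, PredictorCheckpoint],
    schedule: NoiseSchedule,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Unconditional generation probe for privacy assessment.

    For an ensemble, every member is fed a zero vector as its condition
    value (single-condition models have no masking pathway); rejection
    sampling is disabled.  For a multi-condition checkpoint, all
    modalities are masked — the null condition its masking strategy was
    trained on.
    """
    if isinstance(target, EnsembleSpec):
        dummy = ConditionSet.empty([m for _, m in target.members], n=n)
        samples, _ = _run_consensus_trajectory(
            target, dummy, schedule, n, seed, zero_condition=True
        )
        return samples
    cond = ConditionSet.empty(target.condition_modalities, n=n)
    return multi_condition_sample(target, cond, schedule, n=n, seed=seed)
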