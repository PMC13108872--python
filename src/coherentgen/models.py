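"""Conditional diffusion models over per-modality latent embeddings.

The central object is :class:`ConditionalDiffusion`, a model in the
statsmodels sense: it is built from training and validation latent
tables, and ``fit()`` returns a :class:`DiffusionFit` results object
carrying the best checkpoint, the training log and a ``summary()``.

Two conditioning regimes share one network architecture:

* **single-condition** — one fixed conditioning modality (one model per
  ordered condition -> target pair);
* **multi-condition** — several conditioning modalities with a masking
  strategy: each training batch draws a random subset of conditions (the
  empty set included by default) and zeroes out the projections of the
  rest, so one network serves every conditioning pattern, including
  fully unconditional generation.

Early stopping follows generation quality, not the denoising loss: every
``eval_interval`` epochs the model fully denoises the validation set
(conditioned on the real validation conditions) and the MSE against the
real targets decides whether the checkpoint improved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np

from .diffusion import q_sample, reverse_trajectory
from .nn import Adam, NoisePredictorMLP
from .schedule import NoiseSchedule, make_schedule

__all__ = [
    "PredictorConfig",
    "ConditionSet",
    "PredictorCheckpoint",
    "ConditionalDiffusion",
    "DiffusionFit",
    "project_conditions",
    "predict_noise",
    "train_single_condition",
    "train_multi_condition",
    "validation_generation_mse",
    "uniform_subset_sampler",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Hyperparameters of the MLP noise predictor and its training loop.

    Defaults sit inside the search ranges used for the full-scale models
    (4-7 hidden layers of 256-1024 units, 64/128-dim time embeddings,
    8-32-dim condition embeddings, learning rate 1e-4..1e-3, batches of
    64/128); reduce them for desk-scale runs.
    """

    n_hidden_layers: int = 4
    hidden_size: int = 256
    time_embed_dim: int = 64
    cond_embed_dim: int = 16
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 20000
    patience: int = 10
    eval_interval: int = 100

    def __post_init__(self):
        for name in (
            "n_hidden_layers",
            "hidden_size",
            "time_embed_dim",
            "cond_embed_dim",
            "batch_size",
            "max_epochs",
            "patience",
            "eval_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ConditionSet:
    """Named per-modality condition vectors with presence masks.

    ``entries[name]`` is an ``(n, d_name)`` array (or ``None`` when the
    modality carries no values); ``present[name]`` is a boolean per-sample
    mask.  An absent modality contributes nothing to the network — its
    projected activation is zeroed — so whatever values it carries are
    ignored exactly.
    """

    def __init__(
        self,
        entries: Mapping[str, Optional[np.ndarray]],
        present: Optional[Mapping[str, np.ndarray]] = None,
        n: Optional[int] = None,
    ):
        self.entries: Dict[str, Optional[np.ndarray]] = {}
        self.present: Dict[str, np.ndarray] = {}
        sizes = set()
        for name, v in entries.items():
            v = None if v is None else np.asarray(v, dtype=np.float64)
            if v is not None and v.ndim == 1:
                v = v[None, :]
            self.entries[name] = v
            if v is not None:
                sizes.add(v.shape[0])
        if n is None:
            if not sizes:
                raise ValueError("n must be given when all entries are empty")
            n = max(sizes)
        if sizes and sizes != {n}:
            raise ValueError(f"condition tables disagree on sample count: {sizes}")
        self.n = int(n)
        for name, v in self.entries.items():
            if present is not None and name in present:
                p = np.broadcast_to(np.asarray(present[name], bool), (self.n,)).copy()
            else:
                p = np.full(self.n, v is not None)
            if v is None:
                p = np.zeros(self.n, dtype=bool)
            self.present[name] = p

    @classmethod
    def empty(cls, names: Sequence[str], n: int) -> "ConditionSet":
        """A fully masked condition set (the unconditional input)."""
        return cls({name: None for name in names}, n=n)

    @classmethod
    def zeros(cls, dims: Mapping[str, int], n: int) -> "ConditionSet":
        """All modalities *present* but carrying zero vectors.

        This is the probe input for single-condition models, which have no
        masking pathway: the zero vector is injected as the condition value.
        """
        return cls({name: np.zeros((n, d)) for name, d in dims.items()}, n=n)

    def restrict(self, names: Sequence[str]) -> "ConditionSet":
        """Keep only ``names`` present; every other modality is masked."""
        keep = set(names)
        entries = {k: (v if k in keep else None) for k, v in self.entries.items()}
        present = {k: (self.present[k] if k in keep else np.zeros(self.n, bool)) for k in self.entries}
        return ConditionSet(entries, present, n=self.n)

    def network_input(self) -> Dict[str, tuple]:
        return {name: (self.entries[name], self.present[name]) for name in self.entries}

    def rows(self, idx) -> "ConditionSet":
        entries = {k: (None if v is None else v[idx]) for k, v in self.entries.items()}
        present = {k: self.present[k][idx] for k in self.entries}
        return ConditionSet(entries, present, n=len(np.atleast_1d(np.arange(self.n)[idx])))


def project_conditions(
    conditions: ConditionSet, projections: Mapping[str, object]
) -> np.ndarray:
    """Concatenated condition embedding with exact zero blocks when masked.

    ``projections`` maps modality name -> a Dense layer (or any object
    with ``forward``); block order follows the iteration order of
    ``projections`` and is the order baked into the network input.
    """
    n = conditions.n
    blocks = []
    for name, proj in projections.items():
        if name not in conditions.entries:
            raise KeyError(f"condition set lacks modality {name!r}")
        v = conditions.entries[name]
        mask = conditions.present[name]
        if v is None or not mask.any():
            blocks.append(np.zeros((n, proj.W.shape[1])))
        else:
            out = proj.forward(np.asarray(v, dtype=np.float64), False)
            blocks.append(np.where(mask[:, None], out, 0.0))
    unknown = set(conditions.entries) - set(projections)
    if unknown:
        raise KeyError(f"unknown condition modalities: {sorted(unknown)}")
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0))


@dataclass
class PredictorCheckpoint:
    """A trained noise predictor plus everything needed to reuse it."""

    network: NoisePredictorMLP
    config: PredictorConfig
    target_modality: str
    condition_modalities: List[str]
    best_val_mse: float
    schedule: NoiseSchedule
    training_log: Dict[int, float] = field(default_factory=dict)

    def predictor(self) -> Callable:
        """Sampling closure ``(xt, t, condition: ConditionSet) -> eps_hat``."""

        def _predict(xt, t, condition):
            cond_input = None if condition is None else condition.network_input()
            return self.network.forward(np.atleast_2d(xt), t, cond_input)

        return _predict

    # -- persistence: opaque weights blob + plain-text metadata ------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.network.params())
        meta = {
            "config": self.config.__dict__,
            "network": self.network.config(),
            "target_modality": self.target_modality,
            "condition_modalities": self.condition_modalities,
            "best_val_mse": self.best_val_mse,
            "schedule": self.schedule.to_text(),
            "training_log": {str(k): v for k, v in self.training_log.items()},
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PredictorCheckpoint":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        network = NoisePredictorMLP.from_config(meta["network"])
        with np.load(path / "weights.npz") as blob:
            network.set_params({k: blob[k] for k in blob.files})
        return cls(
            network=network,
            config=PredictorConfig(**meta["config"]),
            target_modality=meta["target_modality"],
            condition_modalities=list(meta["condition_modalities"]),
            best_val_mse=float(meta["best_val_mse"]),
            schedule=NoiseSchedule.from_text(meta["schedule"]),
            training_log={int(k): v for k, v in meta["training_log"].items()},
        )


def predict_noise(
    checkpoint: PredictorCheckpoint, xt: np.ndarray, t, conditions: ConditionSet
) -> np.ndarray:
    """Evaluation-mode noise prediction; deterministic given the inputs."""
    missing = set(conditions.entries) - set(checkpoint.condition_modalities)
    if missing:
        raise KeyError(f"checkpoint does not know modalities {sorted(missing)}")
    return checkpoint.network.forward(np.atleast_2d(xt), t, conditions.network_input())


def uniform_subset_sampler(names: Sequence[str]):
    """Uniform distribution over all subsets of ``names`` (empty included)."""
    names = list(names)

    def _draw(rng: np.random.Generator) -> List[str]:
        mask = rng.random(len(names)) < 0.5
        return [n for n, m in zip(names, mask) if m]

    return _draw


def validation_generation_mse(
    checkpoint: PredictorCheckpoint,
    val: Mapping[str, np.ndarray],
    schedule: Optional[NoiseSchedule] = None,
    seed: int = 0,
) -> float:
    """Full-generation validation error.

    Runs one complete reverse diffusion per validation sample, conditioned
    on the real validation conditions, and returns the element-wise mean
    squared error against the real targets.
    """
    schedule = schedule or checkpoint.schedule
    target = np.asarray(val[checkpoint.target_modality], dtype=np.float64)
    cond = ConditionSet(
        {m: np.asarray(val[m], dtype=np.float64) for m in checkpoint.condition_modalities},
        n=target.shape[0],
    )
    gen = reverse_trajectory(
        checkpoint.predictor(), schedule, target.shape[0], target.shape[1], cond, seed
    )
    return float(np.mean((gen - target) ** 2))


class ConditionalDiffusion:
    """Conditional denoising-diffusion model over latent tables.

    Parameters
    ----------
    train, val : mapping modality -> (n, d) array
        Latent tables aligned row-wise on the same samples.  Must contain
        ``target`` and every name in ``conditions``.
    target : str
        The modality to generate.
    conditions : sequence of str
        Conditioning modalities.  One name -> a single-condition model;
        several -> a masked multi-condition model when ``masking`` is on.
    masking : bool
        Enable the subset-masking strategy (multi-condition training).
        When off, every batch sees the full fixed condition set.
    subset_sampler : callable(rng) -> list of names, optional
        Distribution over condition subsets used when masking; defaults
        to uniform over all subsets, empty set included.
    """

    def __init__(
        self,
        train: Mapping[str, np.ndarray],
        val: Mapping[str, np.ndarray],
        target: str,
        conditions: Sequence[str],
        config: Optional[PredictorConfig] = None,
        schedule: Optional[NoiseSchedule] = None,
        masking: bool = False,
        subset_sampler=None,
    ):
        self.config = config or PredictorConfig()
        self.schedule = schedule or make_schedule(1000)
        self.target = target
        self.condition_names = list(conditions)
        self.masking = masking
        self.subset_sampler = subset_sampler or uniform_subset_sampler(self.condition_names)

        def _tables(data):
            out = {}
            for name in [target, *self.condition_names]:
                if name not in data:
                    raise KeyError(f"latent table for {name!r} missing")
                out[name] = np.asarray(data[name], dtype=np.float64)
            sizes = {v.shape[0] for v in out.values()}
            if len(sizes) != 1:
                raise ValueError(f"tables not aligned: row counts {sizes}")
            return out

        self.train_tables = _tables(train)
        self.val_tables = _tables(val)
        if self.train_tables[target].shape[0] == 0:
            raise ValueError("empty training data")

    @classmethod
    def from_dataframes(cls, train, val, target, conditions, **kwargs):
        """Build from pandas DataFrames, aligning on their shared index."""
        import pandas as pd  # local: keeps the array path pandas-free

        names = [target, *conditions]
        idx_tr = None
        for n in names:
            idx_tr = train[n].index if idx_tr is None else idx_tr.intersection(train[n].index)
        idx_va = None
        for n in names:
            idx_va = val[n].index if idx_va is None else idx_va.intersection(val[n].index)
        tr = {n: train[n].loc[idx_tr].to_numpy(float) for n in names}
        va = {n: val[n].loc[idx_va].to_numpy(float) for n in names}
        return cls(tr, va, target, conditions, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, verbose: bool = False, log_stream=None) -> "DiffusionFit":
        cfg = self.config
        rng = np.random.default_rng(seed)
        X = self.train_tables[self.target]
        n, D = X.shape
        cond_dims = {m: self.train_tables[m].shape[1] for m in self.condition_names}
        net = NoisePredictorMLP(
            D,
            cond_dims,
            n_hidden_layers=cfg.n_hidden_layers,
            hidden_size=cfg.hidden_size,
            time_embed_dim=cfg.time_embed_dim,
            cond_embed_dim=cfg.cond_embed_dim,
            seed=int(rng.integers(2**31 - 1)),
        )
        opt = Adam(lr=cfg.learning_rate)
        T = self.schedule.T

        checkpoint = PredictorCheckpoint(
            network=net,
            config=cfg,
            target_modality=self.target,
            condition_modalities=self.condition_names,
            best_val_mse=np.inf,
            schedule=self.schedule,
        )
        best_params = None
        best_mse = np.inf
        evals_since_best = 0
        training_log: Dict[int, float] = {}
        loss_log: List[float] = []
        eval_seed = int(rng.integers(2**31 - 1))

        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            nb = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x0 = X[idx]
                t = rng.integers(1, T + 1, size=len(idx))
                eps = rng.standard_normal(x0.shape)
                xt = q_sample(x0, t, eps, self.schedule)
                cond_input = self._batch_conditions(idx, rng)
                eps_hat = net._train_forward(xt, t, cond_input)
                diff = eps_hat - eps
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(target={self.target}, conditions={self.condition_names})"
                    )
                net.backward(2.0 * diff / diff.size)
                opt.step(net.params(), net.grads())
                epoch_loss += loss
                nb += 1
            loss_log.append(epoch_loss / nb)

            if epoch % cfg.eval_interval == 0 or epoch == cfg.max_epochs:
                val_mse = validation_generation_mse(
                    checkpoint, self.val_tables, self.schedule, seed=eval_seed
                )
                training_log[epoch] = val_mse
                if log_stream is not None:
                    log_stream.write(f"{epoch}\t{loss_log[-1]:.6g}\t{val_mse:.6g}\n")
                if verbose:
                    print(f"epoch {epoch}: train loss {loss_log[-1]:.4g}, val gen MSE {val_mse:.4g}")
                if val_mse < best_mse:
                    best_mse = val_mse
                    best_params = {k: v.copy() for k, v in net.params().items()}
                    evals_since_best = 0
                else:
                    evals_since_best += 1
                    if evals_since_best >= cfg.patience:
                        break

        if best_params is not None:
            net.set_params(best_params)
        checkpoint.best_val_mse = float(best_mse)
        checkpoint.training_log = training_log
        return DiffusionFit(self, checkpoint, loss_log)

    def _batch_conditions(self, idx, rng) -> Dict[str, tuple]:
        """Network-format conditions for a training batch.

        With masking on, a condition subset is drawn per batch and the
        rest is masked; otherwise the full fixed set is present.
        """
        active = (
            set(self.subset_sampler(rng)) if self.masking else set(self.condition_names)
        )
        out = {}
        nb = len(idx)
        for m in self.condition_names:
            if m in active:
                out[m] = (self.train_tables[m][idx], np.ones(nb, dtype=bool))
            else:
                out[m] = (None, np.zeros(nb, dtype=bool))
        return out


class DiffusionFit:
    """Results of :meth:`ConditionalDiffusion.fit`.

    Carries the best checkpoint (by validation generation MSE), the full
    training log, and sampling entry points.
    """

    def __init__(self, model: ConditionalDiffusion, checkpoint: PredictorCheckpoint, loss_log):
        self.model = model
        self.checkpoint = checkpoint
        self.loss_log = list(loss_log)
        self.best_val_mse = checkpoint.best_val_mse
        self.training_log = checkpoint.training_log

    def sample(self, conditions: ConditionSet, n: Optional[int] = None, seed: int = 0) -> np.ndarray:
        """Generate latent vectors conditioned on ``conditions``."""
        n = conditions.n if n is None else n
        D = self.checkpoint.network.D
        return reverse_trajectory(
            self.checkpoint.predictor(), self.checkpoint.schedule, n, D, conditions, seed
        )

    def summary(self) -> str:
        ck = self.checkpoint
        lines = [
            "Conditional diffusion fit",
            "=" * 48,
            f"target modality     : {ck.target_modality}",
            f"conditioning        : {', '.join(ck.condition_modalities) or '(none)'}",
            f"masking strategy    : {'on' if self.model.masking else 'off'}",
            f"schedule            : {ck.schedule.kind}, T={ck.schedule.T}, "
            f"beta {ck.schedule.beta_start:g}..{ck.schedule.beta_end:g}",
            f"hidden layers       : {ck.config.n_hidden_layers} x {ck.config.hidden_size}",
            f"epochs run          : {len(self.loss_log)}",
            f"best val gen MSE    : {ck.best_val_mse:.5g}",
            f"final train loss    : {self.loss_log[-1]:.5g}" if self.loss_log else "",
            "=" * 48,
        ]
        return "\n".join(filter(None, lines))


# -- spec-surface functional wrappers --------------------------------------

def train_single_condition(
    train, val, target: str, condition: str, config=None, schedule=None, seed: int = 0
) -> PredictorCheckpoint:
    """Train one single-condition model for the ordered pair condition -> target."""
    model = ConditionalDiffusion(train, val, target, [condition], config, schedule)
    return model.fit(seed=seed).checkpoint


def train_multi_condition(
    train,
    val,
    target: str,
    conditions: Sequence[str],
    config=None,
    schedule=None,
    subset_sampler=None,
    seed: int = 0,
) -> PredictorCheckpoint:
    """Train a masked multi-condition model (empty subsets included by default)."""
    model = ConditionalDiffusion(
        train, val, target, conditions, config, schedule,
        masking=True, subset_sampler=subset_sampler,
    )
    return model.fit(seed=seed).checkpoint
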