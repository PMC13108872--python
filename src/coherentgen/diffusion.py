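"""Forward and reverse diffusion primitives.

The forward process corrupts a clean latent matrix ``x0`` with Gaussian
noise according to a :class:`~coherentgen.schedule.NoiseSchedule`; the
reverse process iteratively denoises a pure-noise draw using a
noise-prediction function ``predictor(xt, t, condition) -> eps_hat``.

The closed-form marginal

    q(x_t | x_0) = N( sqrt(abar_t) x_0, (1 - abar_t) I )

permits direct sampling of any timestep (``q_sample``), and the reverse
transition mean is

    mu(x_t, t) = (x_t - beta_t / sqrt(1 - abar_t) * eps_hat) / sqrt(alpha_t)

with additive noise sqrt(beta_t) * z for t > 1 and none at the final step,
so generation terminates at the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .schedule import NoiseSchedule

__all__ = [
    "DiffusionBatch",
    "q_sample",
    "reverse_step",
    "sample",
    "reverse_trajectory",
    "gaussian_oracle_predictor",
]

# predictor signature: (xt, t, condition) -> eps_hat.  `t` is a scalar int
# during sampling and an int vector during training; `condition` is whatever
# the predictor was built for (a ConditionSet, a dict, or None).
Predictor = Callable[[np.ndarray, np.ndarray, object], np.ndarray]


@dataclass(frozen=True)
class DiffusionBatch:
    """A training batch: clean data, noise, timesteps and the noised result."""

    x0: np.ndarray
    eps: np.ndarray
    t: np.ndarray
    xt: np.ndarray

    def __post_init__(self):
        if not (self.x0.shape == self.eps.shape == self.xt.shape):
            raise ValueError("x0, eps and xt must share a shape")
        if self.t.shape != (self.x0.shape[0],):
            raise ValueError("t must have one entry per row")


def q_sample(
    x0: np.ndarray, t, eps: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """Directly sample ``x_t`` from ``x_0`` at timestep(s) ``t``.

    ``t`` may be a scalar or a per-row integer vector in ``1..T``.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError(f"shape mismatch: x0 {x0.shape} vs eps {eps.shape}")
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError("t indices must lie in 1..T")
    ab = schedule.alpha_bar(t)
    if ab.ndim == 1 and x0.ndim == 2:
        ab = ab[:, None]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def reverse_step(
    xt: np.ndarray,
    t: int,
    eps_hat: np.ndarray,
    z: Optional[np.ndarray],
    schedule: NoiseSchedule,
) -> np.ndarray:
    """One reverse-diffusion update from ``x_t`` to ``x_{t-1}``.

    Applies the posterior-mean update and, for ``t > 1``, adds
    ``sqrt(beta_t) * z``.  At ``t = 1`` the noise term is omitted and ``z``
    is ignored.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside 1..{schedule.T}")
    xt = np.asarray(xt, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if xt.shape != eps_hat.shape:
        raise ValueError("xt and eps_hat shapes differ")
    beta = schedule.beta(t)
    alpha = schedule.alpha(t)
    abar = schedule.alpha_bar(t)
    mu = (xt - beta / np.sqrt(1.0 - abar) * eps_hat) / np.sqrt(alpha)
    if t > 1:
        if z is None:
            raise ValueError("z is required for t > 1")
        mu = mu + np.sqrt(beta) * np.asarray(z, dtype=np.float64)
    return mu


def reverse_trajectory(
    predictor: Predictor,
    schedule: NoiseSchedule,
    n: int,
    D: int,
    condition=None,
    seed: int = 0,
    step_callback: Optional[Callable[[int, np.ndarray, np.ndarray], None]] = None,
) -> np.ndarray:
    """Run the full reverse loop from pure noise to a generated sample.

    The noise stream (the initial ``x_T`` draw and the per-step ``z``) is a
    pure function of ``seed``, so the output is deterministic given
    ``(predictor, schedule, condition, seed)``.  ``step_callback(t, xt,
    eps_hat)`` is invoked after each prediction and before the update,
    which is how the coherent-denoising sampler records diagnostics.
    """
    rng = np.random.default_rng(seed)
    xt = rng.standard_normal((n, D))
    if n == 0:
        return xt
    for t in range(schedule.T, 0, -1):
        try:
            eps_hat = predictor(xt, t, condition)
        except Exception as exc:  # re-raise with the step index attached
            raise RuntimeError(f"predictor failed at reverse step t={t}") from exc
        if step_callback is not None:
            step_callback(t, xt, eps_hat)
        z = rng.standard_normal((n, D)) if t > 1 else None
        xt = reverse_step(xt, t, eps_hat, z, schedule)
    return xt


def sample(
    predictor: Predictor,
    schedule: NoiseSchedule,
    n: int,
    D: int,
    condition=None,
    seed: int = 0,
) -> np.ndarray:
    """Generate ``n`` samples of dimension ``D`` by reverse diffusion."""
    return reverse_trajectory(predictor, schedule, n, D, condition, seed)


def gaussian_oracle_predictor(
    mu0: np.ndarray, Sigma0: np.ndarray, schedule: NoiseSchedule
) -> Predictor:
    """Exact noise predictor for Gaussian data ``N(mu0, Sigma0)``.

    For Gaussian data the marginal at step t is
    ``x_t ~ N(sqrt(abar_t) mu0, abar_t Sigma0 + (1 - abar_t) I)`` and the
    posterior-mean noise is available in closed form:

        E[eps | x_t] = sqrt(1 - abar_t) *
                       (abar_t Sigma0 + (1 - abar_t) I)^{-1} (x_t - sqrt(abar_t) mu0)

    Used as an independent test oracle for the sampler: reverse diffusion
    driven by this predictor must recover the data distribution's moments.
    """
    mu0 = np.atleast_1d(np.asarray(mu0, dtype=np.float64))
    Sigma0 = np.atleast_2d(np.asarray(Sigma0, dtype=np.float64))
    D = mu0.shape[0]
    if Sigma0.shape != (D, D):
        raise ValueError("Sigma0 shape must match mu0")
    if not np.allclose(Sigma0, Sigma0.T):
        raise ValueError("Sigma0 must be symmetric")
    try:
        np.linalg.cholesky(Sigma0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma0 must be positive-definite") from exc
    eye = np.eye(D)

    def predictor(xt, t, condition=None):
        ab = float(schedule.alpha_bar(t))
        cov_t = ab * Sigma0 + (1.0 - ab) * eye
        centered = np.atleast_2d(xt) - np.sqrt(ab) * mu0
        out = np.sqrt(1.0 - ab) * np.linalg.solve(cov_t, centered.T).T
        return out.reshape(np.shape(xt))

    return predictor
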