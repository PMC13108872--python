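"""Variance schedules for the Gaussian diffusion process.

A schedule fixes the per-step noise variances ``beta_t`` of the forward
(noising) chain, the retention factors ``alpha_t = 1 - beta_t`` and the
cumulative signal retention ``alpha_bar_t = prod_{s<=t} alpha_s``.  All
timestep indexing in this package is 1-based (``t`` runs over ``1..T``),
so ``betas[t - 1]`` is the variance added at step ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "make_schedule"]

_SUPPORTED_KINDS = ("linear",)


@dataclass(frozen=True)
class NoiseSchedule:
    """Fixed variance schedule of a diffusion process.

    Attributes
    ----------
    T : int
        Number of diffusion steps.
    betas, alphas, alpha_bars : ndarray, shape (T,)
        Per-step noise variance ``beta_t`` in (0, 1), retention
        ``alpha_t = 1 - beta_t`` and cumulative retention ``alpha_bar_t``
        (strictly decreasing, in (0, 1)).
    kind, beta_start, beta_end
        Construction parameters, kept so a schedule round-trips through a
        plain key-value text block instead of raw arrays.
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray = field(repr=False)
    alpha_bars: np.ndarray = field(repr=False)
    kind: str = "linear"
    beta_start: float = 1e-4
    beta_end: float = 0.02

    def __post_init__(self) -> None:
        for name in ("betas", "alphas", "alpha_bars"):
            v = getattr(self, name)
            if v.shape != (self.T,):
                raise ValueError(f"{name} must have length T={self.T}")
        if not np.all((self.betas > 0) & (self.betas < 1)):
            raise ValueError("every beta_t must lie in (0, 1)")
        if not np.all(np.diff(self.alpha_bars) < 0) and self.T > 1:
            raise ValueError("alpha_bar must be strictly decreasing")

    # -- indexing helpers (1-based t) --------------------------------------
    def beta(self, t):
        return self.betas[np.asarray(t) - 1]

    def alpha(self, t):
        return self.alphas[np.asarray(t) - 1]

    def alpha_bar(self, t):
        return self.alpha_bars[np.asarray(t) - 1]

    # -- plain-text serialization ------------------------------------------
    def to_text(self) -> str:
        return (
            f"T={self.T}\nkind={self.kind}\n"
            f"beta_start={self.beta_start!r}\nbeta_end={self.beta_end!r}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "NoiseSchedule":
        kv = dict(
            line.split("=", 1) for line in text.strip().splitlines() if "=" in line
        )
        return make_schedule(
            int(kv["T"]),
            float(kv["beta_start"]),
            float(kv["beta_end"]),
            kind=kv.get("kind", "linear"),
        )


def make_schedule(
    T: int,
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
    kind: str = "linear",
) -> NoiseSchedule:
    """Build a :class:`NoiseSchedule`.

    For ``kind="linear"`` the betas form the arithmetic progression from
    ``beta_start`` to ``beta_end`` over ``T`` steps (a single step uses
    ``beta_start``; then ``beta_start`` must equal ``beta_end``).
    """
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got {beta_start}, {beta_end}"
        )
    if kind not in _SUPPORTED_KINDS:
        raise ValueError(f"unknown schedule kind {kind!r}; supported: {_SUPPORTED_KINDS}")
    betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    return NoiseSchedule(
        T=int(T),
        betas=betas,
        alphas=alphas,
        alpha_bars=alpha_bars,
        kind=kind,
        beta_start=float(beta_start),
        beta_end=float(beta_end),
    )
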