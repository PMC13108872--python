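"""Quantitative evaluation metrics for generative reconstruction.

Covers reconstruction fidelity (pooled R-squared, across-run output
variance), distributional similarity (energy distance, k-NN manifold
precision/recall/F1), classification parity (macro F1, balanced
accuracy) and survival concordance (Harrell's C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import balanced_accuracy_score, f1_score

__all__ = [
    "MetricReport",
    "r_squared",
    "output_variance_pct",
    "energy_distance",
    "manifold_precision_recall_f1",
    "macro_f1",
    "balanced_accuracy",
    "concordance_index",
]


@dataclass
class MetricReport:
    """One metric value with optional dispersion over repeated runs."""

    metric: str
    value: float
    dispersion: Optional[float] = None
    n_runs: int = 1
    context: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.n_runs > 1) != (self.dispersion is not None):
            raise ValueError("dispersion must be present exactly when n_runs > 1")

    def as_row(self) -> Dict[str, object]:
        row = {"metric": self.metric, "value": self.value,
               "sd": self.dispersion, "n_runs": self.n_runs}
        row.update(self.context)
        return row


def r_squared(real: np.ndarray, generated: np.ndarray) -> float:
    """Coefficient of determination, pooled over samples and features.

    ``1 - SS_res / SS_tot`` where the total sum of squares is taken about
    the real matrix's per-feature means — so a generator that outputs the
    per-feature mean scores exactly 0, and anything worse than that
    mean-baseline scores negative.
    """
    real = np.asarray(real, dtype=np.float64)
    generated = np.asarray(generated, dtype=np.float64)
    if real.shape != generated.shape:
        raise ValueError(f"shape mismatch: {real.shape} vs {generated.shape}")
    ss_tot = np.sum((real - real.mean(axis=0)) ** 2)
    if ss_tot == 0:
        raise ValueError("real data has zero total variance")
    ss_res = np.sum((real - generated) ** 2)
    return float(1.0 - ss_res / ss_tot)


def output_variance_pct(runs: Sequence[np.ndarray], real: np.ndarray) -> float:
    """Across-run generation variance as a percentage of real variance.

    Per sample and feature, the (unbiased) variance across the generated
    runs; averaged over samples and features; divided by the mean
    per-feature variance of the real data; times 100.  A model that is
    certain of its output scores near 0%; one whose run-to-run spread
    matches the data spread scores near 100%.
    """
    if len(runs) < 2:
        raise ValueError("need at least two generation runs")
    stack = np.stack([np.asarray(r, dtype=np.float64) for r in runs])
    real = np.asarray(real, dtype=np.float64)
    if stack.shape[1:] != real.shape:
        raise ValueError("runs and real data must share a shape")
    real_var = real.var(axis=0, ddof=1).mean()
    if real_var == 0:
        raise ValueError("real data has zero variance")
    run_var = stack.var(axis=0, ddof=1).mean()
    return float(100.0 * run_var / real_var)


def energy_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Energy distance between two finite sample sets (un-rooted V-statistic).

    ``2 E|a - b| - E|a - a'| - E|b - b'|`` with expectations over all
    ordered pairs (diagonals included).  Symmetric, non-negative, and zero
    iff the two multisets coincide.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.size == 0 or B.size == 0:
        raise ValueError("sample sets must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    ab = cdist(A, B).mean()
    aa = cdist(A, A).mean()
    bb = cdist(B, B).mean()
    return float(2.0 * ab - aa - bb)


def manifold_precision_recall_f1(
    real: np.ndarray, generated: np.ndarray, k: int = 5
):
    """k-NN manifold precision, recall and F1 between sample sets.

    The real manifold is estimated as the union of balls centred on each
    real point with radius equal to its distance to its k-th nearest real
    neighbour (self excluded); precision is the fraction of generated
    points falling inside it.  Recall is the symmetric quantity with the
    roles swapped.  F1 is the harmonic mean (0 when both vanish).
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    generated = np.atleast_2d(np.asarray(generated, dtype=np.float64))
    if k >= len(real) or k >= len(generated):
        raise ValueError(f"k={k} must be smaller than both set sizes")

    def _covered_fraction(points, support):
        d_ss = cdist(support, support)
        np.fill_diagonal(d_ss, np.inf)
        radii = np.sort(d_ss, axis=1)[:, k - 1]
        d_ps = cdist(points, support)
        return float(np.mean(np.any(d_ps <= radii[None, :], axis=1)))

    precision = _covered_fraction(generated, real)
    recall = _covered_fraction(real, generated)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _check_labels(y, y_hat):
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    if y.size == 0:
        raise ValueError("empty label vectors")
    if y.shape != y_hat.shape:
        raise ValueError("label vectors must have the same length")
    return y, y_hat


def macro_f1(y, y_hat) -> float:
    """Unweighted mean per-class F1 over the union of observed labels.

    A class that is predicted but never occurs in ``y`` contributes an F1
    of 0 to the average.
    """
    y, y_hat = _check_labels(y, y_hat)
    labels = np.unique(np.concatenate([y, y_hat]))
    return float(f1_score(y, y_hat, labels=labels, average="macro", zero_division=0))


def balanced_accuracy(y, y_hat) -> float:
    """Mean per-class recall over the classes present in ``y``."""
    y, y_hat = _check_labels(y, y_hat)
    return float(balanced_accuracy_score(y, y_hat))


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's concordance index.

    A pair is comparable when the earlier time carries an observed event;
    it is concordant when the shorter survivor has the higher risk, and
    risk ties count one half.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(bool)
    risk = np.asarray(risk_scores, dtype=np.float64)
    if not (times.shape == events.shape == risk.shape):
        raise ValueError("times, events and risk_scores must align")
    n = len(times)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if not events[i]:
            continue
        # j outlives i (later time, or equal time but censored)
        later = (times > times[i]) | ((times == times[i]) & ~events)
        later[i] = False
        comparable += int(later.sum())
        concordant += np.sum(risk[later] < risk[i]) + 0.5 * np.sum(risk[later] == risk[i])
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return float(concordant / comparable)
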