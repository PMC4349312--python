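"""Sensitivity/specificity with stratified bootstrap confidence intervals.

Sensitivity is the proportion of known positive sites a model classifies as
positive, specificity the proportion of known negative sites classified as
negative, with a suitability threshold (default 0.5, reported alongside the
estimates). Confidence intervals are percentile intervals over stratified
bootstrap replicates: presences and absences are resampled separately with
replacement at their original sizes, so every replicate keeps the class
balance of the data (2000 replicates at the 95% level by default).

Evaluation deliberately reuses the training occurrence table — the goal is
a descriptive suitability score, and the interface offers no hidden split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_THRESHOLD = 0.5
DEFAULT_N_REPS = 2000
DEFAULT_LEVEL = 0.95


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_counts(predictions, labels, threshold: float = DEFAULT_THRESHOLD) -> ConfusionCounts:
    """Tally the 2x2 confusion table; predicted positive iff p >= threshold."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size == 0:
        raise InputError("empty prediction vector")
    if p.shape != y.shape:
        raise InputError(f"length mismatch: {p.shape} vs {y.shape}")
    if np.any((p < 0) | (p > 1)):
        raise InputError("predictions must lie in [0, 1]")
    pos = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        tn=int(np.sum(~pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
    )


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity); NaN when the relevant class is absent."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else np.nan
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else np.nan
    return sens, spec


def _metric_values(p, y, metric, threshold):
    counts = confusion_counts(p, y, threshold)
    sens, spec = sens_spec(counts)
    if metric == "sensitivity":
        return sens
    if metric == "specificity":
        return spec
    return metric(p, y)


def bootstrap_ci(
    predictions,
    labels,
    metric="sensitivity",
    n_reps: int = DEFAULT_N_REPS,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for a classification metric.

    Presences and absences are resampled separately with replacement at
    their original sizes. ``metric`` is "sensitivity", "specificity", or a
    callable ``metric(predictions, labels) -> float``. Raises if the metric
    is undefined in more than half of the replicates.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    pres = np.flatnonzero(y == 1)
    abse = np.flatnonzero(y == 0)
    if len(pres) == 0 or len(abse) == 0:
        raise InputError("stratified bootstrap needs both classes")
    rng = np.random.default_rng(seed)

    if metric in ("sensitivity", "specificity"):
        # class-local fast path: each metric depends on one stratum only,
        # but both strata are always resampled to keep the seed stream
        # identical to the general path
        idx_p = rng.integers(0, len(pres), size=(n_reps, len(pres)))
        idx_a = rng.integers(0, len(abse), size=(n_reps, len(abse)))
        if metric == "sensitivity":
            vals = (p[pres][idx_p] >= threshold).mean(axis=1)
        else:
            vals = (p[abse][idx_a] < threshold).mean(axis=1)
    else:
        vals = np.empty(n_reps)
        for r in range(n_reps):
            idx_p = rng.integers(0, len(pres), size=len(pres))
            idx_a = rng.integers(0, len(abse), size=len(abse))
            take = np.concatenate([pres[idx_p], abse[idx_a]])
            vals[r] = _metric_values(p[take], y[take], metric, threshold)
    bad = np.isnan(vals)
    if bad.mean() > 0.5:
        raise InputError("metric undefined in more than half the replicates")
    alpha = (1.0 - level) / 2.0
    low, high = np.nanpercentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)


@dataclass
class AccuracyReport:
    """Per-model sensitivity/specificity with bootstrap CIs."""

    table: pd.DataFrame  # columns: species, model, metric, estimate, ci_low, ci_high
    threshold: float
    n_replicates: int
    level: float
    ci_method: str = "stratified percentile bootstrap"

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["threshold"] = self.threshold
        out["n_replicates"] = self.n_replicates
        out["ci_method"] = self.ci_method
        out.to_csv(path, index=False)


def evaluate_models(
    predictions_by_model: dict[str, np.ndarray],
    labels,
    species: str = "synthetic",
    threshold: float = DEFAULT_THRESHOLD,
    n_reps: int = DEFAULT_N_REPS,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> AccuracyReport:
    """Sensitivity/specificity (with CIs) for each model's predictions."""
    rows = []
    for i, (model, preds) in enumerate(predictions_by_model.items()):
        counts = confusion_counts(preds, labels, threshold)
        sens, spec = sens_spec(counts)
        for j, (metric, est) in enumerate(
            (("sensitivity", sens), ("specificity", spec))
        ):
            low, high = bootstrap_ci(
                preds, labels, metric=metric, n_reps=n_reps, level=level,
                seed=seed + 17 * i + j, threshold=threshold,
            )
            rows.append((species, model, metric, est, low, high))
    return AccuracyReport(
        table=pd.DataFrame(
            rows,
            columns=["species", "model", "metric", "estimate", "ci_low", "ci_high"],
        ),
        threshold=threshold,
        n_replicates=n_reps,
        level=level,
    )
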