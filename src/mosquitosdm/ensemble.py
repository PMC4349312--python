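"""Shared model machinery: balanced samples, bootstrap ensembles, grid
prediction, and variable-importance aggregation.

All three model families (clustered discriminant analysis, balanced-subset
forests, balanced-bootstrap logistic regression) share the same skeleton: a
submodel fitter is applied to seeded balanced samples of the occurrence
table, and the ensemble's suitability is the plain arithmetic mean of the
submodels' [0,1] outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, InputError, PredictionError
from .landscape import Landscape

logger = logging.getLogger(__name__)


def derive_seed(master: int, index: int) -> int:
    """Deterministic child seed for submodel *index*, < 2**31."""
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class BalancedSample:
    """Positional indices of an equal number of presences and absences."""

    presence_idx: np.ndarray
    absence_idx: np.ndarray
    with_replacement: bool

    @property
    def m(self) -> int:
        return len(self.presence_idx)

    def indices(self) -> np.ndarray:
        return np.concatenate([self.presence_idx, self.absence_idx])


def draw_balanced_sample(
    table: pd.DataFrame,
    m: int,
    with_replacement: bool = True,
    seed: int = 0,
) -> BalancedSample:
    """Draw m presence and m absence records (positional indices), seeded."""
    presence_pos = np.flatnonzero(table["presence"].to_numpy() == 1)
    absence_pos = np.flatnonzero(table["presence"].to_numpy() == 0)
    if len(presence_pos) == 0 or len(absence_pos) == 0:
        raise InputError("balanced sampling needs both presence and absence records")
    if not with_replacement and m > min(len(presence_pos), len(absence_pos)):
        raise InputError(
            f"m={m} exceeds a class size "
            f"({len(presence_pos)} presences, {len(absence_pos)} absences) "
            "without replacement"
        )
    rng = np.random.default_rng(seed)
    p = rng.choice(presence_pos, size=m, replace=with_replacement)
    a = rng.choice(absence_pos, size=m, replace=with_replacement)
    return BalancedSample(p, a, with_replacement)


def default_m(table: pd.DataFrame, cap: int = 150) -> int:
    """Bootstrap sample size per class: min class count, capped at 150."""
    counts = table["presence"].value_counts()
    return int(min(int(counts.min()), cap))


@dataclass
class SuitabilityEnsemble:
    """A fitted collection of submodels averaged into one suitability score.

    Every submodel exposes ``predict(X) -> array in [0,1]`` over rows of a
    feature matrix ordered as ``feature_names``; the ensemble output is the
    arithmetic mean. Submodels that failed to fit are recorded, not silently
    dropped.
    """

    family: str
    submodels: list = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    m: int | None = None
    seeds: list[int] = field(default_factory=list)
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def n_submodels(self) -> int:
        return len(self.submodels)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise PredictionError(f"missing features at predict time: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise PredictionError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """Mean submodel suitability for each row of X, in [0,1]."""
        if not self.submodels:
            raise PredictionError("ensemble has no fitted submodels")
        mat = self._matrix(X)
        acc = np.zeros(mat.shape[0])
        for sub in self.submodels:
            acc += np.clip(np.asarray(sub.predict(mat), dtype=float), 0.0, 1.0)
        return acc / len(self.submodels)


def fit_ensemble(
    fit_one: Callable[[np.ndarray, np.ndarray, int], object],
    table: pd.DataFrame,
    feature_names: Sequence[str],
    n_submodels: int = 100,
    m: int | None = None,
    with_replacement: bool = True,
    seed: int = 0,
    family: str = "ensemble",
    max_failure_frac: float = 0.1,
) -> SuitabilityEnsemble:
    """Fit *n_submodels* on seeded balanced bootstrap samples and average.

    ``fit_one(X, y, seed)`` must return an object with ``predict``. Submodel
    i trains on the balanced sample drawn with ``derive_seed(seed, i)``. The
    ensemble fails if more than ``max_failure_frac`` of submodels fail.
    """
    if n_submodels < 1:
        raise InputError("n_submodels must be >= 1")
    if m is None:
        m = default_m(table)
    feature_names = list(feature_names)
    X_all = table[feature_names].to_numpy(dtype=float)
    y_all = table["presence"].to_numpy(dtype=int)
    ens = SuitabilityEnsemble(family=family, feature_names=feature_names, m=m)
    for i in range(n_submodels):
        child = derive_seed(seed, i)
        sample = draw_balanced_sample(table, m, with_replacement, seed=child)
        idx = sample.indices()
        try:
            sub = fit_one(X_all[idx], y_all[idx], child)
        except Exception as exc:  # noqa: BLE001 - failures are policy, not bugs
            ens.n_failed += 1
            ens.failures.append(f"submodel {i}: {exc}")
            logger.warning("submodel %d failed: %s", i, exc)
            continue
        ens.submodels.append(sub)
        ens.seeds.append(child)
    if ens.n_failed > max_failure_frac * n_submodels:
        raise FitError(
            f"{ens.n_failed}/{n_submodels} submodels failed: {ens.failures[:3]}"
        )
    return ens


def predict_grid(
    ensemble,
    features: dict[str, np.ndarray],
    landscape: Landscape,
) -> np.ndarray:
    """Predict suitability for every valid pixel; nodata propagates NaN."""
    missing = [f for f in ensemble.feature_names if f not in features]
    if missing:
        raise PredictionError(f"missing feature rasters: {missing}")
    stack = np.stack(
        [features[f] for f in ensemble.feature_names], axis=-1
    )  # (H, W, p)
    valid = landscape.valid & ~np.isnan(stack).any(axis=-1)
    out = np.full(landscape.shape, np.nan)
    if valid.any():
        out[valid] = ensemble.predict(stack[valid])
    return out


def aggregate_importance(
    contributions: Sequence[pd.Series],
    mode: str = "rank",
) -> pd.DataFrame:
    """Aggregate per-submodel variable importances into one table.

    ``mode="rank"``: each Series holds within-submodel ranks (1 = most
    important); scores are mean ranks, sorted ascending. ``mode="gini"``:
    each Series holds non-negative Gini impurity decreases; scores are means,
    sorted descending. Ties break alphabetically. The returned frame has
    columns ``variable, score, n_submodels`` in final order; ``.head(10)``
    is the reported top-10 view.
    """
    if len(contributions) == 0:
        raise InputError("need at least one submodel contribution")
    if mode not in ("rank", "gini"):
        raise InputError(f"unknown importance mode '{mode}'")
    df = pd.DataFrame({i: s for i, s in enumerate(contributions)})
    score = df.mean(axis=1, skipna=True)
    n = df.notna().sum(axis=1)
    out = pd.DataFrame(
        {"variable": score.index, "score": score.to_numpy(), "n_submodels": n.to_numpy()}
    )
    ascending = mode == "rank"
    out = out.sort_values(
        ["score", "variable"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def rank_descending(values: pd.Series) -> pd.Series:
    """Ranks 1..p for a vector of importances, largest value = rank 1."""
    return values.rank(ascending=False, method="average")
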