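"""Balanced-subset forest ensemble with Gini variable importance.

When presences and absences are unequal, forests trained on the raw table
drift toward the prevalent class. The remedy used here: five balanced
subsets are drawn (the minority class kept whole, the majority class
downsampled without replacement to match), one classification forest is
fitted per subset, and the final suitability is the arithmetic mean of the
five forests' presence probabilities. The forests themselves are not
additionally bootstrapped at the ensemble level — the per-tree bagging
inside each forest already plays that role.

Tree growing is delegated to scikit-learn's RandomForestClassifier (Gini
splits, bootstrap per tree, mtry = floor(sqrt(p)) by default, grown to
purity); variable importance is the forest's accumulated mean decrease in
Gini impurity, averaged over the five subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import FitError, InputError, PredictionError
from .ensemble import SuitabilityEnsemble, derive_seed

logger = logging.getLogger(__name__)

N_SUBSETS = 5
DEFAULT_N_TREES = 500


def make_balanced_subsets(
    table: pd.DataFrame,
    n_subsets: int = N_SUBSETS,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Draw balanced record subsets: minority class whole, majority downsampled.

    Each subset keeps every record of the rarer class and an equally sized
    random subset (without replacement) of the commoner class, so a species
    with 73 presences among 709 absences yields subsets of 73+73 records.
    """
    y = table["presence"].to_numpy(dtype=int)
    n_pres, n_abs = int((y == 1).sum()), int((y == 0).sum())
    if n_pres == 0 or n_abs == 0:
        raise InputError("both presence and absence records are required")
    minority_label = 1 if n_pres <= n_abs else 0
    minority_pos = np.flatnonzero(y == minority_label)
    majority_pos = np.flatnonzero(y != minority_label)
    m = len(minority_pos)
    subsets = []
    for i in range(n_subsets):
        rng = np.random.default_rng(derive_seed(seed, i))
        take = rng.choice(majority_pos, size=m, replace=False)
        idx = np.concatenate([minority_pos, take])
        subsets.append(table.iloc[np.sort(idx)].reset_index(drop=True))
    return subsets


@dataclass
class ForestModel:
    """One fitted forest over a balanced subset."""

    clf: RandomForestClassifier
    feature_names: list[str]
    vote: str = "soft"  # soft = mean leaf probability, hard = majority votes
    gini_importance: pd.Series = field(default=None)  # type: ignore[assignment]

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.vote == "hard":
            votes = np.mean(
                [t.predict(X) for t in self.clf.estimators_], axis=0
            )
            return votes
        proba = self.clf.predict_proba(X)
        col = list(self.clf.classes_).index(1)
        return proba[:, col]

    @property
    def oob_accuracy(self) -> float | None:
        return getattr(self.clf, "oob_score_", None)


def fit_forest(
    subset: pd.DataFrame,
    feature_names,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int | str = "sqrt",
    seed: int = 0,
    vote: str = "soft",
    oob: bool = False,
    bootstrap: bool = True,
) -> ForestModel:
    """Grow one classification forest on a balanced subset.

    ``mtry`` is the number of candidate features per split (default
    floor(sqrt(p))); trees are grown to purity (min leaf = 1) on per-tree
    bootstrap samples of the subset.
    """
    feature_names = list(feature_names)
    if len(subset) < 2:
        raise FitError("cannot grow a forest on fewer than 2 records")
    if n_trees < 1:
        raise InputError("n_trees must be >= 1")
    p = len(feature_names)
    if isinstance(mtry, int) and not (1 <= mtry <= p):
        raise InputError(f"mtry={mtry} outside [1, {p}]")
    X = subset[feature_names].to_numpy(dtype=float)
    y = subset["presence"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise FitError("subset contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=mtry,
        min_samples_leaf=1,
        bootstrap=bootstrap,
        oob_score=oob and bootstrap,
        random_state=seed % (2**31),
        n_jobs=1,
    )
    clf.fit(X, y)
    importance = pd.Series(clf.feature_importances_, index=feature_names)
    return ForestModel(
        clf=clf, feature_names=feature_names, vote=vote, gini_importance=importance
    )


def fit_forest_ensemble(
    table: pd.DataFrame,
    feature_names,
    n_subsets: int = N_SUBSETS,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int | str = "sqrt",
    seed: int = 0,
    vote: str = "soft",
) -> SuitabilityEnsemble:
    """Fit the five-balanced-subset forest ensemble on an occurrence table."""
    subsets = make_balanced_subsets(table, n_subsets=n_subsets, seed=seed)
    ens = SuitabilityEnsemble(
        family="forest", feature_names=list(feature_names), m=len(subsets[0]) // 2
    )
    for i, subset in enumerate(subsets):
        child = derive_seed(seed, 1000 + i)
        ens.submodels.append(
            fit_forest(
                subset, feature_names, n_trees=n_trees, mtry=mtry,
                seed=child, vote=vote,
            )
        )
        ens.seeds.append(child)
    return ens


def predict_forest_ensemble(models, X) -> np.ndarray:
    """Mean over forests of the per-forest mean tree output; in [0,1]."""
    if len(models) == 0:
        raise PredictionError("no forest models supplied")
    preds = np.stack([np.asarray(m.predict(X), dtype=float) for m in models])
    return preds.mean(axis=0)


def forest_importance(ensemble: SuitabilityEnsemble) -> list[pd.Series]:
    """Per-subset mean-decrease-in-Gini series, for rank aggregation."""
    return [m.gini_importance for m in ensemble.submodels]
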