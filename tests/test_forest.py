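"""Balanced-subset forests, CART equivalence, Gini importance."""

import numpy as np
import pandas as pd
import pytest

from mosquitosdm import (
    fit_forest,
    fit_forest_ensemble,
    make_balanced_subsets,
    predict_forest_ensemble,
)
from mosquitosdm.errors import FitError, InputError


def make_table(n_pres, n_abs, n_features=3, seed=0, separable=False):
    gen = np.random.default_rng(seed)
    n = n_pres + n_abs
    y = np.array([1] * n_pres + [0] * n_abs)
    data = {"point_id": np.arange(n), "presence": y}
    for j in range(n_features):
        data[f"f{j}"] = gen.normal(size=n)
    if separable:
        data["f0"] = y * 2.0 + gen.normal(scale=0.1, size=n)
    return pd.DataFrame(data)


def exhaustive_cart_oracle(X, y):
    """Depth-recursive CART with exhaustive split search (tiny inputs only).

    Candidate thresholds are midpoints of sorted unique values per feature;
    the best split maximises the weighted Gini impurity decrease. Returns a
    predict function giving leaf presence fractions.
    """

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = labels.mean()
        return 1 - p**2 - (1 - p) ** 2

    def build(idx):
        labels = y[idx]
        if len(np.unique(labels)) <= 1 or len(idx) <= 1:
            return ("leaf", labels.mean())
        parent = gini(labels) * len(idx)
        best = None
        for j in range(X.shape[1]):
            vals = np.unique(X[idx, j])
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = idx[X[idx, j] <= thr]
                right = idx[X[idx, j] > thr]
                score = parent - gini(y[left]) * len(left) - gini(y[right]) * len(right)
                if best is None or score > best[0] + 1e-12:
                    best = (score, j, thr, left, right)
        if best is None or best[0] <= 1e-12:
            return ("leaf", labels.mean())
        _, j, thr, left, right = best
        return ("node", j, thr, build(left), build(right))

    tree = build(np.arange(len(y)))

    def predict_one(x, node=tree):
        if node[0] == "leaf":
            return node[1]
        _, j, thr, left, right = node
        return predict_one(x, left if x[j] <= thr else right)

    return lambda Xq: np.array([predict_one(x) for x in Xq])


def test_balanced_subsets_for_rare_species_counts():
    table = make_table(73, 709)
    subsets = make_balanced_subsets(table, n_subsets=5, seed=1)
    assert len(subsets) == 5
    for sub in subsets:
        assert len(sub) == 146
        assert (sub["presence"] == 1).sum() == 73
        assert (sub["presence"] == 0).sum() == 73
        # majority drawn without replacement
        absences = sub.loc[sub["presence"] == 0, "point_id"]
        assert absences.is_unique


def test_balanced_subsets_when_already_balanced():
    table = make_table(100, 100)
    subsets = make_balanced_subsets(table, seed=2)
    for sub in subsets:
        assert len(sub) == 200


def test_balanced_subsets_deterministic():
    table = make_table(30, 80)
    a = make_balanced_subsets(table, seed=5)
    b = make_balanced_subsets(table, seed=5)
    for sa, sb in zip(a, b):
        pd.testing.assert_frame_equal(sa, sb)


def test_balanced_subsets_require_both_classes():
    with pytest.raises(InputError):
        make_balanced_subsets(make_table(10, 0), seed=0)


def test_perfectly_separating_feature_gives_training_accuracy_one():
    table = make_table(40, 40, separable=True, seed=3)
    model = fit_forest(table, ["f0", "f1", "f2"], n_trees=50, seed=1)
    preds = model.predict(table[["f0", "f1", "f2"]])
    assert np.array_equal((preds >= 0.5).astype(int), table["presence"])


def test_single_tree_no_bootstrap_matches_exhaustive_cart(rng):
    # tiny, noiseless: both implementations must find the same partition
    X = np.round(rng.normal(size=(16, 2)), 1)
    y = (X[:, 0] + 0.3 * X[:, 1] > 0).astype(int)
    table = pd.DataFrame({"f0": X[:, 0], "f1": X[:, 1], "presence": y,
                          "point_id": np.arange(16)})
    model = fit_forest(
        table, ["f0", "f1"], n_trees=1, mtry=2, seed=0, bootstrap=False
    )
    oracle = exhaustive_cart_oracle(X, y)
    grid = rng.normal(size=(30, 2))
    np.testing.assert_allclose(model.predict(grid), oracle(grid), atol=1e-12)


def test_gini_impurity_endpoints():
    # structural sanity of the impurity criterion on pure and 50/50 leaves
    pure = np.array([1, 1, 1, 1])
    mixed = np.array([0, 1, 0, 1])
    gini = lambda v: 1 - v.mean() ** 2 - (1 - v.mean()) ** 2
    assert gini(pure) == 0.0
    assert gini(mixed) == 0.5


def test_forest_ensemble_is_five_unbootstrapped_submodels(occurrence_table, features):
    ens = fit_forest_ensemble(
        occurrence_table, list(features), n_trees=20, seed=1
    )
    assert ens.family == "forest"
    assert ens.n_submodels == 5  # exactly the balanced subsets; no extra bootstrap layer


def test_ensemble_prediction_averages_forests(rng):
    class Stub:
        def __init__(self, v):
            self.v = v

        def predict(self, X):
            return np.full(np.asarray(X).shape[0], self.v)

    models = [Stub(v) for v in (0.0, 0.0, 0.0, 1.0, 1.0)]
    out = predict_forest_ensemble(models, np.zeros((4, 2)))
    np.testing.assert_allclose(out, 0.4)

    models = [Stub(1.0)] * 5
    np.testing.assert_allclose(predict_forest_ensemble(models, np.zeros((2, 2))), 1.0)

    vals = rng.uniform(0, 1, 5)
    models = [Stub(v) for v in vals]
    np.testing.assert_allclose(
        predict_forest_ensemble(models, np.zeros((3, 2))), vals.mean()
    )


def test_oob_accuracy_reaches_one_on_separable_data():
    table = make_table(60, 60, separable=True, seed=4)
    model = fit_forest(table, ["f0", "f1", "f2"], n_trees=200, seed=2, oob=True)
    assert model.oob_accuracy == pytest.approx(1.0, abs=0.02)


def test_noise_feature_permutation_leaves_true_ranks(rng):
    hits = 0
    for run in range(10):
        gen = np.random.default_rng(100 + run)
        n = 120
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        f_true = y + gen.normal(scale=0.3, size=n)
        f_noise = gen.normal(size=n)
        table = pd.DataFrame({
            "point_id": np.arange(n), "presence": y,
            "signal": f_true, "noise": f_noise,
        })
        m1 = fit_forest(table, ["signal", "noise"], n_trees=100, seed=run)
        table2 = table.copy()
        table2["noise"] = gen.permutation(f_noise)
        m2 = fit_forest(table2, ["signal", "noise"], n_trees=100, seed=run)
        top1 = m1.gini_importance.idxmax()
        top2 = m2.gini_importance.idxmax()
        hits += top1 == top2 == "signal"
    assert hits >= 9


def test_degenerate_subset_rejected():
    table = make_table(1, 0)
    with pytest.raises(FitError):
        fit_forest(table, ["f0"], n_trees=5, seed=0)


def test_hard_vote_mode_stays_in_unit_interval():
    table = make_table(30, 30, separable=True, seed=5)
    model = fit_forest(table, ["f0", "f1", "f2"], n_trees=30, seed=1, vote="hard")
    preds = model.predict(table[["f0", "f1", "f2"]])
    assert np.all((preds >= 0) & (preds <= 1))
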