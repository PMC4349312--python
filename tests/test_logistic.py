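"""IRLS logistic fits, |z| ranking, Moran's I correlogram."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mosquitosdm import (
    fit_ensemble,
    fit_logistic,
    make_logistic_fitter,
    moran_correlogram,
    rank_variables_logistic,
    screen_features,
)
from mosquitosdm.errors import InputError
from mosquitosdm.logistic import deviance_residuals


def simulate_logit(n, beta, intercept, seed):
    gen = np.random.default_rng(seed)
    X = gen.normal(size=(n, len(beta)))
    p = expit(intercept + X @ np.asarray(beta))
    y = (gen.random(n) < p).astype(int)
    return X, y


def moran_double_sum(z, w):
    """Moran's I by explicit double loops (independent arithmetic path)."""
    n = len(z)
    zc = z - np.mean(z)
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * zc[i] * zc[j]
            s0 += w[i, j]
    return (n / s0) * num / np.sum(zc**2)


def test_intercept_only_balanced_sample_predicts_half():
    X = np.zeros((20, 0))
    y = np.array([1, 0] * 10)
    fit = fit_logistic(X, y, feature_names=[])
    assert fit.intercept == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(fit.predict(np.zeros((5, 0))), 0.5, atol=1e-8)


def test_coefficients_within_3se_of_truth():
    X, y = simulate_logit(2000, [1.2, -0.8], 0.5, seed=1)
    fit = fit_logistic(X, y, feature_names=["x1", "x2"])
    assert fit.converged and not fit.regularized
    # fit is on z-scored features: rescale truth by the feature sd
    sd = X.std(axis=0)
    for est, se, truth in zip(fit.coef, fit.se[1:], np.array([1.2, -0.8]) * sd):
        assert abs(est - truth) < 3 * se


def test_loglik_matches_direct_optimizer_on_8_points():
    from scipy.optimize import minimize

    gen = np.random.default_rng(4)
    X = gen.normal(size=(8, 1))
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
    fit = fit_logistic(X, y, feature_names=["x"])
    assert not fit.regularized  # oracle below is the unpenalized optimum
    Z = (X - X.mean(axis=0)) / X.std(axis=0)

    def nll(b):
        eta = b[0] + Z[:, 0] * b[1]
        return -np.sum(y * eta - np.logaddexp(0, eta))

    res = minimize(nll, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_matches_statsmodels_reference_fit():
    sm = pytest.importorskip("statsmodels.api")
    X, y = simulate_logit(500, [0.9, -0.5, 0.2], -0.3, seed=7)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    fit = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
    np.testing.assert_allclose(fit.intercept, ref.params[0], atol=1e-6)
    np.testing.assert_allclose(fit.coef, ref.params[1:], atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-5)


def test_separated_data_triggers_flagged_ridge_fallback():
    X = np.linspace(-1, 1, 30)[:, None]
    y = (X[:, 0] > 0).astype(int)
    fit = fit_logistic(X, y, feature_names=["x"])
    assert fit.regularized
    assert np.all(np.isfinite(fit.coef)) and np.all(np.isfinite(fit.se))


def test_n_not_greater_than_p_rejected():
    X = np.random.default_rng(0).normal(size=(5, 6))
    y = np.array([0, 1, 0, 1, 1])
    with pytest.raises(InputError):
        fit_logistic(X, y)


def test_rmse_improves_with_sample_size():
    beta = np.array([1.0, -0.6, 0.3])
    rmse = {}
    for n in (500, 4000):
        errs = []
        for seed in range(20):
            X, y = simulate_logit(n, beta, 0.2, seed=1000 + seed)
            fit = fit_logistic(X, y)
            est = fit.coef / X.std(axis=0)  # back to raw scale
            errs.append(np.mean((est - beta) ** 2))
        rmse[n] = np.sqrt(np.mean(errs))
    assert rmse[4000] < rmse[500]


def test_single_fit_z_ranking():
    fit = fit_logistic(*simulate_logit(300, [2.0, 0.5, -0.1], 0.0, seed=2),
                       feature_names=["a", "b", "c"])
    out = rank_variables_logistic([fit])
    assert list(out["variable"]) == list(
        fit.z_values.abs().sort_values(ascending=False).index
    )


def test_average_ranks_match_brute_force_over_5_fits():
    fits = [
        fit_logistic(*simulate_logit(300, [1.0, -0.5], 0.0, seed=s),
                     feature_names=["a", "b"])
        for s in range(5)
    ]
    out = rank_variables_logistic(fits).set_index("variable")
    ranks = np.array([
        f.z_values.abs().rank(ascending=False).to_numpy() for f in fits
    ])
    brute = ranks.mean(axis=0)
    for name, expect in zip(["a", "b"], brute):
        assert out.loc[name, "score"] == pytest.approx(expect)


def test_screen_drops_near_duplicates():
    gen = np.random.default_rng(4)
    a = gen.normal(size=200)
    table = pd.DataFrame({
        "a": a, "dup": a + gen.normal(scale=1e-4, size=200),
        "b": gen.normal(size=200), "const": 1.0,
    })
    kept = screen_features(table, ["a", "dup", "b", "const"])
    assert kept == ["a", "b"]


def test_glm_ensemble_monotone_when_coefficients_share_sign(occurrence_table):
    feats = ["NDVI A1", "DLST A0"]
    ens = fit_ensemble(
        make_logistic_fitter(feats), occurrence_table, feats,
        n_submodels=20, seed=3, family="glm",
    )
    signs = {np.sign(s.coef[0]) for s in ens.submodels}
    if len(signs) == 1:  # monotonicity only guaranteed for shared sign
        sweep = np.column_stack([
            np.linspace(0.0, 0.6, 25),
            np.full(25, occurrence_table["DLST A0"].mean()),
        ])
        preds = ens.predict(sweep)
        diffs = np.diff(preds)
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)
    preds = ens.predict(occurrence_table)
    assert np.all((preds >= 0) & (preds <= 1))


def test_alternating_transect_negative_moran():
    coords = np.column_stack([np.arange(10.0), np.zeros(10)])
    resid = np.array([1.0, -1.0] * 5)
    out = moran_correlogram(resid, coords, bin_edges=[0.5, 1.5])
    assert out.loc[0, "moran_i"] < 0


def test_six_point_configuration_matches_double_sum():
    coords = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1]], dtype=float)
    resid = np.array([0.4, -0.2, 0.7, -0.5, 0.1, -0.3])
    out = moran_correlogram(resid, coords, bin_edges=[0.5, 1.1])
    dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    w = ((dist >= 0.5) & (dist < 1.1)).astype(float)
    np.fill_diagonal(w, 0.0)
    expected = moran_double_sum(resid, w)
    assert out.loc[0, "moran_i"] == pytest.approx(expected, abs=1e-12)
    # frozen from the double-sum arithmetic above
    assert expected == pytest.approx(-0.6073732718894007, abs=1e-12)


def test_permutation_null_mean_is_minus_one_over_n_minus_one(rng):
    n = 40
    coords = rng.uniform(0, 10, size=(n, 2))
    resid = rng.normal(size=n)
    edges = [0.0, 3.0]
    vals = []
    for _ in range(1000):
        perm = rng.permutation(resid)
        vals.append(moran_correlogram(perm, coords, bin_edges=edges).loc[0, "moran_i"])
    vals = np.asarray(vals)
    expected = -1.0 / (n - 1)
    band = 3 * vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < band


def test_zero_variance_residuals_flagged_not_raised():
    coords = np.column_stack([np.arange(5.0), np.zeros(5)])
    out = moran_correlogram(np.ones(5), coords, bin_edges=[0.5, 1.5])
    assert np.isnan(out.loc[0, "moran_i"])


def test_empty_bin_gives_nan_pair_count_zero():
    coords = np.column_stack([np.arange(4.0), np.zeros(4)])
    out = moran_correlogram(np.array([1.0, -1, 2, -2]), coords,
                            bin_edges=[10.0, 20.0])
    assert out.loc[0, "n_pairs"] == 0 and np.isnan(out.loc[0, "moran_i"])


def test_deviance_residual_signs_follow_misfit():
    resid = deviance_residuals([1, 0], [0.9, 0.1])
    assert resid[0] > 0 and resid[1] < 0
    big = deviance_residuals([1], [0.01])
    small = deviance_residuals([1], [0.99])
    assert abs(big[0]) > abs(small[0])
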