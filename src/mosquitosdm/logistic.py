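"""Balanced-bootstrap logistic regression with z-based variable ranks and a
Moran's I spatial-autocorrelation check.

Each submodel is a maximum-likelihood logistic fit (IRLS on z-scored
features, tolerance 1e-8 on the log-likelihood, at most 100 iterations).
Balanced bootstrap samples at p close to n invite quasi-complete separation;
on detection (diverging coefficients or a singular weighted normal matrix)
the fit falls back to a lightly ridged IRLS (lambda = 1e-4 on the
standardized coefficients, intercept unpenalized) and is flagged. Standard
errors come from the inverse (penalized) Fisher information; variables are
ranked within each fit by descending |z| and the ranks averaged across
converged fits.

An optional correlation screen (drop the later member of any feature pair
with |r| > 0.95, keep-first) tames the near-collinear seasonality stack
before fitting; it is logged and switchable, since unregularized logistic
regression is ill-posed as p approaches n.

The correlogram utility computes Moran's I of model residuals per distance
bin, the standard check that spatial autocorrelation is weak enough to
ignore (its permutation-null expectation is -1/(n-1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from .ensemble import aggregate_importance
from .errors import FitError, InputError

logger = logging.getLogger(__name__)

MAX_ITER = 100
LOGLIK_TOL = 1e-8
RIDGE_LAMBDA = 1e-4
#: |standardized coefficient| beyond which the fit is treated as separated.
SEPARATION_COEF = 30.0


@dataclass
class LogisticFit:
    """One fitted logistic submodel on standardized features."""

    intercept: float
    coef: np.ndarray
    se: np.ndarray  # intercept first, then coefficients
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    converged: bool
    iterations: int
    regularized: bool
    loglik: float

    @property
    def z_values(self) -> pd.Series:
        return pd.Series(self.coef / self.se[1:], index=self.feature_names)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Z = (X - self.scaler_mean) / self.scaler_sd
        return expit(self.intercept + Z @ self.coef)


def _irls(Xd: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    """IRLS for logistic regression on a design matrix with intercept column.

    Returns (beta, cov, converged, iterations, loglik). ``lam`` penalizes all
    columns except the first (intercept).
    """
    n, p1 = Xd.shape
    beta = np.zeros(p1)
    pen = lam * np.eye(p1)
    pen[0, 0] = 0.0
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = Xd @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        grad = Xd.T @ (y - mu) - pen @ beta
        info = (Xd * w[:, None]).T @ Xd + pen
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
        ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu)) - 0.5 * float(
            beta @ pen @ beta
        )
        if lam == 0.0 and np.max(np.abs(beta[1:]), initial=0.0) > SEPARATION_COEF:
            raise FitError("separation detected: diverging coefficients")
        if abs(ll - ll_old) < LOGLIK_TOL:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = Xd @ beta
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    w = mu * (1 - mu)
    info = (Xd * w[:, None]).T @ Xd + pen
    cov = np.linalg.inv(info)
    loglik = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
    return beta, cov, converged, it, loglik


def fit_logistic(X, y, feature_names=None, allow_ridge_fallback: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic fit with seeded ridge fallback on separation."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise FitError("both classes are required")
    if n <= p:
        raise InputError(
            f"n={n} <= p={p}: screen or subset features before fitting"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    Xd = np.column_stack([np.ones(n), Z])
    regularized = False
    try:
        beta, cov, converged, it, ll = _irls(Xd, y, lam=0.0)
        if not converged:
            raise FitError("no convergence within iteration budget")
    except FitError:
        if not allow_ridge_fallback:
            raise
        regularized = True
        beta, cov, converged, it, ll = _irls(Xd, y, lam=RIDGE_LAMBDA)
        if not converged and not np.all(np.isfinite(beta)):
            raise FitError("logistic fit failed even with ridge fallback")
        logger.debug("separation fallback: ridge lambda=%g", RIDGE_LAMBDA)
    diag = np.diag(cov).copy()
    degenerate = diag <= 0  # numerically singular information: flag, don't rank
    if degenerate.any():
        converged = False
        diag[degenerate] = np.nan
    se = np.sqrt(diag)
    return LogisticFit(
        intercept=float(beta[0]),
        coef=beta[1:],
        se=se,
        feature_names=list(feature_names),
        scaler_mean=mu,
        scaler_sd=sd,
        converged=converged,
        iterations=it,
        regularized=regularized,
        loglik=ll,
    )


def screen_features(
    table: pd.DataFrame, feature_names, threshold: float = 0.95
) -> list[str]:
    """Drop the later member of each feature pair with |correlation| > threshold.

    Keep-first over the canonical feature order; zero-variance features are
    dropped outright. Returns the retained names (logged).
    """
    names = list(feature_names)
    X = table[names].to_numpy(dtype=float)
    sd = X.std(axis=0)
    kept: list[int] = []
    for j in range(len(names)):
        if sd[j] == 0:
            continue
        ok = True
        for i in kept:
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    dropped = len(names) - len(kept)
    if dropped:
        logger.info("feature screen dropped %d of %d features", dropped, len(names))
    return [names[j] for j in kept]


def make_logistic_fitter(feature_names):
    """Submodel fitter for :func:`mosquitosdm.ensemble.fit_ensemble`."""
    names = list(feature_names)

    def fit_one(X, y, seed):  # seed unused: the fit is deterministic
        return fit_logistic(X, y, feature_names=names)

    return fit_one


def rank_variables_logistic(fits) -> pd.DataFrame:
    """Average within-fit |z| ranks across converged fits (1 = most important)."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise InputError("no converged fits to rank")
    if len(converged) < len(fits):
        logger.info(
            "ranking over %d converged of %d fits", len(converged), len(fits)
        )
    ranks = [
        f.z_values.abs().rank(ascending=False, method="average") for f in converged
    ]
    return aggregate_importance(ranks, mode="rank")


def deviance_residuals(y, p) -> np.ndarray:
    """Signed square-root deviance contributions of binary outcomes."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-10, 1 - 1e-10)
    dev = -2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p))
    return np.sign(y - p) * np.sqrt(np.maximum(dev, 0.0))


def moran_i(values, coords, weights) -> float:
    """Moran's I for one weight matrix (zero diagonal)."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    s0 = float(weights.sum())
    if denom == 0.0 or s0 == 0.0:
        return np.nan
    return float(len(z) / s0 * (z @ weights @ z) / denom)


def moran_correlogram(
    residuals,
    coords,
    bin_edges=None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Moran's I of residuals per distance bin.

    Bin b uses binary weights w_ij = 1 iff distance(i, j) falls in
    [low_b, high_b) (the last bin is closed). Default bins: ``n_bins``
    equal-width bins up to half the maximum pairwise distance — beyond that,
    few pairs remain and the statistic becomes erratic. Bins without pairs,
    or residuals with zero variance, yield NaN rather than an error.

    Returns a frame with columns ``bin_low, bin_high, n_pairs, moran_i``.
    """
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(z) != len(coords):
        raise InputError("residuals and coordinates differ in length")
    if len(z) < 2:
        raise InputError("need at least two points")
    dist = squareform(pdist(coords))
    if bin_edges is None:
        dmax = dist.max() / 2.0
        bin_edges = np.linspace(0.0, dmax, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    rows = []
    zero_var = np.allclose(z, z.mean())
    if zero_var:
        logger.warning("zero residual variance: Moran's I undefined in every bin")
    for low, high in zip(bin_edges[:-1], bin_edges[1:]):
        last = high == bin_edges[-1]
        w = (dist >= low) & ((dist <= high) if last else (dist < high))
        np.fill_diagonal(w, False)
        n_pairs = int(w.sum())
        value = np.nan
        if n_pairs > 0 and not zero_var:
            value = moran_i(z, coords, w.astype(float))
        rows.append((low, high, n_pairs, value))
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n_pairs", "moran_i"])
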