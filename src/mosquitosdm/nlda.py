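"""Non-linear discriminant analysis via k-means sub-clustering.

Presence and absence records are each partitioned into k clusters by k-means
on standardized "generic" seasonality variables (elevation plus the means,
amplitudes, extrema, variance and phases of the thermal and vegetation
signals). Each cluster becomes one Gaussian discriminant class — mean,
regularized covariance, prior proportional to cluster size — and suitability
is the posterior probability that a point belongs to any presence cluster:

    s(x) = sum_{c in presence} pi_c N(x; mu_c, S_c)
           / sum_{all clusters} pi_c N(x; mu_c, S_c)

computed with log-density stabilization (logsumexp), so s(x) in [0,1] and
the two super-class posteriors always sum to one. Sub-clustering lets a
single "species niche" be multimodal — the non-linearity in the name.

With k=1 per class the model reduces exactly to two-class quadratic
Gaussian discriminant analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import ConfigurationError, FitError
from .fourier import COMPONENTS

logger = logging.getLogger(__name__)

#: Components of the generic-variable set: means, amplitudes, extrema,
#: total variance and phases — not the variance proportions.
GENERIC_COMPONENTS: tuple[str, ...] = (
    "A0", "A1", "A2", "A3", "MN", "MX", "VR", "P1", "P2", "P3",
)
#: Thermal and vegetation signals used for clustering; "LST" covers both the
#: day and night products.
GENERIC_VARIABLES: tuple[str, ...] = ("MIR", "DLST", "NLST", "NDVI")

assert set(GENERIC_COMPONENTS) <= set(COMPONENTS)


def select_generic_variables(feature_names) -> list[str]:
    """The clustering feature subset: DEM + 10 components x 4 signals = 41.

    Raises if any expected name is missing from the supplied feature set.
    """
    available = set(feature_names)
    wanted = ["DEM"] + [
        f"{var} {comp}" for var in GENERIC_VARIABLES for comp in GENERIC_COMPONENTS
    ]
    missing = [name for name in wanted if name not in available]
    if missing:
        raise ConfigurationError(f"generic variables missing from stack: {missing}")
    return wanted


@dataclass
class GaussianCluster:
    """One discriminant class: a Gaussian fitted to one k-means cluster."""

    label: int  # 1 = presence, 0 = absence
    mean: np.ndarray
    cov: np.ndarray
    prior: float
    _chol: tuple = field(default=None, repr=False)  # type: ignore[assignment]
    _logdet: float = field(default=0.0, repr=False)

    def prepare(self):
        self._chol = cho_factor(self.cov, lower=True)
        self._logdet = 2.0 * np.sum(np.log(np.diag(self._chol[0])))

    def log_density(self, X: np.ndarray) -> np.ndarray:
        d = X - self.mean
        maha = np.einsum("ij,ij->i", d, cho_solve(self._chol, d.T).T)
        p = len(self.mean)
        return -0.5 * (p * np.log(2 * np.pi) + self._logdet + maha)


@dataclass
class NldaModel:
    """Fitted cluster-discriminant model on standardized features."""

    clusters: list[GaussianCluster]
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    k_presence: int
    k_absence: int

    def cluster_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [c.label for c in self.clusters],
                "prior": [c.prior for c in self.clusters],
            }
        )

    def predict(self, X) -> np.ndarray:
        """Posterior probability of the presence super-class, in [0,1]."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Z = (X - self.scaler_mean) / self.scaler_sd
        logs = np.column_stack(
            [np.log(c.prior) + c.log_density(Z) for c in self.clusters]
        )
        if not np.all(np.isfinite(logs.max(axis=1))):
            bad = int(np.argmax(~np.isfinite(logs.max(axis=1))))
            raise FitError(f"non-finite discriminant density at point {bad}")
        total = logsumexp(logs, axis=1)
        pres = [i for i, c in enumerate(self.clusters) if c.label == 1]
        num = logsumexp(logs[:, pres], axis=1)
        return np.exp(num - total)


def _regularized_cov(Z: np.ndarray, reg: float, fallback_scale: float) -> np.ndarray:
    """Population covariance + lambda*I, lambda = reg * trace/dim (or fallback)."""
    p = Z.shape[1]
    if Z.shape[0] > 1:
        cov = np.cov(Z, rowvar=False, bias=True)
        cov = np.atleast_2d(cov)
    else:
        cov = np.zeros((p, p))
    tr = np.trace(cov)
    lam = reg * (tr / p if tr > 0 else fallback_scale)
    lam = max(lam, 1e-12)
    return cov + lam * np.eye(p)


def fit_nlda(
    X,
    y,
    k_presence: int = 4,
    k_absence: int = 4,
    seed: int = 0,
    reg: float = 1e-6,
    feature_names=None,
    n_init: int = 10,
) -> NldaModel:
    """Fit the cluster-discriminant model on a (balanced) training sample.

    k-means (seeded, ``n_init`` restarts, Euclidean on z-scored features)
    runs separately within each class; k is reduced to the class size when a
    class has fewer points than clusters, and covariance regularization is
    escalated (lambda x10, up to 6 times) if a cluster covariance is not
    positive-definite.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if k_presence < 1 or k_absence < 1:
        raise ConfigurationError("cluster counts must be >= 1")
    if len(np.unique(y)) < 2:
        raise FitError("training sample must contain both classes")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    n = len(y)

    clusters: list[GaussianCluster] = []
    for label, k in ((1, k_presence), (0, k_absence)):
        Zc = Z[y == label]
        k_eff = min(k, len(Zc))
        if k_eff < k:
            logger.warning(
                "class %d has %d points; reducing k from %d to %d",
                label, len(Zc), k, k_eff,
            )
        if k_eff > 1:
            km = KMeans(n_clusters=k_eff, n_init=n_init, random_state=seed % (2**31))
            assign = km.fit_predict(Zc)
        else:
            assign = np.zeros(len(Zc), dtype=int)
        for c in range(k_eff):
            members = Zc[assign == c]
            if len(members) == 0:  # defensive: sklearn k-means avoids this
                continue
            cov = _regularized_cov(members, reg, fallback_scale=1.0)
            cluster = GaussianCluster(
                label=label,
                mean=members.mean(axis=0),
                cov=cov,
                prior=len(members) / n,
            )
            lam_boost = reg
            for _ in range(6):
                try:
                    cluster.prepare()
                    break
                except (LinAlgError, np.linalg.LinAlgError):
                    lam_boost *= 10.0
                    cluster.cov = cluster.cov + lam_boost * np.eye(Z.shape[1])
            else:
                raise FitError(
                    f"singular covariance for cluster (label={label}, idx={c}) "
                    "despite escalating regularization"
                )
            clusters.append(cluster)
    total_prior = sum(c.prior for c in clusters)
    for c in clusters:
        c.prior /= total_prior
    return NldaModel(
        clusters=clusters,
        feature_names=list(feature_names),
        scaler_mean=mu,
        scaler_sd=sd,
        k_presence=k_presence,
        k_absence=k_absence,
    )


def fisher_ratio_ranks(X, y, feature_names) -> pd.Series:
    """Within-submodel variable ranks from the Fisher separation ratio.

    For each variable, the ratio of squared class-mean difference to pooled
    within-class variance on the training sample; rank 1 = most separating.
    Used as the discriminant model's per-bootstrap importance ranking.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    Xp, Xa = X[y == 1], X[y == 0]
    num = (Xp.mean(axis=0) - Xa.mean(axis=0)) ** 2
    den = (
        len(Xp) * Xp.var(axis=0) + len(Xa) * Xa.var(axis=0)
    ) / max(len(y), 1)
    ratio = pd.Series(num / np.where(den > 0, den, np.inf), index=list(feature_names))
    return ratio.rank(ascending=False, method="average")


def make_nlda_fitter(
    feature_names,
    k_presence: int = 4,
    k_absence: int = 4,
    reg: float = 1e-6,
    n_init: int = 10,
):
    """Submodel fitter for :func:`mosquitosdm.ensemble.fit_ensemble`.

    The returned submodels carry ``importance_ranks`` (Fisher-ratio ranks on
    their own balanced sample) for Table-style rank aggregation.
    """
    names = list(feature_names)

    def fit_one(X, y, seed):
        model = fit_nlda(
            X, y, k_presence=k_presence, k_absence=k_absence,
            seed=seed, reg=reg, feature_names=names, n_init=n_init,
        )
        model.importance_ranks = fisher_ratio_ranks(X, y, names)
        return model

    return fit_one
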