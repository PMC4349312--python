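"""Synthetic study region, covariate stack, true suitability and trap survey.

This module generates landscapes with the statistical structure a national
mosquito trap survey assumes: a patchy categorical land-cover map (urban,
sampled and excluded agricultural land, natural areas, water), static
environmental layers (elevation, two precipitation products, human population
density), seasonal remote-sensing layers (MIR, day/night land surface
temperature, EVI, NDVI) built from annual and bi-annual harmonics plus white
noise, a known logistic suitability surface over derived seasonality
features, and a stratified one-visit trap survey (40% urban, 40% sampled
agricultural, 20% natural by default) whose presence/absence outcomes are
Bernoulli draws from the true suitability.

High-productivity arable land ("agricultural_excluded") and water are never
sampled; the excluded class is given a distinctive covariate signature
(strong crop seasonality in the vegetation indices) so that its unsuitability
is only learnable through pseudo-absences, mirroring the survey design the
models must cope with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ConfigurationError, GenerationError

logger = logging.getLogger(__name__)

# Land-cover classes, in the canonical code order used by every grid.
CLASSES: tuple[str, ...] = (
    "urban",
    "agricultural_sampled",
    "agricultural_excluded",
    "natural",
    "water",
)
CLASS_CODE = {name: i for i, name in enumerate(CLASSES)}

#: Strata that receive traps, in the order ties are broken when rounding.
SAMPLED_STRATA: tuple[str, ...] = ("urban", "agricultural_sampled", "natural")

#: Trap allocation across strata: 40% urban, 40% agricultural, 20% natural.
DEFAULT_STRATA_PROPS: dict[str, float] = {
    "urban": 0.4,
    "agricultural_sampled": 0.4,
    "natural": 0.2,
}

DEFAULT_CLASS_PROPS: dict[str, float] = {
    "urban": 0.15,
    "agricultural_sampled": 0.30,
    "agricultural_excluded": 0.20,
    "natural": 0.30,
    "water": 0.05,
}

SEASONAL_VARIABLES: tuple[str, ...] = ("MIR", "DLST", "NLST", "EVI", "NDVI")

#: Display names of the static layers, as they appear in feature tables.
STATIC_NAMES: dict[str, str] = {
    "dem": "DEM",
    "precipitation_a": "WORLDCLIM precipitation",
    "precipitation_b": "CMORPH precipitation",
    "population_density": "Population density",
}


@dataclass
class Landscape:
    """Categorical land-cover grid with georeferencing and a validity mask.

    ``landcover`` holds integer codes into :data:`CLASSES`; ``valid`` is True
    where the cell carries data. Row 0 is the northern edge (see
    :mod:`mosquitosdm.rasters` for the point-to-cell rule).
    """

    landcover: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.landcover = np.asarray(self.landcover, dtype=int)
        if self.valid is None:
            self.valid = np.ones(self.landcover.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.landcover.shape:
            raise ConfigurationError("valid mask shape does not match landcover")

    @property
    def height(self) -> int:
        return self.landcover.shape[0]

    @property
    def width(self) -> int:
        return self.landcover.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.landcover.shape

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean grid of cells in land-cover class *name* (valid only)."""
        return (self.landcover == CLASS_CODE[name]) & self.valid

    def class_fractions(self) -> dict[str, float]:
        n = int(self.valid.sum())
        return {c: float(self.class_mask(c).sum()) / n for c in CLASSES}

    def sampleable_mask(self) -> np.ndarray:
        """Cells eligible for traps: valid and in a sampled stratum."""
        out = np.zeros(self.shape, dtype=bool)
        for name in SAMPLED_STRATA:
            out |= self.class_mask(name)
        return out

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (self.height - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); half-open cells."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = self.height - 1 - np.floor(
            (np.asarray(y) - self.origin[1]) / self.cell_size
        ).astype(int)
        return row, col

    def in_bounds(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        row, col = np.asarray(row), np.asarray(col)
        return (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)


@dataclass
class SeasonalParams:
    """Harmonic parameters of one seasonal variable, per land-cover class.

    The monthly series at a pixel is
    ``mean + amp1*cos(2*pi*(t - peak1)/12) + amp2*cos(2*pi*2*(t - peak2)/12)``
    plus N(0, noise_sd) white noise, where *t* is the month index. Class
    means/amplitudes are perturbed by independent smooth spatial fields with
    standard deviations ``mean_field_sd`` / ``amp_field_sd`` so that
    within-class variation exists and components stay identifiable; the
    annual peak month is likewise perturbed by a smooth field with standard
    deviation ``phase_field_sd`` (months), emulating spatial variation in
    green-up/thermal timing.
    """

    mean: dict[str, float]
    amp1: dict[str, float]
    amp2: dict[str, float]
    peak1: float
    peak2: float
    noise_sd: float
    mean_field_sd: float
    amp_field_sd: float
    phase_field_sd: float = 0.0


# Loosely temperate-European magnitudes: LST in deg C, vegetation indices and
# MIR dimensionless. Excluded arable land gets the strongest vegetation-index
# seasonality (crop green-up/harvest) — its distinguishing signature.
DEFAULT_SEASONAL: dict[str, SeasonalParams] = {
    "MIR": SeasonalParams(
        mean={"urban": 0.14, "agricultural_sampled": 0.10, "agricultural_excluded": 0.12,
              "natural": 0.08, "water": 0.03},
        amp1={"urban": 0.02, "agricultural_sampled": 0.03, "agricultural_excluded": 0.05,
              "natural": 0.025, "water": 0.005},
        amp2={"urban": 0.005, "agricultural_sampled": 0.008, "agricultural_excluded": 0.015,
              "natural": 0.006, "water": 0.002},
        peak1=7.0, peak2=3.0, noise_sd=0.008, mean_field_sd=0.015, amp_field_sd=0.008,
        phase_field_sd=0.6,
    ),
    "DLST": SeasonalParams(
        mean={"urban": 13.0, "agricultural_sampled": 11.0, "agricultural_excluded": 11.5,
              "natural": 10.0, "water": 9.0},
        amp1={"urban": 9.0, "agricultural_sampled": 10.0, "agricultural_excluded": 10.5,
              "natural": 8.5, "water": 6.0},
        amp2={"urban": 1.0, "agricultural_sampled": 1.2, "agricultural_excluded": 1.4,
              "natural": 0.9, "water": 0.5},
        peak1=7.2, peak2=2.0, noise_sd=0.8, mean_field_sd=1.2, amp_field_sd=0.8,
        phase_field_sd=0.5,
    ),
    "NLST": SeasonalParams(
        mean={"urban": 7.5, "agricultural_sampled": 5.5, "agricultural_excluded": 5.8,
              "natural": 5.0, "water": 6.0},
        amp1={"urban": 6.5, "agricultural_sampled": 7.0, "agricultural_excluded": 7.2,
              "natural": 6.8, "water": 5.0},
        amp2={"urban": 0.8, "agricultural_sampled": 0.9, "agricultural_excluded": 1.0,
              "natural": 0.8, "water": 0.4},
        peak1=7.5, peak2=1.5, noise_sd=0.7, mean_field_sd=1.0, amp_field_sd=0.6,
        phase_field_sd=0.3,
    ),
    "EVI": SeasonalParams(
        mean={"urban": 0.25, "agricultural_sampled": 0.40, "agricultural_excluded": 0.38,
              "natural": 0.45, "water": 0.05},
        amp1={"urban": 0.08, "agricultural_sampled": 0.15, "agricultural_excluded": 0.28,
              "natural": 0.18, "water": 0.01},
        amp2={"urban": 0.02, "agricultural_sampled": 0.04, "agricultural_excluded": 0.09,
              "natural": 0.03, "water": 0.005},
        peak1=6.5, peak2=4.0, noise_sd=0.02, mean_field_sd=0.04, amp_field_sd=0.03,
        phase_field_sd=0.8,
    ),
    "NDVI": SeasonalParams(
        mean={"urban": 0.35, "agricultural_sampled": 0.55, "agricultural_excluded": 0.50,
              "natural": 0.62, "water": 0.05},
        amp1={"urban": 0.10, "agricultural_sampled": 0.20, "agricultural_excluded": 0.35,
              "natural": 0.30, "water": 0.01},
        amp2={"urban": 0.02, "agricultural_sampled": 0.05, "agricultural_excluded": 0.10,
              "natural": 0.04, "water": 0.005},
        peak1=6.8, peak2=4.5, noise_sd=0.025, mean_field_sd=0.05, amp_field_sd=0.035,
        phase_field_sd=0.8,
    ),
}


@dataclass
class CovariateStack:
    """Static layers plus per-pixel monthly series for each seasonal variable.

    ``static`` maps layer key (``dem``, ``precipitation_a``,
    ``precipitation_b``, ``population_density``) to a (H, W) grid; ``seasonal``
    maps variable name to a (12*years, H, W) array.
    """

    static: dict[str, np.ndarray]
    seasonal: dict[str, np.ndarray]
    years: int

    def n_months(self) -> int:
        return 12 * self.years


@dataclass
class TruthModel:
    """The (synthetic, known) species response used to simulate surveys.

    Suitability at a pixel is ``sigmoid(intercept + sum_j beta_j * z_j)``
    where ``z_j`` are the named derived features z-scored over valid cells.
    Standardizing makes the intercept an interpretable prevalence dial:
    ``sigmoid(intercept)`` is roughly the landscape-average suitability.

    ``force_excluded_zero`` clamps suitability to exactly 0 on
    agricultural_excluded cells, the scenario where unsampled arable land is
    truly unsuitable and pseudo-absences carry real information.
    """

    coefficients: dict[str, float]
    intercept: float = 0.0
    force_excluded_zero: bool = False

    def suitability_map(self, features: dict[str, np.ndarray], landscape: Landscape) -> np.ndarray:
        missing = [f for f in self.coefficients if f not in features]
        if missing:
            raise ConfigurationError(f"truth model uses unknown features: {missing}")
        valid = landscape.valid
        eta = np.full(landscape.shape, self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            grid = features[name]
            vals = grid[valid]
            mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals))
            if sd == 0:
                sd = 1.0
            eta += beta * (grid - mu) / sd
        suit = expit(eta)
        if self.force_excluded_zero:
            suit[landscape.class_mask("agricultural_excluded")] = 0.0
        suit[~valid] = np.nan
        return suit


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def generate_landscape(
    width: int,
    height: int,
    class_proportions: dict[str, float] | None = None,
    seed: int = 0,
    smooth_sigma: float | None = None,
) -> Landscape:
    """Generate a patchy land-cover map by quantile-thresholding smoothed noise.

    Class patches are contiguous because the underlying field is spatially
    autocorrelated; thresholds at the cumulative class-proportion quantiles
    make realised class counts match the targets up to ties.
    """
    props = dict(class_proportions or DEFAULT_CLASS_PROPS)
    unknown = set(props) - set(CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown land-cover classes: {sorted(unknown)}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-6:
        raise ConfigurationError(f"class proportions sum to {total}, expected 1")
    if width * height < 100:
        raise ConfigurationError("landscape must have at least 100 cells")

    rng = np.random.default_rng(seed)
    if smooth_sigma is None:
        smooth_sigma = max(1.5, min(width, height) / 12.0)
    fld = _smooth_field(rng, (height, width), smooth_sigma)
    # tiny jitter breaks ties between equal smoothed values deterministically
    fld = fld + rng.normal(scale=1e-9, size=fld.shape)

    order = [c for c in CLASSES if props.get(c, 0.0) > 0]
    cum = np.cumsum([props[c] for c in order])
    thresholds = np.quantile(fld, cum[:-1]) if len(order) > 1 else np.array([])
    codes = np.digitize(fld, thresholds)
    landcover = np.empty((height, width), dtype=int)
    for i, c in enumerate(order):
        landcover[codes == i] = CLASS_CODE[c]
    return Landscape(landcover=landcover)


def generate_covariates(
    landscape: Landscape,
    years: int = 2,
    seed: int = 0,
    seasonal_params: dict[str, SeasonalParams] | None = None,
    noise_scale: float = 1.0,
) -> CovariateStack:
    """Simulate the static and seasonal covariate layers on a landscape.

    Each seasonal variable is a per-class harmonic (annual + bi-annual)
    perturbed by smooth spatial fields and monthly white noise; ``noise_scale``
    rescales every stochastic component (0 gives an exactly harmonic stack).
    Static layers: DEM is a smooth west-east gradient plus correlated noise,
    the two precipitation products are independent smooth fields, and
    population density is a skewed positive field that is high in urban
    cells and exactly zero over water.
    """
    if years < 1:
        raise ConfigurationError("years must be >= 1")
    params = seasonal_params or DEFAULT_SEASONAL
    rng = np.random.default_rng(seed)
    h, w = landscape.shape
    sigma = max(1.5, min(h, w) / 16.0)
    code = landscape.landcover
    xnorm = np.linspace(0.0, 1.0, w)[None, :] * np.ones((h, 1))
    ynorm = np.linspace(0.0, 1.0, h)[:, None] * np.ones((1, w))

    static: dict[str, np.ndarray] = {}
    static["dem"] = (
        15.0 + 55.0 * xnorm + 10.0 * noise_scale * _smooth_field(rng, (h, w), sigma)
    )
    static["precipitation_a"] = (
        800.0 - 120.0 * xnorm + 40.0 * ynorm
        + 60.0 * noise_scale * _smooth_field(rng, (h, w), sigma)
    )
    static["precipitation_b"] = (
        760.0 - 90.0 * xnorm + 30.0 * ynorm
        + 55.0 * noise_scale * _smooth_field(rng, (h, w), sigma)
    )
    pop_base = np.select(
        [code == CLASS_CODE[c] for c in CLASSES],
        [1500.0, 60.0, 40.0, 15.0, 0.0],
    )
    pop = pop_base * np.exp(0.8 * noise_scale * _smooth_field(rng, (h, w), sigma / 2))
    pop[landscape.class_mask("water")] = 0.0
    static["population_density"] = np.maximum(pop, 0.0)

    n_months = 12 * years
    t = np.arange(n_months, dtype=float)
    seasonal: dict[str, np.ndarray] = {}
    for var in SEASONAL_VARIABLES:
        p = params[var]
        mean_map = np.select(
            [code == CLASS_CODE[c] for c in CLASSES], [p.mean[c] for c in CLASSES]
        ) + p.mean_field_sd * noise_scale * _smooth_field(rng, (h, w), sigma)
        amp1_map = np.maximum(
            np.select(
                [code == CLASS_CODE[c] for c in CLASSES], [p.amp1[c] for c in CLASSES]
            ) + p.amp_field_sd * noise_scale * _smooth_field(rng, (h, w), sigma),
            0.0,
        )
        amp2_map = np.maximum(
            np.select(
                [code == CLASS_CODE[c] for c in CLASSES], [p.amp2[c] for c in CLASSES]
            ) + 0.3 * p.amp_field_sd * noise_scale * _smooth_field(rng, (h, w), sigma),
            0.0,
        )
        peak1_map = p.peak1 + p.phase_field_sd * noise_scale * _smooth_field(
            rng, (h, w), sigma
        )
        phase1 = np.cos(2 * np.pi * (t[:, None, None] - peak1_map[None]) / 12.0)
        phase2 = np.cos(2 * np.pi * 2 * (t[:, None, None] - p.peak2) / 12.0)
        series = (
            mean_map[None] + amp1_map[None] * phase1 + amp2_map[None] * phase2
        )
        if noise_scale > 0:
            series = series + rng.normal(
                scale=p.noise_sd * noise_scale, size=series.shape
            )
        seasonal[var] = series
    return CovariateStack(static=static, seasonal=seasonal, years=years)


def allocate_strata(n_traps: int, strata_props: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of traps across strata.

    Floors of ``n * p`` are topped up in order of descending fractional
    remainder; ties break in :data:`SAMPLED_STRATA` order, so the totals are
    exact and reproducible (e.g. 766 traps at 0.4/0.4/0.2 gives 307/306/153).
    """
    strata = [s for s in SAMPLED_STRATA if s in strata_props]
    total = sum(strata_props[s] for s in strata)
    if abs(total - 1.0) > 1e-6:
        raise ConfigurationError(f"strata proportions sum to {total}, expected 1")
    quotas = {s: n_traps * strata_props[s] for s in strata}
    counts = {s: int(np.floor(quotas[s])) for s in strata}
    short = n_traps - sum(counts.values())
    by_remainder = sorted(
        strata, key=lambda s: (-(quotas[s] - counts[s]), SAMPLED_STRATA.index(s))
    )
    for s in by_remainder[:short]:
        counts[s] += 1
    return counts


def simulate_survey(
    landscape: Landscape,
    covariates: CovariateStack,
    truth: TruthModel,
    n_traps: int = 766,
    strata_props: dict[str, float] | None = None,
    seed: int = 0,
    n_weeks: int = 30,
    features: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate a stratified one-visit trap survey.

    Traps are placed uniformly at random without replacement within each
    stratum (each location sampled once); catch presence is Bernoulli with
    the true suitability at the trap's cell, and positive traps receive a
    1 + Poisson(2) count (the count itself is cosmetic: only presence/absence
    is used downstream). Returns a table with columns
    ``trap_id, x, y, stratum, week, abundance``.

    ``features`` may carry a precomputed derived-feature stack to avoid
    re-running the seasonality decomposition.
    """
    from .fourier import fourier_stack  # deferred: avoids import cycle

    props = dict(strata_props or DEFAULT_STRATA_PROPS)
    counts = allocate_strata(n_traps, props)
    if features is None:
        features = fourier_stack(covariates, landscape)
    suit = truth.suitability_map(features, landscape)

    rng = np.random.default_rng(seed)
    records = []
    trap_id = 0
    for stratum in SAMPLED_STRATA:
        need = counts.get(stratum, 0)
        if need == 0:
            continue
        rows, cols = np.nonzero(landscape.class_mask(stratum))
        if len(rows) == 0:
            raise GenerationError(f"stratum '{stratum}' has no eligible cells")
        if need > len(rows):
            raise GenerationError(
                f"stratum '{stratum}' has {len(rows)} eligible cells, "
                f"cannot place {need} traps without revisits"
            )
        pick = rng.choice(len(rows), size=need, replace=False)
        r, c = rows[pick], cols[pick]
        x, y = landscape.cell_center(r, c)
        p = suit[r, c]
        present = rng.random(need) < p
        abundance = np.where(present, 1 + rng.poisson(2.0, size=need), 0)
        week = rng.integers(1, n_weeks + 1, size=need)
        for i in range(need):
            records.append(
                (trap_id + i, x[i], y[i], stratum, int(week[i]), int(abundance[i]))
            )
        trap_id += need
    df = pd.DataFrame.from_records(
        records, columns=["trap_id", "x", "y", "stratum", "week", "abundance"]
    )
    logger.info(
        "simulated survey: %d traps, %.1f%% positive",
        len(df), 100.0 * (df["abundance"] > 0).mean(),
    )
    return df
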