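"""Temporal Fourier analysis of monthly environmental time series.

Each per-pixel monthly series (a whole number of years) is summarised by 14
seasonality components:

========  ====================================================
A0        mean of the series
MN, MX    minimum / maximum of the raw series
A1-A3     amplitudes of the annual, bi-annual, tri-annual cycles
VR        total (population) variance of the series
P1-P3     phases: month of the cycle's peak, in [0, 12)
D1-D3     proportion of total variance due to each cycle
DA        proportion due to all three cycles (= D1 + D2 + D3)
========  ====================================================

Harmonics are estimated by least squares of cosine/sine terms at k = 1, 2, 3
cycles per year, which for regularly sampled whole-year series coincides
with the discrete Fourier transform: with n = 12*Y samples,
``a_k = (2/n) * sum x_t cos(w_k t)``, ``b_k = (2/n) * sum x_t sin(w_k t)``,
``w_k = 2*pi*k/12``; then ``A_k = sqrt(a_k^2 + b_k^2)`` and the fitted cycle
is ``A_k cos(w_k (t - t0))`` peaking at ``t0 = atan2(b_k, a_k)/w_k``, reported
modulo 12 months. Each cycle contributes ``A_k^2 / 2`` to the series variance
(Parseval), so ``D_k = (A_k^2/2)/VR``; a zero-variance series has all D and
DA defined as 0.

Phase convention: months since the start of the series' calendar (t = 0 is
the first month), not radians — chosen for ecological readability (P1 ~ 6.5
means the annual cycle peaks in mid-summer for a January-start series).
Radians convert as ``phi = 2*pi*k*P/12``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .landscape import (
    STATIC_NAMES,
    CovariateStack,
    Landscape,
)

#: Component names in canonical table order.
COMPONENTS: tuple[str, ...] = (
    "A0", "MN", "MX", "A1", "A2", "A3", "VR",
    "P1", "P2", "P3", "D1", "D2", "D3", "DA",
)

N_HARMONICS = 3


@dataclass(frozen=True)
class FourierComponents:
    """The 14 seasonality summaries of one monthly series."""

    A0: float
    MN: float
    MX: float
    A1: float
    A2: float
    A3: float
    VR: float
    P1: float
    P2: float
    P3: float
    D1: float
    D2: float
    D3: float
    DA: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPONENTS}


def _component_arrays(series: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised component computation; series has time on axis 0."""
    n = series.shape[0]
    t = np.arange(n, dtype=float)
    x = series.astype(float)
    out: dict[str, np.ndarray] = {}
    out["A0"] = x.mean(axis=0)
    out["MN"] = x.min(axis=0)
    out["MX"] = x.max(axis=0)
    vr = x.var(axis=0)  # population denominator N
    out["VR"] = vr
    safe_vr = np.where(vr > 0, vr, 1.0)
    da = np.zeros_like(vr)
    # project the centred series: identical in exact arithmetic (the harmonic
    # basis is orthogonal to the constant over whole years) but keeps a
    # constant series at exactly zero amplitude in floating point
    xc = x - out["A0"]
    for k in range(1, N_HARMONICS + 1):
        w = 2.0 * np.pi * k / 12.0
        cos_t = np.cos(w * t)
        sin_t = np.sin(w * t)
        a = (2.0 / n) * np.tensordot(cos_t, xc, axes=(0, 0))
        b = (2.0 / n) * np.tensordot(sin_t, xc, axes=(0, 0))
        amp = np.hypot(a, b)
        phase = np.mod(np.arctan2(b, a) / w, 12.0)
        phase = np.where(phase >= 12.0, phase - 12.0, phase)  # mod can round up
        d = np.where(vr > 0, (amp**2 / 2.0) / safe_vr, 0.0)
        out[f"A{k}"] = amp
        out[f"P{k}"] = phase
        out[f"D{k}"] = d
        da = da + d
    out["DA"] = da
    return out


def fourier_components(series) -> FourierComponents:
    """Decompose one monthly series into its 14 seasonality components.

    The series must cover a whole number of years (length divisible by 12)
    and contain only finite values; nodata handling belongs upstream.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InputError(f"expected 1-D series, got shape {x.shape}")
    if x.size == 0 or x.size % 12 != 0:
        raise InputError(
            f"series length {x.size} is not a positive multiple of 12 months"
        )
    if not np.all(np.isfinite(x)):
        raise InputError("series contains non-finite values")
    arrays = _component_arrays(x[:, None])
    return FourierComponents(**{k: float(v[0]) for k, v in arrays.items()})


def feature_names(
    seasonal_variables=("MIR", "DLST", "NLST", "EVI", "NDVI"),
    include_static: bool = True,
) -> list[str]:
    """Canonical ordered feature names: '<VAR> <COMPONENT>' then statics."""
    names = [f"{var} {comp}" for var in seasonal_variables for comp in COMPONENTS]
    if include_static:
        names += [STATIC_NAMES[k] for k in STATIC_NAMES]
    return names


def fourier_stack(
    covariates: CovariateStack, landscape: Landscape
) -> dict[str, np.ndarray]:
    """Derive one feature raster per (seasonal variable x component).

    Returns a dict mapping feature name ("NDVI A1", "DLST P2", ...) to a
    (H, W) grid; static layers pass through under their display names
    ("DEM", "WORLDCLIM precipitation", "CMORPH precipitation", "Population
    density"). Nodata cells propagate NaN into every derived component.
    """
    shape = landscape.shape
    for key, grid in covariates.static.items():
        if grid.shape != shape:
            raise InputError(f"static layer '{key}' shape {grid.shape} != {shape}")
    features: dict[str, np.ndarray] = {}
    invalid = ~landscape.valid
    for var, series in covariates.seasonal.items():
        if series.shape[1:] != shape:
            raise InputError(f"seasonal layer '{var}' shape {series.shape[1:]} != {shape}")
        if series.shape[0] % 12 != 0 or series.shape[0] == 0:
            raise InputError(
                f"seasonal layer '{var}' has {series.shape[0]} months, "
                "not a whole number of years"
            )
        arrays = _component_arrays(series)
        for comp in COMPONENTS:
            grid = arrays[comp].astype(float)
            grid[invalid] = np.nan
            features[f"{var} {comp}"] = grid
    for key, display in STATIC_NAMES.items():
        if key in covariates.static:
            grid = covariates.static[key].astype(float).copy()
            grid[invalid] = np.nan
            features[display] = grid
    return features
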