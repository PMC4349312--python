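"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from mosquitosdm import (
    TruthModel,
    add_pseudo_absences,
    dedup_cells,
    extract_features,
    fourier_stack,
    generate_covariates,
    generate_landscape,
    simulate_survey,
    survey_to_points,
)

MASTER_SEED = 20260921


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(30, 30, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def covariates(landscape):
    return generate_covariates(landscape, years=2, seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def features(covariates, landscape):
    return fourier_stack(covariates, landscape)


@pytest.fixture(scope="session")
def truth():
    return TruthModel(
        coefficients={"NDVI A1": 1.5, "DLST A0": 1.2, "Population density": -1.0},
        intercept=0.0,
    )


@pytest.fixture(scope="session")
def survey(landscape, covariates, truth, features):
    return simulate_survey(
        landscape, covariates, truth, n_traps=300,
        seed=MASTER_SEED + 2, features=features,
    )


@pytest.fixture(scope="session")
def occurrence_table(survey, landscape, features):
    points = survey_to_points(survey, landscape)
    points = dedup_cells(points, landscape)
    points = add_pseudo_absences(points, landscape, n=15, seed=MASTER_SEED + 3)
    return extract_features(points, features, landscape)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def tiny_table():
    """A 12-record occurrence table with two plain features."""
    gen = np.random.default_rng(11)
    n = 12
    return pd.DataFrame(
        {
            "point_id": np.arange(n),
            "x": gen.uniform(0, 10, n),
            "y": gen.uniform(0, 10, n),
            "row": 0,
            "col": np.arange(n),
            "presence": [1, 0] * (n // 2),
            "origin": "observed",
            "f1": gen.normal(size=n),
            "f2": gen.normal(size=n),
        }
    )
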