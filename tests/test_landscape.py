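"""Synthetic landscape, covariates, truth model and survey generation."""

import numpy as np
import pytest

from mosquitosdm import (
    TruthModel,
    allocate_strata,
    fourier_components,
    fourier_stack,
    generate_covariates,
    generate_landscape,
    simulate_survey,
)
from mosquitosdm.errors import ConfigurationError, GenerationError
from mosquitosdm.landscape import CLASS_CODE, DEFAULT_SEASONAL


PROPS = {
    "urban": 0.2,
    "agricultural_sampled": 0.3,
    "agricultural_excluded": 0.2,
    "natural": 0.25,
    "water": 0.05,
}


def test_class_counts_within_5pct_of_targets():
    land = generate_landscape(50, 50, PROPS, seed=1)
    fractions = land.class_fractions()
    for name, target in PROPS.items():
        assert abs(fractions[name] - target) <= 0.05


def test_degenerate_single_class_map():
    land = generate_landscape(20, 20, {"urban": 1.0}, seed=3)
    assert np.all(land.landcover == CLASS_CODE["urban"])


def test_same_seed_reproduces_landscape():
    a = generate_landscape(40, 30, PROPS, seed=9)
    b = generate_landscape(40, 30, PROPS, seed=9)
    assert np.array_equal(a.landcover, b.landcover)
    c = generate_landscape(40, 30, PROPS, seed=10)
    assert not np.array_equal(a.landcover, c.landcover)


def test_landscape_is_patchy_not_salt_and_pepper():
    land = generate_landscape(50, 50, PROPS, seed=2)
    same = 0
    total = 0
    lc = land.landcover
    same += np.sum(lc[:, 1:] == lc[:, :-1]) + np.sum(lc[1:, :] == lc[:-1, :])
    total += lc[:, 1:].size + lc[1:, :].size
    # independent class draws would agree ~26% of the time; patches >> that
    assert same / total > 0.8


def test_bad_proportions_rejected():
    with pytest.raises(ConfigurationError):
        generate_landscape(20, 20, {"urban": 0.5, "water": 0.4}, seed=0)
    with pytest.raises(ConfigurationError):
        generate_landscape(5, 5, {"urban": 1.0}, seed=0)


def test_configured_ndvi_amplitude_recovered_by_refit():
    import dataclasses

    land = generate_landscape(40, 40, PROPS, seed=4)
    # amplitude spatial field switched off: the only scatter around the
    # configured class amplitude (0.3 at natural pixels) is the white noise
    params = {
        var: dataclasses.replace(p, amp_field_sd=0.0)
        for var, p in DEFAULT_SEASONAL.items()
    }
    cov = generate_covariates(land, years=2, seed=5, seasonal_params=params)
    target = DEFAULT_SEASONAL["NDVI"].amp1["natural"]
    assert target == 0.3
    # var(Ahat) ~ noise_sd^2 * 2/n for the DFT amplitude at high SNR
    sigma = DEFAULT_SEASONAL["NDVI"].noise_sd * np.sqrt(2.0 / 24)
    rows, cols = np.nonzero(land.class_mask("natural"))
    for r, c in zip(rows[:20], cols[:20]):
        a1 = fourier_components(cov.seasonal["NDVI"][:, r, c]).A1
        assert abs(a1 - target) < 3 * sigma + 1e-6


def test_zero_noise_series_is_exactly_harmonic():
    land = generate_landscape(20, 20, PROPS, seed=6)
    cov = generate_covariates(land, years=1, seed=7, noise_scale=0.0)
    p = DEFAULT_SEASONAL["EVI"]
    r, c = np.argwhere(land.class_mask("urban"))[0]
    t = np.arange(12)
    expected = (
        p.mean["urban"]
        + p.amp1["urban"] * np.cos(2 * np.pi * (t - p.peak1) / 12)
        + p.amp2["urban"] * np.cos(2 * np.pi * 2 * (t - p.peak2) / 12)
    )
    np.testing.assert_allclose(cov.seasonal["EVI"][:, r, c], expected, atol=1e-12)


def test_population_density_zero_on_water_nonnegative_everywhere():
    land = generate_landscape(40, 40, PROPS, seed=8)
    cov = generate_covariates(land, years=1, seed=9)
    pop = cov.static["population_density"]
    assert np.all(pop[land.class_mask("water")] == 0)
    assert np.all(pop >= 0)
    assert pop[land.class_mask("urban")].mean() > pop[land.class_mask("natural")].mean()


def test_largest_remainder_allocation_for_766_traps():
    counts = allocate_strata(766, {"urban": 0.4, "agricultural_sampled": 0.4, "natural": 0.2})
    assert counts["urban"] in (306, 307)
    assert counts["agricultural_sampled"] in (306, 307)
    assert counts["natural"] in (153, 154)
    assert sum(counts.values()) == 766


@pytest.mark.parametrize("n", [10, 77, 300, 766])
def test_allocation_exact_total(n):
    counts = allocate_strata(n, {"urban": 0.4, "agricultural_sampled": 0.4, "natural": 0.2})
    assert sum(counts.values()) == n


def test_survey_respects_strata_and_exclusions(landscape, covariates, truth, features):
    survey = simulate_survey(
        landscape, covariates, truth, n_traps=200, seed=1, features=features
    )
    counts = survey["stratum"].value_counts()
    assert counts["urban"] == 80 and counts["agricultural_sampled"] == 80
    assert counts["natural"] == 40
    rows, cols = landscape.cell_of(survey["x"].to_numpy(), survey["y"].to_numpy())
    for r, c, stratum in zip(rows, cols, survey["stratum"]):
        assert landscape.landcover[r, c] == CLASS_CODE[stratum]
    assert survey["week"].between(1, 30).all()
    assert (survey["abundance"] >= 0).all()
    # no revisits: every trap in its own cell
    assert len(set(zip(rows, cols))) == len(survey)


def test_survey_deterministic_under_seed(landscape, covariates, truth, features):
    a = simulate_survey(landscape, covariates, truth, 150, seed=3, features=features)
    b = simulate_survey(landscape, covariates, truth, 150, seed=3, features=features)
    assert a.equals(b)


def test_certain_suitability_gives_all_positive_traps(landscape, covariates, features):
    sure = TruthModel(coefficients={}, intercept=50.0)  # sigmoid(50) ~ 1
    survey = simulate_survey(
        landscape, covariates, sure, 100, seed=2, features=features
    )
    assert (survey["abundance"] >= 1).all()


def test_presence_fraction_matches_mean_suitability_binomial_bound():
    land = generate_landscape(80, 80, PROPS, seed=11)
    cov = generate_covariates(land, years=1, seed=12)
    feats = fourier_stack(cov, land)
    truth = TruthModel({"NDVI A1": 1.0, "DLST A0": 0.8}, intercept=0.2)
    survey = simulate_survey(land, cov, truth, 2000, seed=13, features=feats)
    suit = truth.suitability_map(feats, land)
    rows, cols = land.cell_of(survey["x"].to_numpy(), survey["y"].to_numpy())
    expected = suit[rows, cols].mean()
    observed = (survey["abundance"] >= 1).mean()
    bound = 2.576 * np.sqrt(0.25 / len(survey))  # conservative binomial 99%
    assert abs(observed - expected) < bound


def test_prevalence_monotone_in_truth_intercept(landscape, covariates, features):
    prevalences = []
    for intercept in (-1.5, 0.0, 1.5):
        truth = TruthModel({"NDVI A1": 1.0}, intercept=intercept)
        survey = simulate_survey(
            landscape, covariates, truth, 200, seed=21, features=features
        )
        prevalences.append((survey["abundance"] >= 1).mean())
    assert prevalences[0] < prevalences[1] < prevalences[2]


def test_oversampling_a_stratum_raises(landscape, covariates, truth, features):
    with pytest.raises(GenerationError, match="urban"):
        simulate_survey(
            landscape, covariates, truth, 2000,
            strata_props={"urban": 1.0}, seed=1, features=features,
        )


def test_covariates_deterministic_under_seed(landscape):
    a = generate_covariates(landscape, years=1, seed=5)
    b = generate_covariates(landscape, years=1, seed=5)
    assert np.array_equal(a.seasonal["MIR"], b.seasonal["MIR"])
    assert np.array_equal(a.static["dem"], b.static["dem"])
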