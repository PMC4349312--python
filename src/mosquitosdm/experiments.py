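"""Canned synthetic-study experiments for validation and reproducibility.

These functions run the package end to end under fixed study conditions —
a 766-location stratified survey (the size of the national survey this
workflow emulates) over a 50x50 km landscape with three known environmental
drivers — and measure how well each model family recovers what was planted:

* :func:`importance_recovery` — are all three true drivers in each family's
  top-10 importance table?
* :func:`ablation_contrast` — does adding pseudo-absences in the excluded
  land-cover class lower predicted suitability there?

The drivers are the annual-cycle peak months of the vegetation and thermal
signals plus their timing fields; phase components are used because they
carry no structural correlation with the mean/extreme components, making
"exactly three features drive suitability" well defined.
"""

from __future__ import annotations

import logging

from .ensemble import (
    aggregate_importance,
    default_m,
    derive_seed,
    fit_ensemble,
)
from .forest import fit_forest_ensemble, forest_importance
from .fourier import fourier_stack
from .landscape import (
    TruthModel,
    generate_covariates,
    generate_landscape,
    simulate_survey,
)
from .logistic import (
    make_logistic_fitter,
    rank_variables_logistic,
    screen_features,
)
from .nlda import make_nlda_fitter, select_generic_variables
from .occurrence import (
    add_pseudo_absences,
    dedup_cells,
    extract_features,
    survey_to_points,
)
from .pipeline import RunConfig, ablate_pseudo_absences

logger = logging.getLogger(__name__)

#: The three known drivers of the synthetic species' suitability: timing of
#: the vegetation green-up, of the middle-infra-red cycle, and of the
#: day-temperature cycle (standardized effects on the logit scale).
RECOVERY_DRIVERS: dict[str, float] = {
    "NDVI P1": 2.0,
    "MIR P1": -1.8,
    "DLST P1": 1.6,
}


def build_recovery_table(seed: int, drivers=None, width=50, height=50, n_traps=766):
    """One synthetic study: landscape, survey, occurrence table, features."""
    drivers = dict(drivers or RECOVERY_DRIVERS)
    land = generate_landscape(width, height, seed=derive_seed(seed, 1))
    cov = generate_covariates(land, years=1, seed=derive_seed(seed, 2))
    feats = fourier_stack(cov, land)
    truth = TruthModel(drivers, intercept=0.0)
    survey = simulate_survey(
        land, cov, truth, n_traps, seed=derive_seed(seed, 3), features=feats
    )
    pts = dedup_cells(survey_to_points(survey, land), land)
    pts = add_pseudo_absences(pts, land, n=38, seed=derive_seed(seed, 4))
    table = extract_features(pts, feats, land)
    return land, feats, truth, table


def top10_tables(table, feature_names, seed) -> dict[str, list[str]]:
    """Fit the three families and return each one's top-10 variable list."""
    m = default_m(table)
    out: dict[str, list[str]] = {}
    generic = select_generic_variables(feature_names)
    nlda_ens = fit_ensemble(
        make_nlda_fitter(generic), table, generic,
        n_submodels=100, m=m, seed=derive_seed(seed, 5), family="nlda",
    )
    out["nlda"] = aggregate_importance(
        [s.importance_ranks for s in nlda_ens.submodels], mode="rank"
    ).head(10)["variable"].tolist()

    forest_ens = fit_forest_ensemble(table, feature_names, seed=derive_seed(seed, 6))
    out["forest"] = aggregate_importance(
        forest_importance(forest_ens), mode="gini"
    ).head(10)["variable"].tolist()

    glm_feats = screen_features(table, feature_names)
    glm_ens = fit_ensemble(
        make_logistic_fitter(glm_feats), table, glm_feats,
        n_submodels=100, m=m, seed=derive_seed(seed, 7), family="glm",
    )
    out["glm"] = rank_variables_logistic(glm_ens.submodels).head(10)[
        "variable"
    ].tolist()
    return out


def importance_recovery(n_runs: int = 20, seed: int = 0, drivers=None) -> dict:
    """Fraction of runs in which every true driver makes each top-10 table."""
    drivers = dict(drivers or RECOVERY_DRIVERS)
    hits = {"nlda": 0, "forest": 0, "glm": 0}
    for i in range(n_runs):
        run_seed = derive_seed(seed, 100 + i)
        _, feats, _, table = build_recovery_table(run_seed, drivers)
        tables = top10_tables(table, list(feats), run_seed)
        for family, top in tables.items():
            hits[family] += all(d in top for d in drivers)
        logger.info("recovery run %d/%d: %s", i + 1, n_runs,
                    {f: t[:3] for f, t in tables.items()})
    return {
        "n_runs": n_runs,
        "hits": hits,
        "fraction": {f: h / n_runs for f, h in hits.items()},
    }


def ablation_config(seed: int) -> RunConfig:
    """Study conditions for the pseudo-absence ablation contrast.

    The excluded arable class has true suitability zero; two vegetation
    features drive suitability elsewhere. Discriminant/logistic ensembles are
    kept small — only the forest map enters the contrast.
    """
    return RunConfig(
        width=40, height=40, n_traps=400, years=1, seed=seed,
        truth_coefficients={"NDVI A1": 2.0, "DLST A0": 1.0},
        truth_excluded_zero=True, n_pseudo_absences=43,
        nlda_n_bootstraps=10, glm_n_bootstraps=10, eval_n_replicates=200,
    )


def ablation_contrast(n_seeds: int = 10, seed: int = 0) -> list[dict]:
    """Paired with/without-pseudo-absence runs over independent seeds."""
    results = []
    for i in range(n_seeds):
        cfg = ablation_config(derive_seed(seed, 200 + i))
        results.append(ablate_pseudo_absences(cfg))
    return results
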