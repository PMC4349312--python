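"""Configuration-driven orchestration of the full suitability workflow.

Stages, in order: generate (landscape + covariates + survey) -> fourier
(seasonality feature stack) -> prep (presence/absence table with
pseudo-absences and extracted covariates) -> fit (discriminant, forest and
logistic ensembles) -> map (per-model suitability rasters) -> evaluate
(accuracy report, importance tables, residual correlogram). A single master
seed fans out deterministically to every stochastic stage, so a rerun with
the same config reproduces every artifact.

The pseudo-absence ablation mode runs the pipeline twice — identical except
for the pseudo-absence count (0 vs n) — and reports the mean predicted
suitability over the excluded land-cover cells for each run, quantifying how
much the added absences rein in predictions over unsampled unsuitable land.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import __version__
from .ensemble import (
    aggregate_importance,
    derive_seed,
    fit_ensemble,
    predict_grid,
)
from .errors import PipelineError
from .evaluation import evaluate_models
from .forest import fit_forest_ensemble, forest_importance
from .fourier import fourier_stack
from .landscape import (
    DEFAULT_CLASS_PROPS,
    DEFAULT_STRATA_PROPS,
    CovariateStack,
    Landscape,
    TruthModel,
    generate_covariates,
    generate_landscape,
    simulate_survey,
)
from .logistic import (
    deviance_residuals,
    make_logistic_fitter,
    moran_correlogram,
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
from .rasters import write_ascii_grid

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("nlda", "forest", "glm")


@dataclass
class RunConfig:
    """Everything a reproducible run needs, round-trippable through YAML."""

    width: int = 50
    height: int = 50
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPS))
    years: int = 2
    species: str = "synthetic_species"
    truth_coefficients: dict = field(
        default_factory=lambda: {
            "NDVI A1": 1.5,
            "DLST A0": 1.2,
            "Population density": -1.0,
        }
    )
    truth_intercept: float = 0.0
    truth_excluded_zero: bool = False
    n_traps: int = 300
    strata_proportions: dict = field(default_factory=lambda: dict(DEFAULT_STRATA_PROPS))
    n_pseudo_absences: int | None = None  # None = 5% of observed records
    # model hyperparameters
    nlda_k: int = 4
    nlda_n_bootstraps: int = 100
    nlda_generic_only: bool = True
    glm_n_bootstraps: int = 100
    glm_screen_threshold: float | None = 0.95
    forest_n_subsets: int = 5
    forest_n_trees: int = 500
    bootstrap_m_cap: int = 150
    # evaluation
    eval_threshold: float = 0.5
    eval_n_replicates: int = 2000
    eval_level: float = 0.95
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def truth(self) -> TruthModel:
        return TruthModel(
            coefficients=dict(self.truth_coefficients),
            intercept=self.truth_intercept,
            force_excluded_zero=self.truth_excluded_zero,
        )


@dataclass
class RunArtifacts:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    landscape: Landscape
    covariates: CovariateStack
    features: dict
    table: object  # occurrence DataFrame
    ensembles: dict
    maps: dict
    importance: dict
    accuracy: object
    correlogram: object
    outdir: Path | None = None


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("generate")
def stage_generate(config: RunConfig):
    seed = config.seed
    landscape = generate_landscape(
        config.width, config.height, config.class_proportions,
        seed=derive_seed(seed, 1),
    )
    covariates = generate_covariates(
        landscape, years=config.years, seed=derive_seed(seed, 2)
    )
    return landscape, covariates


@_stage("fourier")
def stage_fourier(covariates, landscape):
    return fourier_stack(covariates, landscape)


@_stage("prep")
def stage_prep(config: RunConfig, landscape, covariates, features):
    survey = simulate_survey(
        landscape, covariates, config.truth(),
        n_traps=config.n_traps,
        strata_props=config.strata_proportions,
        seed=derive_seed(config.seed, 3),
        features=features,
    )
    points = survey_to_points(survey, landscape)
    points = dedup_cells(points, landscape)
    points = add_pseudo_absences(
        points, landscape, n=config.n_pseudo_absences, seed=derive_seed(config.seed, 4)
    )
    table = extract_features(points, features, landscape)
    return survey, table


@_stage("fit")
def stage_fit(config: RunConfig, table, feature_names):
    from .ensemble import default_m

    m = default_m(table, cap=config.bootstrap_m_cap)
    ensembles = {}

    nlda_features = (
        select_generic_variables(feature_names)
        if config.nlda_generic_only
        else list(feature_names)
    )
    ensembles["nlda"] = fit_ensemble(
        make_nlda_fitter(nlda_features, k_presence=config.nlda_k, k_absence=config.nlda_k),
        table,
        nlda_features,
        n_submodels=config.nlda_n_bootstraps,
        m=m,
        seed=derive_seed(config.seed, 5),
        family="nlda",
    )

    ensembles["forest"] = fit_forest_ensemble(
        table,
        list(feature_names),
        n_subsets=config.forest_n_subsets,
        n_trees=config.forest_n_trees,
        seed=derive_seed(config.seed, 6),
    )

    glm_features = list(feature_names)
    if config.glm_screen_threshold is not None:
        glm_features = screen_features(
            table, glm_features, threshold=config.glm_screen_threshold
        )
    ensembles["glm"] = fit_ensemble(
        make_logistic_fitter(glm_features),
        table,
        glm_features,
        n_submodels=config.glm_n_bootstraps,
        m=m,
        seed=derive_seed(config.seed, 7),
        family="glm",
    )
    return ensembles


@_stage("map")
def stage_map(ensembles, features, landscape):
    return {
        name: predict_grid(ens, features, landscape)
        for name, ens in ensembles.items()
    }


@_stage("evaluate")
def stage_evaluate(config: RunConfig, ensembles, table):
    predictions = {name: ens.predict(table) for name, ens in ensembles.items()}
    labels = table["presence"].to_numpy(dtype=int)
    accuracy = evaluate_models(
        predictions,
        labels,
        species=config.species,
        threshold=config.eval_threshold,
        n_reps=config.eval_n_replicates,
        level=config.eval_level,
        seed=derive_seed(config.seed, 8),
    )

    importance = {
        "nlda": aggregate_importance(
            [s.importance_ranks for s in ensembles["nlda"].submodels], mode="rank"
        ),
        "forest": aggregate_importance(
            forest_importance(ensembles["forest"]), mode="gini"
        ),
        "glm": rank_variables_logistic(ensembles["glm"].submodels),
    }

    resid = deviance_residuals(labels, predictions["glm"])
    coords = table[["x", "y"]].to_numpy(dtype=float)
    correlogram = moran_correlogram(resid, coords)
    return predictions, accuracy, importance, correlogram


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    write_covariates: bool = False,
) -> RunArtifacts:
    """Run every stage in order; optionally persist the artifact set.

    Artifacts written under *outdir*: the config echo, land-cover and
    (optionally) covariate rasters, the survey and occurrence tables, one
    suitability map and importance table per model family, the accuracy
    report, the GLM residual correlogram, fitted ensembles, and a manifest
    of derived seeds and the package version.
    """
    landscape, covariates = stage_generate(config)
    features = stage_fourier(covariates, landscape)
    feature_names = list(features)
    survey, table = stage_prep(config, landscape, covariates, features)
    ensembles = stage_fit(config, table, feature_names)
    maps = stage_map(ensembles, features, landscape)
    predictions, accuracy, importance, correlogram = stage_evaluate(
        config, ensembles, table
    )

    artifacts = RunArtifacts(
        config=config, landscape=landscape, covariates=covariates,
        features=features, table=table, ensembles=ensembles, maps=maps,
        importance=importance, accuracy=accuracy, correlogram=correlogram,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts.outdir = outdir
        config.to_yaml(outdir / "config.yaml")
        write_ascii_grid(outdir / "landcover.asc", landscape.landcover.astype(float),
                         landscape.origin, landscape.cell_size)
        if write_covariates:
            covdir = outdir / "covariates"
            covdir.mkdir(exist_ok=True)
            for key, grid in covariates.static.items():
                write_ascii_grid(covdir / f"{key}.asc", grid,
                                 landscape.origin, landscape.cell_size)
            for var, series in covariates.seasonal.items():
                for month in range(series.shape[0]):
                    write_ascii_grid(
                        covdir / f"{var}_m{month:02d}.asc", series[month],
                        landscape.origin, landscape.cell_size,
                    )
        survey.to_csv(outdir / "survey.csv", index=False)
        table.to_csv(outdir / "occurrences.csv", index=False)
        for name in ensembles:
            write_ascii_grid(outdir / f"suitability_{name}.asc", maps[name],
                             landscape.origin, landscape.cell_size)
            importance[name].to_csv(outdir / f"importance_{name}.csv", index=False)
            importance[name].head(10).to_csv(
                outdir / f"importance_{name}_top10.csv", index=False
            )
        accuracy.to_csv(outdir / "accuracy.csv")
        correlogram.to_csv(outdir / "correlogram_glm.csv", index=False)
        joblib.dump(ensembles, outdir / "ensembles.joblib")
        manifest = {
            "package_version": __version__,
            "master_seed": config.seed,
            "stage_seeds": {
                "landscape": derive_seed(config.seed, 1),
                "covariates": derive_seed(config.seed, 2),
                "survey": derive_seed(config.seed, 3),
                "pseudo_absences": derive_seed(config.seed, 4),
                "nlda": derive_seed(config.seed, 5),
                "forest": derive_seed(config.seed, 6),
                "glm": derive_seed(config.seed, 7),
                "evaluation": derive_seed(config.seed, 8),
            },
            "n_occurrence_records": int(len(table)),
            "n_features": len(feature_names),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return artifacts


def excluded_mean_suitability(artifacts: RunArtifacts, model: str = "forest") -> float:
    """Mean predicted suitability over excluded-class cells."""
    mask = artifacts.landscape.class_mask("agricultural_excluded")
    return float(np.nanmean(artifacts.maps[model][mask]))


def ablate_pseudo_absences(
    config: RunConfig,
    outdir: str | Path | None = None,
    model: str = "forest",
) -> dict:
    """Paired runs with and without pseudo-absences (Figure-2-style contrast).

    Both runs share every seed; only the pseudo-absence count differs (0 vs
    the configured n). Returns the mean predicted suitability over excluded
    cells for each run, their difference, and the cell count.
    """
    if not config.truth_excluded_zero:
        raise PipelineError(
            "ablate", "ablation requires truth_excluded_zero=True "
            "(an excluded class with zero true suitability)"
        )
    cfg_without = dataclasses.replace(config, n_pseudo_absences=0)
    cfg_with = dataclasses.replace(config)
    out_without = Path(outdir) / "without_pseudo" if outdir else None
    out_with = Path(outdir) / "with_pseudo" if outdir else None
    run_without = run_pipeline(cfg_without, out_without)
    run_with = run_pipeline(cfg_with, out_with)
    n_cells = int(run_with.landscape.class_mask("agricultural_excluded").sum())
    result = {
        "model": model,
        "mean_excluded_without_pseudo": excluded_mean_suitability(run_without, model),
        "mean_excluded_with_pseudo": excluded_mean_suitability(run_with, model),
        "n_excluded_cells": n_cells,
        "n_pseudo_absences": int(
            (run_with.table["origin"] == "pseudo_absence").sum()
        ),
    }
    result["difference"] = (
        result["mean_excluded_without_pseudo"] - result["mean_excluded_with_pseudo"]
    )
    if outdir is not None:
        with open(Path(outdir) / "ablation.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
    return result
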