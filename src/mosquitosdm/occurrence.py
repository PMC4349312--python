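"""Trap survey -> model-ready presence/absence table.

Seasonally varying catch counts are collapsed to presence/absence, records
are deduplicated to one per 1-km grid cell with presence taking priority,
pseudo-absences are added in unsampled land cover that is deemed unsuitable
(high-productivity arable land), and covariate values are extracted at each
point. The occurrence table is a plain DataFrame with columns::

    point_id, x, y, row, col, presence (0/1), origin (observed |
    pseudo_absence), [one column per extracted feature]

keeping the origin tag so pseudo-absences stay auditable end to end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import GenerationError, InputError, PipelineError
from .landscape import Landscape

logger = logging.getLogger(__name__)

POINT_COLUMNS = ["point_id", "x", "y", "row", "col", "presence", "origin"]


def reclassify(abundance):
    """Collapse catch counts to presence (>=1 mosquito) / absence (0).

    Accepts a scalar or array; returns int 0/1 of the same shape.
    """
    arr = np.asarray(abundance)
    if np.any(arr < 0):
        raise InputError("abundance counts must be non-negative")
    out = (arr >= 1).astype(int)
    return out if arr.ndim else int(out)


def survey_to_points(survey: pd.DataFrame, landscape: Landscape) -> pd.DataFrame:
    """Convert a trap survey table into observed occurrence points."""
    row, col = landscape.cell_of(survey["x"].to_numpy(), survey["y"].to_numpy())
    return pd.DataFrame(
        {
            "point_id": survey["trap_id"].to_numpy(),
            "x": survey["x"].to_numpy(),
            "y": survey["y"].to_numpy(),
            "row": row,
            "col": col,
            "presence": reclassify(survey["abundance"].to_numpy()),
            "origin": "observed",
        }
    )


def dedup_cells(points: pd.DataFrame, landscape: Landscape) -> pd.DataFrame:
    """Keep one record per grid cell, presence winning over absence.

    A cell holding at least one presence keeps a presence record; a cell with
    only absences keeps one absence. Ties within a class break on the lowest
    point_id, making the result independent of input order. Idempotent.
    """
    inside = landscape.in_bounds(points["row"].to_numpy(), points["col"].to_numpy())
    if not np.all(inside):
        bad = points.loc[~inside, "point_id"].tolist()
        raise InputError(f"points outside the landscape grid: {bad}")
    ordered = points.sort_values(
        ["presence", "point_id"], ascending=[False, True], kind="mergesort"
    )
    kept = ordered.drop_duplicates(subset=["row", "col"], keep="first")
    return kept.sort_values("point_id", kind="mergesort").reset_index(drop=True)


def add_pseudo_absences(
    points: pd.DataFrame,
    landscape: Landscape,
    n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Add *n* pseudo-absence points in excluded (unsampled, unsuitable) cells.

    Placement is uniform at random, seeded, over agricultural_excluded cells
    not already holding a record. When *n* is None it defaults to 5% of the
    observed records (rounded up) — the survey this emulates used a fixed 43
    points for its particular excluded area, but stated no general rule.
    """
    if n is None:
        n = int(np.ceil(0.05 * len(points)))
    if n == 0:
        return points.copy()
    occupied = set(zip(points["row"].to_numpy(), points["col"].to_numpy()))
    rows, cols = np.nonzero(landscape.class_mask("agricultural_excluded"))
    free = [(r, c) for r, c in zip(rows, cols) if (r, c) not in occupied]
    if n > len(free):
        raise GenerationError(
            f"requested {n} pseudo-absences but only {len(free)} free excluded cells"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(free), size=n, replace=False)
    sel = np.array(free)[pick]
    x, y = landscape.cell_center(sel[:, 0], sel[:, 1])
    next_id = int(points["point_id"].max()) + 1 if len(points) else 0
    pseudo = pd.DataFrame(
        {
            "point_id": np.arange(next_id, next_id + n),
            "x": x,
            "y": y,
            "row": sel[:, 0],
            "col": sel[:, 1],
            "presence": 0,
            "origin": "pseudo_absence",
        }
    )
    out = pd.concat([points, pseudo], ignore_index=True)
    logger.info("added %d pseudo-absences in excluded land cover", n)
    return out


def extract_features(
    points: pd.DataFrame,
    features: dict[str, np.ndarray],
    landscape: Landscape,
) -> pd.DataFrame:
    """Attach the pixel value of every feature raster to each point.

    Points falling on nodata pixels (NaN in any feature) are dropped with a
    logged count; an empty result raises, since nothing downstream can run.
    """
    shape = landscape.shape
    for name, grid in features.items():
        if grid.shape != shape:
            raise InputError(f"feature raster '{name}' shape {grid.shape} != {shape}")
    out = points.reset_index(drop=True).copy()
    r = out["row"].to_numpy()
    c = out["col"].to_numpy()
    for name, grid in features.items():
        out[name] = grid[r, c]
    feat_cols = list(features)
    bad = out[feat_cols].isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d points on nodata pixels", int(bad.sum()))
    out = out[~bad].reset_index(drop=True)
    if len(out) == 0:
        raise PipelineError("occurrence_prep", "all points fell on nodata pixels")
    return out
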