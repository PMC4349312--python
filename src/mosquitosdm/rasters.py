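"""ESRI ASCII grid reading and writing.

All gridded artifacts (land cover, covariates, feature rasters, suitability
maps) are exchanged as single-band ESRI ASCII grids: a plain-text format with
a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows of values, northernmost row first.

Grid convention used throughout the package: arrays are indexed [row, col]
with row 0 the northern edge, matching the on-disk row order. A point (x, y)
in projected km falls in::

    col = floor((x - x_origin) / cell_size)
    row = nrows - 1 - floor((y - y_origin) / cell_size)

with half-open cells, so a point on a cell's south/west edge belongs to it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    origin: tuple[float, float] = (0.0, 0.0),
    cell_size: float = 1.0,
    nodata: float = NODATA_DEFAULT,
    fmt: str = "%.10g",
) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN cells become *nodata*."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"expected 2-D grid, got shape {grid.shape}")
    nrows, ncols = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {origin[0]:.10g}\n"
        f"yllcorner {origin[1]:.10g}\n"
        f"cellsize {cell_size:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read an ESRI ASCII grid.

    Returns ``(grid, (xllcorner, yllcorner), cell_size)`` with nodata cells
    mapped to NaN.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (nrows, ncols):
        raise ValueError(
            f"grid shape {grid.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, (header["xllcorner"], header["yllcorner"]), header["cellsize"]
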