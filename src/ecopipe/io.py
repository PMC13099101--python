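"""Plain-text raster and table I/O.

Rasters are exchanged as ESRI ASCII grids (6-line header + whitespace-
separated values), the simplest interoperable grid format; lookup tables
are CSV with a ``landuse_code`` key column; networks, models and reports
round-trip through JSON.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "default_carbon_pools",
    "default_biophysical",
    "config_hash",
]

NODATA = -9999.0


def write_ascii_grid(
    path,
    grid: np.ndarray,
    cellsize: float = 1000.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = NODATA,
    mask: np.ndarray | None = None,
) -> None:
    grid = np.asarray(grid, dtype=float)
    out = grid.copy()
    if mask is not None:
        out[~mask] = nodata
    out[~np.isfinite(out)] = nodata
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in out:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Returns (array with NODATA as nan, header dict)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    data = np.loadtxt(lines[6:])
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    return data, header


def _data_path(name: str):
    return resources.files("ecopipe").joinpath("data", name)


def default_carbon_pools():
    """The package's default carbon-pool table (synthetic defaults in the
    style of published land-use carbon densities; fully user-overridable)."""
    from .es import CarbonPoolTable
    import pandas as pd

    with resources.as_file(_data_path("default_carbon_pools.csv")) as p:
        return CarbonPoolTable(pd.read_csv(p))


def default_biophysical():
    """The package's default biophysical coefficient table."""
    from .es import BiophysicalTable
    import pandas as pd

    with resources.as_file(_data_path("default_biophysical.csv")) as p:
        return BiophysicalTable(pd.read_csv(p))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
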