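"""Ecosystem-service layers from simplified production equations.

Seven services are computed per grid cell from a ``LandscapeGrid`` and two
lookup tables keyed by land-use code:

* WY  — water yield, ``Y = (1 - AET/P) * P`` (mm), clamped at zero;
* SDR — soil retention from USLE-style factor products,
  ``PSLA = R*K*LS``, ``USLE = R*K*C*P``, ``SEDRET = PSLA - USLE``
  (t/(ha*a));
* CS  — carbon storage, sum of above-ground, below-ground, soil and dead
  organic pools (t/ha);
* N/P — nutrient export, ``export = load * NDR`` (kg/cell);
* HQ  — habitat quality, suitability degraded by distance-decayed threats
  through a saturating response with exponent z=2.5 and half-saturation
  K=0.5;
* FS  — food supply, the regional grain total apportioned over cropland
  proportionally to NDVI (t).

All operators are pure functions of their inputs.  ``SEDRET`` is computed
from the factor products exactly as written above; because the cover and
practice factors enter the actual-loss term without the topographic factor,
negative retention cells are possible and are counted in the QC summary
(``usle_includes_ls=True`` switches to the conventional USLE variant with
LS in both terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import LANDUSE_CODES, LandscapeGrid

__all__ = [
    "ESLayer",
    "CarbonPoolTable",
    "BiophysicalTable",
    "water_yield",
    "ls_factor",
    "soil_retention",
    "carbon_storage",
    "nutrient_export",
    "habitat_quality",
    "food_supply",
    "compute_all_es",
    "ES_NAMES",
]

ES_NAMES = ("WY", "SDR", "CS", "N", "P", "HQ", "FS")

ES_UNITS = {
    "WY": "mm",
    "SDR": "t/(ha*a)",
    "CS": "t/ha",
    "N": "kg/cell",
    "P": "kg/cell",
    "HQ": "dimensionless",
    "FS": "t",
}


@dataclass
class ESLayer:
    """One named ecosystem-service raster."""

    name: str
    grid: np.ndarray
    units: str = ""
    qc: dict | None = None

    def __post_init__(self) -> None:
        if self.name not in ES_NAMES:
            raise ValueError(f"unknown ES name {self.name!r}")
        if not self.units:
            self.units = ES_UNITS[self.name]

    def summary(self, mask: np.ndarray | None = None) -> dict:
        v = self.grid if mask is None else self.grid[mask]
        v = v[np.isfinite(v)]
        return {
            "name": self.name,
            "units": self.units,
            "min": float(v.min()),
            "mean": float(v.mean()),
            "max": float(v.max()),
            "negatives": int((v < 0).sum()),
        }


def _check_codes(table: pd.DataFrame, what: str) -> None:
    missing = set(LANDUSE_CODES) - set(table.index)
    if missing:
        raise KeyError(f"{what} table missing land-use code(s): {sorted(missing)}")


class CarbonPoolTable:
    """Per-land-use carbon pools (t/ha): c_above, c_below, c_soil, c_dead."""

    COLUMNS = ("c_above", "c_below", "c_soil", "c_dead")

    def __init__(self, df: pd.DataFrame):
        df = df.set_index("landuse_code") if "landuse_code" in df.columns else df
        _check_codes(df, "carbon pool")
        if (df[list(self.COLUMNS)] < 0).any().any():
            raise ValueError("carbon pools must be non-negative")
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "CarbonPoolTable":
        return cls(pd.read_csv(path))

    def total(self, code: int) -> float:
        if code not in self.df.index:
            raise KeyError(f"carbon pool table missing land-use code {code}")
        return float(self.df.loc[code, list(self.COLUMNS)].sum())


class BiophysicalTable:
    """Per-land-use biophysical coefficients.

    Columns: usle_c, usle_p (cover/practice factors in [0,1]); load_n,
    load_p (kg/cell); ndr_n, ndr_p (delivery ratios in [0,1]); habitat_h
    (suitability in [0,1]); threat_weight (>=0); threat_decay (distance
    scale in cells, >0 where the class is a threat).
    """

    UNIT_COLS = ("usle_c", "usle_p", "ndr_n", "ndr_p", "habitat_h")

    def __init__(self, df: pd.DataFrame):
        df = df.set_index("landuse_code") if "landuse_code" in df.columns else df
        _check_codes(df, "biophysical")
        for col in self.UNIT_COLS:
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if (df[["load_n", "load_p"]] < 0).any().any():
            raise ValueError("nutrient loads must be non-negative")
        if (df["threat_weight"] < 0).any():
            raise ValueError("threat weights must be non-negative")
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "BiophysicalTable":
        return cls(pd.read_csv(path))

    def per_cell(self, landuse: np.ndarray, column: str) -> np.ndarray:
        lut = np.full(max(LANDUSE_CODES) + 1, np.nan)
        for code in self.df.index:
            lut[code] = self.df.loc[code, column]
        return lut[landuse]


def water_yield(pre: np.ndarray, aet: np.ndarray, mask: np.ndarray | None = None) -> ESLayer:
    """Annual water yield Y = (1 - AET/P) * P = P - AET, clamped at zero."""
    pre = np.asarray(pre, dtype=float)
    aet = np.asarray(aet, dtype=float)
    if pre.shape != aet.shape:
        raise ValueError("pre/aet shape mismatch")
    bad = pre <= 0
    if mask is not None:
        bad &= mask
    with np.errstate(divide="ignore", invalid="ignore"):
        y = (1.0 - aet / pre) * pre
    y = np.where(bad, np.nan, np.maximum(y, 0.0))
    return ESLayer("WY", y, qc={"nonpositive_pre_cells": int(bad.sum())})


def ls_factor(slope_deg: np.ndarray, cellsize: float = 1000.0) -> np.ndarray:
    """Topographic (slope length-steepness) factor.

    Default formula: ``LS = (flowlength/22.13)**0.4 * (sin(theta)/0.0896)**1.3``
    with flow length fixed at the cell size, the common raster USLE form.
    Flat cells take the formula's minimum (sin 0 -> LS = 0).
    """
    theta = np.radians(np.asarray(slope_deg, dtype=float))
    if np.any(theta < 0):
        raise ValueError("slope must be non-negative")
    m = (cellsize / 22.13) ** 0.4
    return m * (np.sin(theta) / 0.0896) ** 1.3


def soil_retention(
    r: np.ndarray,
    k: np.ndarray,
    ls: np.ndarray,
    usle_c: np.ndarray,
    usle_p: np.ndarray,
    usle_includes_ls: bool = False,
    clamp_negative: bool = False,
) -> tuple[np.ndarray, np.ndarray, ESLayer]:
    """PSLA = R*K*LS; USLE = R*K*C*P (optionally *LS); SEDRET = PSLA - USLE.

    Returns (PSLA, USLE, ESLayer('SDR')) where the SDR layer holds SEDRET.
    Negative SEDRET cells (possible when C*P > LS under the default forms)
    are counted in the layer's QC summary.
    """
    arrays = [np.asarray(a, dtype=float) for a in (r, k, ls, usle_c, usle_p)]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("soil_retention inputs must share a shape")
    r, k, ls, c, p = arrays
    psla = r * k * ls
    usle = r * k * c * p
    if usle_includes_ls:
        usle = usle * ls
    sedret = psla - usle
    n_neg = int(np.nansum(sedret < 0))
    if clamp_negative:
        sedret = np.maximum(sedret, 0.0)
    layer = ESLayer("SDR", sedret, qc={"negative_sedret_cells": n_neg})
    return psla, usle, layer


def carbon_storage(landuse: np.ndarray, pools: CarbonPoolTable) -> ESLayer:
    """Total carbon stock per cell: sum of the four pools for its class."""
    lut = np.full(max(LANDUSE_CODES) + 1, np.nan)
    for code in pools.df.index:
        lut[code] = pools.total(code)
    present = np.unique(landuse)
    for code in present:
        if code not in pools.df.index:
            raise KeyError(f"carbon pool table missing land-use code {int(code)}")
    return ESLayer("CS", lut[landuse])


def nutrient_export(
    landuse: np.ndarray,
    table: BiophysicalTable,
    nutrient: str,
    modifier: np.ndarray | float = 1.0,
) -> ESLayer:
    """Nutrient export = modified load * delivery ratio, per cell.

    ``modifier`` scales the per-class load (default 1; an NDVI-based
    retention scaling may be passed)."""
    nutrient = nutrient.upper()
    if nutrient not in ("N", "P"):
        raise ValueError("nutrient must be 'N' or 'P'")
    load = table.per_cell(landuse, f"load_{nutrient.lower()}")
    ndr = table.per_cell(landuse, f"ndr_{nutrient.lower()}")
    modifier = np.asarray(modifier, dtype=float)
    if np.any(modifier < 0):
        raise ValueError("load modifier must be non-negative")
    return ESLayer(nutrient, load * modifier * ndr)


def threat_degradation(
    landuse: np.ndarray,
    table: BiophysicalTable,
    normalize: bool = True,
) -> np.ndarray:
    """Degradation D in [0,1]: distance-decayed, weighted threat exposure.

    Each land-use class with positive threat weight is a threat source; its
    contribution at a cell is ``weight * exp(-d / decay)`` with d the
    Euclidean distance (in cells) to the nearest source cell of that class.
    Contributions are summed over threat classes and min-max normalized.
    """
    d_total = np.zeros(np.asarray(landuse).shape, dtype=float)
    for code in table.df.index:
        w = float(table.df.loc[code, "threat_weight"])
        if w <= 0:
            continue
        decay = float(table.df.loc[code, "threat_decay"])
        if decay <= 0:
            raise ValueError(f"threat class {code} needs a positive decay scale")
        source = landuse == code
        if not source.any():
            continue
        dist = ndimage.distance_transform_edt(~source)
        d_total += w * np.exp(-dist / decay)
    if normalize and d_total.max() > 0:
        d_total = (d_total - d_total.min()) / (d_total.max() - d_total.min())
    return d_total


def habitat_quality(
    landuse: np.ndarray,
    table: BiophysicalTable,
    z: float = 2.5,
    half_saturation: float = 0.5,
    degradation: np.ndarray | None = None,
) -> ESLayer:
    """Habitat quality Q = H * (1 - D**z / (D**z + K**z)), in [0,1].

    H is the class habitat suitability, D the normalized degradation score
    (computed from the table's threat classes when not supplied), z=2.5 and
    K=0.5 the response constants.
    """
    h = table.per_cell(landuse, "habitat_h")
    d = threat_degradation(landuse, table) if degradation is None else np.asarray(degradation, float)
    dz = np.power(d, z)
    q = h * (1.0 - dz / (dz + half_saturation**z))
    return ESLayer("HQ", q)


def food_supply(ndvi: np.ndarray, landuse: np.ndarray, fs_total: float,
                mask: np.ndarray | None = None) -> ESLayer:
    """Regional grain total apportioned over cropland proportionally to NDVI."""
    from .landscape import CROPLAND

    ndvi = np.asarray(ndvi, dtype=float)
    crop = (landuse == CROPLAND)
    if mask is not None:
        crop &= mask
    weights = np.where(crop & (ndvi > 0), ndvi, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no cropland cell with positive NDVI")
    return ESLayer("FS", weights * (fs_total / total))


def compute_all_es(
    grid: LandscapeGrid,
    pools: CarbonPoolTable,
    bio: BiophysicalTable,
    fs_total: float = 6.5e7,
    usle_includes_ls: bool = False,
) -> dict[str, ESLayer]:
    """All seven ES layers for a landscape, keyed by ES name."""
    wy = water_yield(grid.pre, grid.aet, grid.mask)
    ls = ls_factor(grid.slope, grid.cellsize)
    _, _, sdr = soil_retention(
        grid.r, grid.k, ls,
        bio.per_cell(grid.landuse, "usle_c"),
        bio.per_cell(grid.landuse, "usle_p"),
        usle_includes_ls=usle_includes_ls,
    )
    cs = carbon_storage(grid.landuse, pools)
    n = nutrient_export(grid.landuse, bio, "N")
    p = nutrient_export(grid.landuse, bio, "P")
    hq = habitat_quality(grid.landuse, bio)
    fs = food_supply(grid.ndvi, grid.landuse, fs_total, grid.mask)
    return {L.name: L for L in (wy, sdr, cs, n, p, hq, fs)}
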