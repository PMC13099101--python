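"""Seeded synthetic landscape generation.

Produces aligned raster stacks that emulate the statistical structure of a
temperate monsoon study region: west-high/east-low terrain, annual
precipitation in a configured 500-900 mm band, mean annual temperature
between 12 and 16 degrees C, spatially autocorrelated six-class land use,
and the ancillary layers (NDVI, population, soil erodibility, rainfall
erosivity, actual evapotranspiration) that drive the ecosystem-service
models.  Every layer is a deterministic function of the configuration and a
single integer seed, and the generator also returns a ``GroundTruth`` record
describing any planted driver effects or threshold structure so that
downstream driver-identification and threshold-detection stages can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GeneratorConfig",
    "LandscapeGrid",
    "GroundTruth",
    "PlantedThreshold",
    "generate_landscape",
    "derive_slope",
    "derive_erosivity",
    "plant_pair_relationship",
    "synthesize_es_from_drivers",
]

# Land-use codes (shared across the package).
CROPLAND, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED = 1, 2, 3, 4, 5, 6
LANDUSE_CODES = (CROPLAND, FOREST, GRASSLAND, WATER, BUILTUP, UNUSED)

FACTOR_NAMES = ("tem", "slope", "landuse", "k", "r", "pre", "pop", "ndvi")


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic landscape.

    Defaults are the study conditions: ~1 km cells, precipitation between
    500 and 900 mm/yr, temperature between 12 and 16 C, a westward
    elevation trend of ~800 m across the grid.
    """

    nrows: int = 64
    ncols: int = 64
    cellsize: float = 1000.0  # metres
    pre_min: float = 500.0    # mm/yr
    pre_max: float = 900.0
    tem_min: float = 12.0     # degrees C
    tem_max: float = 16.0
    dem_base: float = 100.0   # m, eastern lowland
    dem_trend: float = 800.0  # m, west-over-east elevation excess
    dem_relief: float = 250.0 # m, random-field amplitude
    smooth_sigma: float = 3.0 # cells, Gaussian correlation length
    aet_frac_mean: float = 0.62  # AET as a fraction of precipitation
    aet_frac_sd: float = 0.08
    ndvi_max: float = 0.9
    pop_max: float = 2500.0   # persons/km^2
    k_min: float = 0.10       # t*ha*h/(ha*MJ*mm)
    k_max: float = 0.40
    erosivity_a: float = 0.05  # r = a * pre**b
    erosivity_b: float = 1.5
    fs_total: float = 6.5e7   # t, regional total grain yield

    def validate(self) -> None:
        if self.nrows < 8 or self.ncols < 8:
            raise ConfigurationError("grid must be at least 8x8")
        if self.cellsize <= 0:
            raise ConfigurationError("cellsize must be positive")
        for lo, hi, name in (
            (self.pre_min, self.pre_max, "pre"),
            (self.tem_min, self.tem_max, "tem"),
            (self.k_min, self.k_max, "k"),
        ):
            if not lo < hi:
                raise ConfigurationError(f"{name} range invalid: [{lo}, {hi}]")
        if self.erosivity_a < 0 or self.erosivity_b < 0:
            raise ConfigurationError("erosivity coefficients must be non-negative")


@dataclass
class LandscapeGrid:
    """Aligned raster stack; all layers share (nrows, ncols)."""

    nrows: int
    ncols: int
    cellsize: float
    dem: np.ndarray
    slope: np.ndarray
    pre: np.ndarray
    tem: np.ndarray
    aet: np.ndarray
    ndvi: np.ndarray
    pop: np.ndarray
    k: np.ndarray
    r: np.ndarray
    landuse: np.ndarray
    mask: np.ndarray

    LAYERS = ("dem", "slope", "pre", "tem", "aet", "ndvi", "pop", "k", "r", "landuse")

    def __post_init__(self) -> None:
        shape = (self.nrows, self.ncols)
        for name in self.LAYERS + ("mask",):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} has shape {arr.shape}, expected {shape}")
        if not set(np.unique(self.landuse[self.mask])) <= set(LANDUSE_CODES):
            raise ValueError("landuse codes outside 1..6")

    def layer(self, name: str) -> np.ndarray:
        if name not in self.LAYERS:
            raise KeyError(name)
        return getattr(self, name)

    def factor_table(self):
        """Masked cell values of the eight driver factors as a DataFrame."""
        import pandas as pd

        m = self.mask
        return pd.DataFrame({name: self.layer(name)[m] for name in FACTOR_NAMES})


@dataclass(frozen=True)
class PlantedThreshold:
    """A planted sign reversal: the association between ``driver`` and the
    synergy/trade-off state of ``pair`` reverses direction at ``x_star``."""

    driver: str
    pair: tuple[str, str]
    x_star: float
    sharpness: float = 20.0
    effect: float = 3.0
    direction: int = 1  # +1: synergy below x_star; -1: synergy above


@dataclass
class GroundTruth:
    """Planted structure of a generated landscape (for recovery testing)."""

    driver_effects: dict = field(default_factory=dict)   # (driver, es) -> effect size
    planted_thresholds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "driver_effects": {f"{d}->{e}": v for (d, e), v in self.driver_effects.items()},
            "planted_thresholds": [asdict(t) for t in self.planted_thresholds],
        }


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field (white noise, Gaussian-smoothed)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def _rescale(field_: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field_.min(), field_.max()
    if fmax - fmin < 1e-12:
        return np.full_like(field_, 0.5 * (lo + hi))
    return lo + (field_ - fmin) * (hi - lo) / (fmax - fmin)


def derive_slope(dem: np.ndarray, cellsize: float) -> np.ndarray:
    """Slope in degrees from a DEM via Horn's 3x3 stencil, edge-replicated."""
    if cellsize <= 0:
        raise ConfigurationError("cellsize must be positive")
    z = np.pad(np.asarray(dem, dtype=float), 1, mode="edge")
    # Horn weights: dz/dx = ((c+2f+i) - (a+2d+g)) / (8*cellsize) on the
    # 3x3 window [[a b c], [d e f], [g h i]].
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cellsize)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cellsize)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def derive_erosivity(pre: np.ndarray, a: float = 0.05, b: float = 1.5) -> np.ndarray:
    """Rainfall erosivity from annual precipitation, power law r = a * pre**b.

    The power-law form is this package's default (configurable coefficients);
    it is strictly increasing in precipitation for positive coefficients and
    zero at zero rainfall.
    """
    if a < 0 or b < 0:
        raise ConfigurationError("erosivity coefficients must be non-negative")
    pre = np.asarray(pre, dtype=float)
    if np.any(pre < 0):
        raise ConfigurationError("precipitation must be non-negative")
    return a * np.power(pre, b)


def _classify_landuse(rng, dem_n, slope, pre_n, pop_n, sigma) -> np.ndarray:
    """Six-class land use from terrain covariates plus smoothed noise.

    Suitability scores mirror the region's pattern: cropland on flat low
    plains, forest on steep high terrain, grassland in between, water in the
    lowest wet cells, built-up where population concentrates, unused land as
    scattered residual patches.  Argmax of the scores yields spatially
    autocorrelated patches because every term is itself smooth.
    """
    noise = {c: 0.55 * _smooth_field(rng, dem_n.shape, sigma) for c in LANDUSE_CODES}
    slope_n = slope / max(slope.max(), 1e-9)
    score = {
        CROPLAND: 1.0 - 1.6 * slope_n - 0.8 * dem_n + noise[CROPLAND],
        FOREST: 1.8 * slope_n + 1.1 * dem_n - 0.9 + noise[FOREST],
        GRASSLAND: 0.9 * slope_n + 0.4 * dem_n - 0.25 + noise[GRASSLAND],
        WATER: 0.9 * pre_n - 1.9 * dem_n - 1.35 + noise[WATER],
        BUILTUP: 1.7 * pop_n - 1.3 * slope_n - 1.0 + noise[BUILTUP],
        UNUSED: -1.35 + 0.9 * noise[UNUSED],
    }
    stack = np.stack([score[c] for c in LANDUSE_CODES])
    return np.asarray(LANDUSE_CODES, dtype=np.int64)[np.argmax(stack, axis=0)]


def generate_landscape(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[LandscapeGrid, GroundTruth]:
    """Generate a seeded landscape; identical (config, seed) gives identical output."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (config.nrows, config.ncols)

    # DEM: linear west->east decreasing trend + smoothed random relief.
    cols = np.linspace(1.0, 0.0, config.ncols)[None, :]
    dem = (
        config.dem_base
        + config.dem_trend * cols
        + config.dem_relief * _smooth_field(rng, shape, config.smooth_sigma)
    )
    dem = np.maximum(dem, 0.0)
    dem_n = _rescale(dem, 0.0, 1.0)
    slope = derive_slope(dem, config.cellsize)

    # Precipitation increases with elevation (orographic) plus its own field.
    pre_field = 0.7 * dem_n + 0.5 * _smooth_field(rng, shape, config.smooth_sigma)
    pre = _rescale(pre_field, config.pre_min, config.pre_max)

    # Temperature: lapse with elevation.
    tem_field = -dem_n + 0.25 * _smooth_field(rng, shape, config.smooth_sigma)
    tem = _rescale(tem_field, config.tem_min, config.tem_max)

    frac = np.clip(
        config.aet_frac_mean
        + config.aet_frac_sd * _smooth_field(rng, shape, config.smooth_sigma),
        0.05,
        0.95,
    )
    aet = frac * pre

    ndvi_field = 0.6 * _rescale(pre, 0, 1) + 0.4 * _smooth_field(rng, shape, config.smooth_sigma)
    ndvi = _rescale(ndvi_field, 0.05, config.ndvi_max)

    pop_field = -1.2 * dem_n + 0.8 * _smooth_field(rng, shape, config.smooth_sigma)
    pop_n = _rescale(pop_field, 0.0, 1.0)
    pop = config.pop_max * pop_n**2  # concentrated settlement pattern

    k = _rescale(_smooth_field(rng, shape, config.smooth_sigma), config.k_min, config.k_max)
    r = derive_erosivity(pre, config.erosivity_a, config.erosivity_b)

    landuse = _classify_landuse(rng, dem_n, slope, _rescale(pre, 0, 1), pop_n, config.smooth_sigma)
    ndvi = np.where(landuse == WATER, np.minimum(ndvi, 0.05), ndvi)

    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)

    grid = LandscapeGrid(
        nrows=config.nrows,
        ncols=config.ncols,
        cellsize=config.cellsize,
        dem=dem,
        slope=slope,
        pre=pre,
        tem=tem,
        aet=aet,
        ndvi=ndvi,
        pop=pop,
        k=k,
        r=r,
        landuse=landuse,
        mask=mask,
    )
    return grid, GroundTruth()


def plant_pair_relationship(
    driver_values: np.ndarray,
    x_star: float,
    sharpness: float = 20.0,
    effect: float = 1.0,
    direction: int = 1,
    center: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Binary synergy(1)/trade-off(0) labels whose dependence on a driver
    reverses at ``x_star``.

    With ``center=False`` the label probability is the monotone logistic
    ``sigmoid(effect * sharpness * direction * (x_star - x))``: sharpness to
    infinity gives a deterministic step at ``x_star``; ``effect=0`` gives
    labels independent of the driver.

    With ``center=True`` the planted log-odds is the antisymmetric sigmoid
    step ``effect * direction * (2*w(x) - 1)`` (with
    ``w(x) = sigmoid(sharpness * (x_star - x))``), made exactly zero-mean
    over the supplied cells by subtracting the mean concentrated in the
    deep tail on the heavy side — where the curve is saturated, so the
    subtraction cannot introduce a sign change.  A zero-mean planted
    log-odds makes the sign reversal of the *attribution* (log-odds minus
    its population baseline, which is what the SHAP-curve detector
    estimates) coincide with ``x_star``; use this form when planting
    recoverable thresholds.
    """
    x = np.asarray(driver_values, dtype=float).ravel()
    if not (x.min() < x_star < x.max()):
        raise ConfigurationError(
            f"x_star={x_star} outside driver range [{x.min()}, {x.max()}]"
        )
    if direction not in (1, -1):
        raise ConfigurationError("direction must be +1 or -1")
    with np.errstate(over="ignore"):
        w = 1.0 / (1.0 + np.exp(-sharpness * (x_star - x)))
    if center:
        margin = effect * direction * (2.0 * w - 1.0)
        base = margin.mean()
        amp = abs(effect)
        if amp > 0 and base != 0.0:
            deep = margin > 0.98 * amp if base > 0 else margin < -0.98 * amp
            p_deep = deep.mean()
            shift = base / p_deep if p_deep > 0 else 0.0
            if p_deep > 0 and abs(shift) < 0.9 * amp:
                margin = margin - shift * deep
            else:  # threshold too close to the range edge to localize
                margin = margin - base
        p = 1.0 / (1.0 + np.exp(-margin))
    else:
        with np.errstate(invalid="ignore"):
            z = effect * sharpness * direction * (x_star - x)
        if not np.isfinite(sharpness) or not np.isfinite(effect):
            p = np.where(z > 0, 1.0, np.where(z < 0, 0.0, 0.5))
        else:
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    rng = np.random.default_rng(seed)
    return (rng.random(x.shape) < p).astype(np.int64)


def synthesize_es_from_drivers(
    grid: LandscapeGrid,
    driver_effects: dict[tuple[str, str], float],
    es_names: Sequence[str],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple["np.ndarray", GroundTruth]:
    """Synthesize ES target variables as linear functions of chosen drivers.

    Each ES named in ``es_names`` is built as
    ``sum_d effect(d, es) * zscore(driver d) + noise`` over masked cells.
    ES names absent from ``driver_effects`` become pure noise.  This gives a
    landscape with a *known* driver->ES dependency structure, the ground
    truth against which BBN driver identification is validated; it bypasses
    the production-equation ES models on purpose (their fixed algebra couples
    nearly all factors, which precludes a controlled two-driver design).

    Returns (DataFrame of ES columns over masked cells, GroundTruth).
    """
    import pandas as pd

    factors = grid.factor_table()
    rng = np.random.default_rng(seed)
    n = len(factors)
    out = {}
    for es in es_names:
        signal = np.zeros(n)
        for (drv, target), eff in driver_effects.items():
            if target != es:
                continue
            v = factors[drv].to_numpy(dtype=float)
            signal = signal + eff * (v - v.mean()) / max(v.std(), 1e-12)
        out[es] = signal + noise_sd * rng.standard_normal(n)
    gt = GroundTruth(driver_effects=dict(driver_effects))
    return pd.DataFrame(out), gt
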